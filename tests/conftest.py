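"""Shared fixtures: a designed toy ORF for the mutagenesis-screen tests and
small bilayer constructions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from derlintools.structio import Frame

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

from derlintools.synthetic import design_orf

# Codons fixed so the classic screen mutants exist at their canonical protein
# positions; everything else is non-stop filler.
_FIXED_CODONS = {5: "TAC", 58: "TTT", 64: "CTG", 67: "AAA", 101: "CAA",
                 107: "TTC"}

#: 0-based nucleotide substitutions reproducing the screen's five mutants
SCREEN_MUTANTS = {
    "F58S": (172, "C"),   # TTT -> TCT
    "L64V": (189, "G"),   # CTG -> GTG
    "K67E": (198, "G"),   # AAA -> GAA
    "Q101R": (301, "G"),  # CAA -> CGA
    "F107S": (319, "C"),  # TTC -> TCC
}


def make_screen_orf() -> str:
    return design_orf(112, _FIXED_CODONS)


@pytest.fixture(scope="session")
def screen_orf() -> str:
    orf = make_screen_orf()
    assert len(orf) == 336 and len(orf) % 3 == 0
    return orf


def make_two_leaflet_frame(
    upper_xy: np.ndarray,
    lower_xy: np.ndarray,
    z_sep: float = 4.2,
    box=(10.0, 10.0, 10.0),
    species: str = "POPC",
) -> Frame:
    """Minimal phospholipid-only bilayer frame from explicit lateral sites."""
    upper_xy = np.atleast_2d(upper_xy)
    lower_xy = np.atleast_2d(lower_xy)
    n_u, n_l = len(upper_xy), len(lower_xy)
    coords = np.zeros((n_u + n_l, 3))
    coords[:n_u, :2] = upper_xy
    coords[:n_u, 2] = box[2] / 2 + z_sep / 2
    coords[n_u:, :2] = lower_xy
    coords[n_u:, 2] = box[2] / 2 - z_sep / 2
    n = n_u + n_l
    return Frame(
        atom_names=["P"] * n,
        residue_names=[species] * n,
        residue_ids=list(range(1, n + 1)),
        chains=["U"] * n_u + ["L"] * n_l,
        elements=["P"] * n,
        coordinates=coords,
        box=box,
    )
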