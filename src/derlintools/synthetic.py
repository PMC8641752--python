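"""Synthetic bilayer trajectories and mutagenesis-screen read pairs.

The generator plants known structure — lipid composition, leaflet planes,
localized thinning funnels near a protein stand-in, nucleotide substitutions
in paired reads — so every downstream analysis can be validated against a
closed-form ground truth instead of an MD engine.

Geometry: each leaflet is a square lattice of headgroup particles at the
configured area-per-lipid spacing, with Gaussian lateral/vertical jitter
refreshed every frame (the mapping analyses pool frames, so temporal
correlation is deliberately absent).  A thinning defect pulls both headgroup
planes toward the midplane with a lateral Gaussian profile; ``leaflet_share``
sets how much of the deformation the upper (cytosolic) leaflet carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .structio import Frame, Trajectory, min_image_displacement

__all__ = [
    "ThinningDefect",
    "ProteinStub",
    "BilayerSpec",
    "ReadPair",
    "PRESET_NAMES",
    "build_bilayer_spec",
    "allocate_species",
    "generate_trajectory",
    "planted_thickness",
    "generate_screen_read_pair",
    "reverse_complement",
    "design_orf",
    "write_read_pairs_fasta",
]

#: ER membrane composition by number fraction (mixed bilayer patch)
ER_COMPOSITION: Mapping[str, float] = {
    "POPC": 0.47,
    "POPE": 0.20,
    "CHL1": 0.15,
    "POPI": 0.11,
    "POPS": 0.07,
}

PHOSPHOLIPIDS = frozenset({"POPC", "POPE", "POPI", "POPS"})


@dataclass(frozen=True)
class ThinningDefect:
    """A localized membrane-thinning funnel.

    ``floor_thickness`` is the total (trans-leaflet) thickness at the defect
    center; the deformation depth decays laterally as a Gaussian of width
    ``sigma``.  ``leaflet_share`` is the fraction of the deformation carried
    by the upper leaflet (1.0 = cytosolic side only).
    """

    center_xy: tuple[float, float]
    floor_thickness: float
    sigma: float
    leaflet_share: float = 0.5

    def validate(self, leaflet_separation: float) -> None:
        if not (0.0 < self.floor_thickness <= leaflet_separation + 1e-12):
            raise ValueError(
                f"floor_thickness {self.floor_thickness} must be in "
                f"(0, leaflet_separation={leaflet_separation}]"
            )
        if self.sigma <= 0:
            raise ValueError("defect sigma must be > 0")
        if not (0.0 <= self.leaflet_share <= 1.0):
            raise ValueError("leaflet_share must be in [0, 1]")


@dataclass(frozen=True)
class ProteinStub:
    """Lateral helix-axis positions standing in for a TM-helix bundle."""

    helix_axes: tuple[tuple[str, tuple[float, float]], ...]
    exclusion_radius: float = 0.4

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.helix_axes]
        if len(set(labels)) != len(labels):
            raise ValueError("helix labels must be unique")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")

    def axis_positions(self) -> np.ndarray:
        return np.array([xy for _, xy in self.helix_axes], dtype=float)

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.helix_axes]


@dataclass(frozen=True)
class BilayerSpec:
    """Full description of a synthetic bilayer patch."""

    box_x: float = 10.0
    box_y: float = 10.0
    leaflet_separation: float = 4.2
    area_per_lipid: float = 0.50
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(ER_COMPOSITION)
    )
    lateral_jitter_sd: float = 0.05
    vertical_jitter_sd: float = 0.05
    defects: tuple[ThinningDefect, ...] = ()
    protein: ProteinStub | None = None
    n_frames: int = 50
    frame_interval_label: str = "1 ns"

    def __post_init__(self) -> None:
        for name, value in [
            ("box_x", self.box_x),
            ("box_y", self.box_y),
            ("leaflet_separation", self.leaflet_separation),
            ("area_per_lipid", self.area_per_lipid),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lateral_jitter_sd < 0 or self.vertical_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, expected 1")
        if self.box_x * self.box_y / self.area_per_lipid < 4:
            raise ValueError("patch too small: fewer than 4 lipids per leaflet")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for d in self.defects:
            d.validate(self.leaflet_separation)

    @property
    def box_z(self) -> float:
        return 2.0 * self.leaflet_separation

    def lattice(self) -> tuple[np.ndarray, float, float]:
        """Lattice site centers and the effective spacings (nm).

        Sites per side round ``box / sqrt(area_per_lipid)`` so the lattice
        tiles the periodic box exactly.
        """
        target = math.sqrt(self.area_per_lipid)
        nx = max(2, round(self.box_x / target))
        ny = max(2, round(self.box_y / target))
        sx, sy = self.box_x / nx, self.box_y / ny
        xs = (np.arange(nx) + 0.5) * sx
        ys = (np.arange(ny) + 0.5) * sy
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()]), sx, sy


@dataclass(frozen=True)
class ReadPair:
    """Paired Sanger-style reads; the reverse read is 5'->3' on the opposite
    strand of its covered interval."""

    forward_seq: str
    reverse_seq: str
    coverage_intervals: Mapping[str, tuple[int, int]]
    planted_mutations: tuple[tuple[int, str, str], ...]


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("ER_BULK", "DFM1_WT", "DFM1_F107S", "DFM1_QUAD", "DERLIN1_TETRAMER")

_HELIX_RING_RADIUS = 1.1
# ring placement (degrees) of the six TM helices; TM2/TM5 are spatially
# adjacent (the lateral gate) and TM1/TM6 adjacent on the far face
_HELIX_ANGLES = {"TM1": 200.0, "TM2": 40.0, "TM3": 260.0, "TM4": 320.0,
                 "TM5": 100.0, "TM6": 140.0}
_MONOMER_DEFECT_SIGMA = 3.0
_TETRAMER_DEFECT_SIGMA = 2.5


def _helix_xy(angle_deg: float, center: tuple[float, float],
              rotation_deg: float = 0.0) -> tuple[float, float]:
    a = math.radians(angle_deg + rotation_deg)
    return (center[0] + _HELIX_RING_RADIUS * math.cos(a),
            center[1] + _HELIX_RING_RADIUS * math.sin(a))


def _monomer_stub(center: tuple[float, float]) -> ProteinStub:
    axes = tuple(
        (name, _helix_xy(ang, center)) for name, ang in _HELIX_ANGLES.items()
    )
    return ProteinStub(helix_axes=axes)


def _tetramer_stub(center: tuple[float, float], ring_radius: float = 2.2) -> ProteinStub:
    axes = []
    for protomer, theta in zip("ABCD", (45.0, 135.0, 225.0, 315.0)):
        pc = (center[0] + ring_radius * math.cos(math.radians(theta)),
              center[1] + ring_radius * math.sin(math.radians(theta)))
        # rotate each protomer so its TM1/TM6 face (local angle 170 deg)
        # points radially outward
        rot = theta - 170.0
        for name, ang in _HELIX_ANGLES.items():
            axes.append((f"{protomer}:{name}", _helix_xy(ang, pc, rot)))
    return ProteinStub(helix_axes=tuple(axes))


def _gate_midpoint(stub: ProteinStub, label_a: str, label_b: str) -> tuple[float, float]:
    pos = dict(stub.helix_axes)
    (ax, ay), (bx, by) = pos[label_a], pos[label_b]
    return ((ax + bx) / 2.0, (ay + by) / 2.0)


def build_bilayer_spec(preset_name: str, overrides: Mapping | None = None) -> BilayerSpec:
    """Build one of the named study presets, optionally overriding fields.

    Presets other than ER_BULK carry a single thinning defect at the TM2–TM5
    gate midpoint (or the peripheral TM1–TM6 midpoint for the tetramer) whose
    floor thickness is the midpoint of the thickness range observed for that
    condition: WT 2.25 nm split over both leaflets, F107S 3.25 nm carried by
    the cytosolic leaflet only, quad mutant capped at the unperturbed
    separation (thinning ablated), tetramer periphery 3.5 nm.
    """
    if preset_name not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {preset_name!r}; expected one of {PRESET_NAMES}"
        )
    base = BilayerSpec()
    center = (base.box_x / 2.0, base.box_y / 2.0)

    if preset_name == "ER_BULK":
        spec = base
    elif preset_name == "DERLIN1_TETRAMER":
        stub = _tetramer_stub(center)
        spec = replace(
            base,
            protein=stub,
            defects=(
                ThinningDefect(
                    center_xy=_gate_midpoint(stub, "A:TM1", "A:TM6"),
                    floor_thickness=3.5,
                    sigma=_TETRAMER_DEFECT_SIGMA,
                    leaflet_share=0.5,
                ),
            ),
        )
    else:
        stub = _monomer_stub(center)
        gate = _gate_midpoint(stub, "TM2", "TM5")
        floor, share = {
            "DFM1_WT": (2.25, 0.5),
            "DFM1_F107S": (3.25, 1.0),  # cytosolic leaflet only
            "DFM1_QUAD": (base.leaflet_separation, 0.5),  # thinning ablated
        }[preset_name]
        spec = replace(
            base,
            protein=stub,
            defects=(
                ThinningDefect(
                    center_xy=gate,
                    floor_thickness=floor,
                    sigma=_MONOMER_DEFECT_SIGMA,
                    leaflet_share=share,
                ),
            ),
        )

    if overrides:
        spec = replace(spec, **dict(overrides))
    return spec


# ---------------------------------------------------------------------------
# trajectory generation


def allocate_species(composition: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` lipids over ``composition``.

    Ties broken by larger fraction, then species name, so the allocation is
    deterministic.
    """
    items = list(composition.items())
    floors = {name: int(math.floor(frac * n)) for name, frac in items}
    leftover = n - sum(floors.values())
    remainders = sorted(
        items,
        key=lambda kv: (-(kv[1] * n - math.floor(kv[1] * n)), -kv[1], kv[0]),
    )
    for name, _ in remainders[:leftover]:
        floors[name] += 1
    return floors


def _deformation_depths(
    spec: BilayerSpec, xy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point deformation of the upper and lower headgroup planes (nm >= 0)."""
    up = np.zeros(len(xy))
    lo = np.zeros(len(xy))
    box = np.array([spec.box_x, spec.box_y, 1.0])
    for d in spec.defects:
        depth_total = spec.leaflet_separation - d.floor_thickness
        if depth_total <= 0:
            continue
        disp = min_image_displacement(
            np.column_stack([xy, np.zeros(len(xy))]),
            np.array([d.center_xy[0], d.center_xy[1], 0.0]),
            box,
            wrap_axes=("x", "y"),
        )
        r2 = disp[:, 0] ** 2 + disp[:, 1] ** 2
        g = depth_total * np.exp(-r2 / (2.0 * d.sigma**2))
        up += d.leaflet_share * g
        lo += (1.0 - d.leaflet_share) * g
    return up, lo


def planted_thickness(spec: BilayerSpec, xy: np.ndarray) -> np.ndarray:
    """Closed-form planted total thickness at lateral points (jitter-free)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    up, lo = _deformation_depths(spec, xy)
    return spec.leaflet_separation - up - lo


_BACKBONE_OFFSETS = {
    "N": (0.00, 0.12, -0.10),
    "CA": (0.00, 0.00, 0.00),
    "C": (0.12, 0.00, 0.10),
    "O": (0.18, 0.10, 0.12),
}


def generate_trajectory(spec: BilayerSpec, seed: int, k_default: int = 3) -> Trajectory:
    """Generate a multi-frame trajectory realising ``spec``.

    Deterministic for fixed (spec, seed).  Species are assigned by
    largest-remainder allocation over the (post-exclusion) lipid count of each
    leaflet and randomly permuted over lattice sites once; jitter is fresh
    every frame.  Cholesterol carries its hydroxyl-proxy particle (atom name
    O3, non-phosphate); phospholipids carry a single P particle.  If a protein
    stub is present, each helix axis contributes four backbone pseudo-residues
    (N, CA, C, O) spanning the membrane, with small per-frame wobble.
    """
    rng = np.random.default_rng(seed)
    sites, _, _ = spec.lattice()

    if spec.protein is not None and spec.protein.exclusion_radius > 0:
        axes = spec.protein.axis_positions()
        box = np.array([spec.box_x, spec.box_y, 1.0])
        keep = np.ones(len(sites), dtype=bool)
        for axis_xy in axes:
            disp = min_image_displacement(
                np.column_stack([sites, np.zeros(len(sites))]),
                np.array([axis_xy[0], axis_xy[1], 0.0]),
                box,
            )
            keep &= np.hypot(disp[:, 0], disp[:, 1]) >= spec.protein.exclusion_radius
        sites = sites[keep]

    n_per_leaflet = len(sites)
    if n_per_leaflet < 2 * k_default + 2:
        raise ValueError(
            f"only {n_per_leaflet} lipids per leaflet after exclusion; "
            f"need >= {2 * k_default + 2} for the thickness analysis"
        )

    counts = allocate_species(spec.composition, n_per_leaflet)
    species_template = [
        name for name in spec.composition for _ in range(counts[name])
    ]

    atom_names: list[str] = []
    residue_names: list[str] = []
    residue_ids: list[int] = []
    chains: list[str] = []
    elements: list[str] = []
    leaflet_species: dict[str, list[str]] = {}

    resid = 1
    for leaflet_code in ("U", "L"):
        order = rng.permutation(n_per_leaflet)
        species = [species_template[j] for j in order]
        leaflet_species[leaflet_code] = species
        for sp in species:
            is_chol = sp not in PHOSPHOLIPIDS
            atom_names.append("O3" if is_chol else "P")
            elements.append("O" if is_chol else "P")
            residue_names.append(sp)
            residue_ids.append(resid)
            chains.append(leaflet_code)
            resid += 1

    protein_base: np.ndarray | None = None
    if spec.protein is not None:
        coords = []
        z_levels = np.linspace(-1.5, 1.5, 4)
        for label, (hx, hy) in spec.protein.helix_axes:
            for z in z_levels:
                for aname, off in _BACKBONE_OFFSETS.items():
                    atom_names.append(aname)
                    elements.append(aname[0])
                    residue_names.append("ALA")
                    residue_ids.append(resid)
                    chains.append("P")
                    coords.append([hx + off[0], hy + off[1], z + off[2]])
                resid += 1
        protein_base = np.asarray(coords)

    box = np.array([spec.box_x, spec.box_y, spec.box_z])
    mid_z = spec.box_z / 2.0
    n_lipids = 2 * n_per_leaflet

    frames = []
    for t in range(spec.n_frames):
        lateral = np.concatenate([sites, sites], axis=0)
        if spec.lateral_jitter_sd > 0:
            lateral = lateral + rng.normal(0.0, spec.lateral_jitter_sd, lateral.shape)
        lateral %= box[:2]
        up_def, _ = _deformation_depths(spec, lateral[:n_per_leaflet])
        _, lo_def = _deformation_depths(spec, lateral[n_per_leaflet:])
        z = np.empty(n_lipids)
        z[:n_per_leaflet] = mid_z + spec.leaflet_separation / 2.0 - up_def
        z[n_per_leaflet:] = mid_z - spec.leaflet_separation / 2.0 + lo_def
        if spec.vertical_jitter_sd > 0:
            z += rng.normal(0.0, spec.vertical_jitter_sd, n_lipids)
        coords = np.column_stack([lateral, z])
        if protein_base is not None:
            wobble = rng.normal(0.0, 0.02, protein_base.shape)
            prot = protein_base + wobble
            prot[:, 2] += mid_z
            coords = np.vstack([coords, prot])
        frames.append(
            Frame(
                atom_names, residue_names, residue_ids, chains, elements,
                coords, box=box, frame_index=t,
            )
        )

    return Trajectory(
        frames,
        metadata={
            "source": "synthetic",
            "frame_interval": spec.frame_interval_label,
            "species_counts": counts,
            "n_per_leaflet": n_per_leaflet,
        },
    )


# ---------------------------------------------------------------------------
# screen reads

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_screen_read_pair(
    reference_orf: str,
    mutations: Sequence[tuple[int, str]],
    error_rate: float = 0.0,
    seed: int = 0,
    forward_interval: tuple[int, int] | None = None,
    reverse_interval: tuple[int, int] | None = None,
) -> ReadPair:
    """Emulate paired forward/reverse Sanger reads of a mutagenized clone.

    Both reads carry the planted substitutions where their coverage interval
    spans them; independent random read errors are sprinkled at
    ``error_rate`` per base.  The reverse read is the reverse complement of
    its covered interval (reported 5'->3' on the opposite strand).
    """
    ref = reference_orf.upper()
    n = len(ref)
    if not (0.0 <= error_rate <= 0.05):
        raise ValueError("error_rate must be in [0, 0.05]")
    fwd_iv = (0, n) if forward_interval is None else tuple(forward_interval)
    rev_iv = (0, n) if reverse_interval is None else tuple(reverse_interval)
    for s, e in (fwd_iv, rev_iv):
        if not (0 <= s < e <= n):
            raise ValueError(f"coverage interval ({s}, {e}) outside reference")

    mutated = list(ref)
    planted = []
    for pos, alt in mutations:
        if not (0 <= pos < n):
            raise ValueError(f"mutation position {pos} outside reference")
        alt = alt.upper()
        if ref[pos] == alt:
            raise ValueError(
                f"alt base {alt} equals reference base at position {pos}"
            )
        planted.append((pos, ref[pos], alt))
        mutated[pos] = alt
    mutated = "".join(mutated)

    rng = np.random.default_rng(seed)

    def with_errors(seq: str) -> str:
        if error_rate == 0.0:
            return seq
        out = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
        for i in hits:
            choices = [b for b in _BASES if b != out[i]]
            out[i] = choices[rng.integers(len(choices))]
        return "".join(out)

    forward = with_errors(mutated[fwd_iv[0] : fwd_iv[1]])
    reverse = with_errors(reverse_complement(mutated[rev_iv[0] : rev_iv[1]]))
    return ReadPair(
        forward_seq=forward,
        reverse_seq=reverse,
        coverage_intervals={"forward": fwd_iv, "reverse": rev_iv},
        planted_mutations=tuple(planted),
    )


_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOP_CODONS
)


def design_orf(n_codons: int = 112, fixed_codons: Mapping[int, str] | None = None) -> str:
    """Deterministic toy ORF: ATG start, non-stop filler codons, TAA terminus.

    Filler codons are drawn pseudo-randomly from a fixed internal seed so the
    sequence is reproducible yet non-repetitive (repetitive filler would make
    read placement ambiguous).  ``fixed_codons`` pins specific codons by
    1-based codon index so screen scenarios can place wild-type residues at
    canonical protein positions.
    """
    if n_codons < 3:
        raise ValueError("need at least start, one codon and stop")
    fixed = {1: "ATG", n_codons: "TAA"}
    if fixed_codons:
        fixed.update(fixed_codons)
    rng = np.random.default_rng(8675309)
    codons = []
    for i in range(1, n_codons + 1):
        filler = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
        codons.append(fixed.get(i, filler))
    return "".join(codons)


def write_read_pairs_fasta(pairs: Mapping[str, ReadPair], path) -> None:
    """Write read pairs as plain FASTA with /fwd and /rev id suffixes."""
    with open(path, "w") as fh:
        for clone_id, pair in pairs.items():
            fh.write(f">{clone_id}/fwd\n{pair.forward_seq}\n")
            fh.write(f">{clone_id}/rev\n{pair.reverse_seq}\n")
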