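"""Coordinate I/O and shared geometry utilities.

Internal units are nm everywhere (the convention of the MD engine output this
pipeline mirrors); Ångström appears only at the PDB boundary.  Boxes are
orthorhombic; the membrane normal is fixed to z and inputs are never
reoriented.  Atom indices are 0-based internally; residue numbering is
preserved verbatim from input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "HeadgroupSelection",
    "DEFAULT_HEADGROUP_RULES",
    "read_structure",
    "write_structure",
    "select_headgroups",
    "min_image_displacement",
    "min_image_distance",
]

NM_PER_ANGSTROM = 0.1

#: residues treated as protein and silently skipped by lipid selections
PROTEIN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: names, residue bookkeeping and a coordinate in nm."""

    atom_name: str
    residue_name: str
    residue_id: int
    chain_or_segment: str
    element: str
    coordinate: np.ndarray

    def __post_init__(self) -> None:
        coord = np.asarray(self.coordinate, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("coordinate must be a finite 3-vector")
        object.__setattr__(self, "coordinate", coord)
        if self.residue_id < 0:
            raise ValueError("residue_id must be >= 0")


class Frame:
    """A single frame: flat numpy topology arrays plus coordinates (nm).

    Columnar storage keeps the analyses vectorised; :meth:`atom` materialises
    an :class:`AtomRecord` view when a per-atom object is convenient.
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        chains: Sequence[str],
        elements: Sequence[str],
        coordinates: np.ndarray,
        box: Sequence[float] | None = None,
        frame_index: int = 0,
    ) -> None:
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.coordinates = np.array(coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        n = self.coordinates.shape[0]
        for arr, name in [
            (self.atom_names, "atom_names"),
            (self.residue_names, "residue_names"),
            (self.residue_ids, "residue_ids"),
            (self.chains, "chains"),
            (self.elements, "elements"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_atoms {n}")
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None and self.box.shape != (3,):
            raise ValueError("box must be a 3-vector")
        self.frame_index = int(frame_index)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_name=str(self.atom_names[i]),
            residue_name=str(self.residue_names[i]),
            residue_id=int(self.residue_ids[i]),
            chain_or_segment=str(self.chains[i]),
            element=str(self.elements[i]),
            coordinate=self.coordinates[i],
        )

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def require_periodic_box(self) -> np.ndarray:
        if self.box is None or np.any(self.box[:2] <= 0):
            raise ValueError("periodic analysis requested but frame has no valid box")
        return self.box

    def with_coordinates(self, coords: np.ndarray, frame_index: int | None = None) -> "Frame":
        return Frame(
            self.atom_names,
            self.residue_names,
            self.residue_ids,
            self.chains,
            self.elements,
            coords,
            box=self.box,
            frame_index=self.frame_index if frame_index is None else frame_index,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table."""

    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        names0 = self.frames[0].atom_names
        for f in self.frames[1:]:
            if f.n_atoms != n0:
                raise ValueError(
                    f"inconsistent atom count across frames: {f.n_atoms} != {n0}"
                )
            if not np.array_equal(f.atom_names, names0):
                raise ValueError("inconsistent atom ordering across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


# ---------------------------------------------------------------------------
# periodic geometry


def min_image_displacement(
    a: np.ndarray,
    b: np.ndarray,
    box: Sequence[float] | None,
    wrap_axes: Iterable[int | str] = ("x", "y"),
) -> np.ndarray:
    """Displacement a-b with minimum-image convention on ``wrap_axes`` only.

    ``wrap_axes`` defaults to the lateral axes: the bilayer normal (z) is not
    wrapped.  Axes may be given as names or indices.  Broadcasts over leading
    dimensions of ``a`` and ``b``.
    """
    axis_index = {"x": 0, "y": 1, "z": 2}
    axes = sorted(axis_index.get(ax, ax) for ax in wrap_axes)
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if axes:
        if box is None:
            raise ValueError("box required for wrapped axes")
        box = np.asarray(box, dtype=float)
        for ax in axes:
            if box[ax] <= 0:
                raise ValueError(f"box component {ax} must be > 0 for wrapping")
            d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def min_image_distance(
    a: np.ndarray,
    b: np.ndarray,
    box: Sequence[float] | None,
    wrap_axes: Iterable[int | str] = ("x", "y"),
) -> float | np.ndarray:
    """Euclidean distance under lateral minimum-image wrapping."""
    d = min_image_displacement(a, b, box, wrap_axes)
    return np.linalg.norm(d, axis=-1)


# ---------------------------------------------------------------------------
# headgroup selection

#: residue-name -> headgroup atom name; cholesterol's hydroxyl oxygen is the
#: proxy headgroup and is flagged non-phosphate downstream.
DEFAULT_HEADGROUP_RULES: Mapping[str, str] = {
    "POPC": "P",
    "POPE": "P",
    "POPI": "P",
    "POPS": "P",
    "CHL1": "O3",
    "CHOL": "O3",
}

NON_PHOSPHATE_ATOMS = frozenset({"O3"})


@dataclass
class HeadgroupSelection:
    """One headgroup atom index per lipid residue, with audit reports.

    ``is_phosphate`` parallels ``indices``; lipids whose named atom is absent
    are reported in ``missing`` (residue_name, residue_id), residues matching
    no rule in ``unclassified`` — neither is silently dropped.
    """

    indices: np.ndarray
    is_phosphate: np.ndarray
    missing: list[tuple[str, int]]
    unclassified: list[str]

    def __len__(self) -> int:
        return len(self.indices)


def select_headgroups(
    frame: Frame, rules: Mapping[str, str] | None = None
) -> HeadgroupSelection:
    """Pick one headgroup atom per lipid residue according to ``rules``."""
    rules = DEFAULT_HEADGROUP_RULES if rules is None else rules
    indices: list[int] = []
    phosphate: list[bool] = []
    missing: list[tuple[str, int]] = []
    unclassified: list[str] = []
    seen_unclassified: set[str] = set()

    # group atoms by (chain, residue_id, residue_name) preserving order
    keys = list(zip(frame.chains, frame.residue_ids, frame.residue_names))
    residue_atoms: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        residue_atoms.setdefault(key, []).append(i)

    for (chain, resid, resname), atom_ids in residue_atoms.items():
        resname = str(resname)
        if resname in PROTEIN_RESIDUES:
            continue
        if resname not in rules:
            if resname not in seen_unclassified:
                unclassified.append(resname)
                seen_unclassified.add(resname)
            continue
        target = rules[resname]
        hit = next(
            (i for i in atom_ids if str(frame.atom_names[i]) == target), None
        )
        if hit is None:
            missing.append((resname, int(resid)))
        else:
            indices.append(hit)
            phosphate.append(target not in NON_PHOSPHATE_ATOMS)

    return HeadgroupSelection(
        indices=np.asarray(indices, dtype=int),
        is_phosphate=np.asarray(phosphate, dtype=bool),
        missing=missing,
        unclassified=unclassified,
    )


# ---------------------------------------------------------------------------
# PDB / GRO readers and writers


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _parse_pdb(path: Path) -> Trajectory:
    frames: list[Frame] = []
    box = None
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    chains: list[str] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    in_model = False
    model_count = 0

    def flush() -> None:
        nonlocal names, resnames, resids, chains, elements, coords, model_count
        if not coords:
            return
        frames.append(
            Frame(
                names,
                resnames,
                resids,
                chains,
                elements,
                np.asarray(coords) * NM_PER_ANGSTROM,
                box=box,
                frame_index=model_count,
            )
        )
        model_count += 1
        names, resnames, resids, chains, elements, coords = [], [], [], [], [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                    alpha = float(line[33:40])
                    beta = float(line[40:47])
                    gamma = float(line[47:54])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed CRYST1 record") from exc
                if not (alpha == beta == gamma == 90.0):
                    raise ValueError(
                        f"{path}:{lineno}: triclinic box not supported "
                        "(orthorhombic boxes only)"
                    )
                box = np.array([a, b, c]) * NM_PER_ANGSTROM
            elif rec == "MODEL ":
                in_model = True
            elif rec == "ENDMDL":
                flush()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    chain = line[21].strip() or line[72:76].strip()
                    resid = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed ATOM/HETATM record"
                    ) from exc
                element = line[76:78].strip() or _infer_element(name)
                names.append(name)
                resnames.append(resname)
                resids.append(resid)
                chains.append(chain)
                elements.append(element)
                coords.append([x, y, z])
    flush()
    if not frames:
        raise ValueError(f"{path}: no atom records found")
    n0 = frames[0].n_atoms
    for f in frames:
        if f.n_atoms != n0:
            raise ValueError(
                f"{path}: inconsistent atom count across models ({f.n_atoms} != {n0})"
            )
    return Trajectory(frames, metadata={"source": str(path), "format": "pdb"})


def _parse_gro(path: Path) -> Trajectory:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    lineno = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        title_line = pos
        try:
            n_atoms = int(lines[pos + 1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}:{title_line + 2}: expected atom count"
            ) from exc
        body = lines[pos + 2 : pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ValueError(f"{path}: truncated frame starting at line {title_line + 1}")
        names, resnames, resids, chains, elements = [], [], [], [], []
        coords = np.empty((n_atoms, 3))
        for k, line in enumerate(body):
            lineno = title_line + 3 + k
            try:
                resids.append(int(line[0:5]))
                resnames.append(line[5:10].strip())
                names.append(line[10:15].strip())
                coords[k, 0] = float(line[20:28])
                coords[k, 1] = float(line[28:36])
                coords[k, 2] = float(line[36:44])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed GRO atom line") from exc
            chains.append("")
            elements.append(_infer_element(names[-1]))
        box_line = lines[pos + 2 + n_atoms]
        parts = box_line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{title_line + n_atoms + 3}: malformed box line")
        if len(parts) > 3 and any(float(v) != 0.0 for v in parts[3:]):
            raise ValueError(
                f"{path}:{title_line + n_atoms + 3}: triclinic box not supported"
            )
        box = np.array([float(parts[0]), float(parts[1]), float(parts[2])])
        frames.append(
            Frame(
                names, resnames, resids, chains, elements, coords,
                box=box, frame_index=len(frames),
            )
        )
        pos += 2 + n_atoms + 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(frames, metadata={"source": str(path), "format": "gro"})


def read_structure(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a multi-model PDB or (multi-frame) GRO file into a Trajectory.

    Coordinates are converted to nm internally (PDB is Å-native, GRO is
    nm-native); the box is taken from CRYST1 / the GRO box line when present.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "pdb":
        return _parse_pdb(path)
    if format == "gro":
        return _parse_gro(path)
    raise ValueError(f"unsupported structure format: {format!r}")


def write_structure(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB (Å) or concatenated GRO (nm)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "pdb":
        _write_pdb(traj, path)
    elif format == "gro":
        _write_gro(traj, path)
    else:
        raise ValueError(f"unsupported structure format: {format!r}")


def _write_pdb(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        first = traj.frames[0]
        if first.box is not None:
            a, b, c = first.box * 10.0
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        multi = traj.n_frames > 1
        for m, frame in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(frame.n_atoms):
                name = str(frame.atom_names[i])
                pad_name = f" {name:<3s}" if len(name) < 4 else name[:4]
                x, y, z = frame.coordinates[i] * 10.0
                chain = (str(frame.chains[i]) or " ")[:1]
                fh.write(
                    f"ATOM  {min(i + 1, 99999):5d} {pad_name} {str(frame.residue_names[i]):<4s}"
                    f"{chain}{int(frame.residue_ids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                    f"{str(frame.elements[i]):>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_gro(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"frame {frame.frame_index}\n")
            fh.write(f"{frame.n_atoms:5d}\n")
            for i in range(frame.n_atoms):
                x, y, z = frame.coordinates[i]
                fh.write(
                    f"{int(frame.residue_ids[i]) % 100000:5d}"
                    f"{str(frame.residue_names[i]):<5s}"
                    f"{str(frame.atom_names[i]):>5s}"
                    f"{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            box = frame.box if frame.box is not None else np.zeros(3)
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")
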