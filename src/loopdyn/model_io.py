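"""Topologies, coordinate ensembles and atom selection.

The data model is deliberately small: a :class:`Topology` (atoms, residues,
purine/pyrimidine typing and the symmetry permutation group of a
self-complementary duplex) and a :class:`Trajectory` (frames x atoms x 3
Cartesian coordinates in Angstrom).  Multi-model PDB files are read and
written through biotite; a plain columnar text dialect
(``frame,time,atom,x,y,z``) is provided for diff-able fixtures.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "FormatError",
    "SelectionError",
    "load_topology",
    "load_trajectory",
    "write_trajectory",
    "select_atoms",
    "parse_selection",
    "set_symmetry",
]

PURINES = {"A", "G", "DA", "DG", "RA", "RG", "ADE", "GUA"}
PYRIMIDINES = {"C", "U", "T", "DC", "DT", "RC", "RU", "CYT", "URA", "THY"}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class SelectionError(ValueError):
    """Raised for empty or out-of-range atom selections."""


@dataclass(frozen=True)
class Atom:
    """A single atom: PDB-convention name, element and residue membership."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str

    @property
    def is_hydrogen(self) -> bool:
        # Element field is authoritative; fall back to the atom name with
        # leading digits stripped (PDB hydrogen names like "1H5'").
        if self.element:
            return self.element.upper() == "H"
        stripped = self.name.lstrip("0123456789")
        return stripped[:1].upper() == "H"


@dataclass(frozen=True)
class Residue:
    """A residue: contiguous atom index range [start, stop)."""

    chain_id: str
    index: int
    name: str
    start: int
    stop: int
    resseq: int = 0  # author numbering, metadata only

    @property
    def atom_indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


def _base_type(residue_name: str) -> str:
    name = residue_name.strip().upper()
    if name in PURINES:
        return "purine"
    if name in PYRIMIDINES:
        return "pyrimidine"
    return "unknown"


@dataclass
class Topology:
    """Atoms, residues, base typing and symmetry permutations of a model.

    ``symmetry_perms`` always contains the identity; :func:`set_symmetry`
    adds the strand-swap permutation of a self-complementary duplex.  Every
    permutation maps each atom index to an atom of identical name.
    """

    atoms: list[Atom]
    residues: list[Residue]
    symmetry_perms: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.symmetry_perms:
            self.symmetry_perms = [np.arange(self.n_atoms)]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def base_types(self) -> list[str]:
        return [_base_type(r.name) for r in self.residues]

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        return self.residues[residue_index].atom_indices

    def find_atom(self, residue_index: int, name: str) -> int | None:
        res = self.residues[residue_index]
        for i in range(res.start, res.stop):
            if self.atoms[i].name == name:
                return i
        return None


@dataclass
class Trajectory:
    """An ordered ensemble of frames over a fixed topology.

    Coordinates are Angstrom, shape (n_frames, n_atoms, 3); frame times are
    strictly increasing and default to the frame index.
    """

    coordinates: np.ndarray
    topology: Topology
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology ({self.topology.n_atoms} atoms)"
            )
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def slice_frames(self, index) -> "Trajectory":
        idx = np.arange(self.n_frames)[index]
        return Trajectory(
            self.coordinates[idx], self.topology, self.frame_times[idx]
        )


# ---------------------------------------------------------------------------
# PDB reading / writing


def _validate_pdb_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise FormatError(
                        f"{path}: unparseable coordinate record at line {lineno}"
                    ) from None


def _topology_from_atom_array(array: struc.AtomArray) -> Topology:
    atoms: list[Atom] = []
    residues: list[Residue] = []
    res_key = None
    for i in range(array.array_length()):
        chain = str(array.chain_id[i])
        resseq = int(array.res_id[i])
        resname = str(array.res_name[i]).strip()
        key = (chain, resseq, resname)
        if key != res_key:
            if residues:
                residues[-1] = replace(residues[-1], stop=i)
            residues.append(
                Residue(chain, len(residues), resname, i, -1, resseq=resseq)
            )
            res_key = key
        element = str(array.element[i]).strip() if array.element is not None else ""
        atoms.append(
            Atom(
                name=str(array.atom_name[i]).strip(),
                element=element,
                residue_index=len(residues) - 1,
                residue_name=resname,
                chain_id=chain,
            )
        )
    if residues:
        residues[-1] = replace(residues[-1], stop=len(atoms))
    topo = Topology(atoms, residues)
    for res, btype in zip(topo.residues, topo.base_types):
        if btype == "unknown":
            warnings.warn(
                f"residue {res.name} (chain {res.chain_id}, index {res.index}) "
                "has unknown base type; excluded from glycosidic analysis",
                stacklevel=3,
            )
    return topo


def load_topology(path: str) -> Topology:
    """Read a PDB file and return its topology (first model).

    Residues are grouped by (chain, resSeq) in file order; purine or
    pyrimidine typing follows the residue name, unknown names are kept with
    a warning.  ``symmetry_perms`` starts as [identity].
    """
    _validate_pdb_lines(path)
    try:
        pdb_file = pdbio.PDBFile.read(path)
        array = pdb_file.get_structure(model=1)
    except FormatError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"{path}: {exc}") from exc
    if array.array_length() == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return _topology_from_atom_array(array)


def _load_columnar(path: str, topology: Topology) -> Trajectory:
    df = pd.read_csv(path)
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: columnar dialect requires columns {sorted(required)}"
        )
    n_atoms = topology.n_atoms
    frames = []
    times = []
    time_col = next(
        (c for c in df.columns if c == "time" or c.startswith("time_")), None
    )
    for k, (frame_id, grp) in enumerate(df.groupby("frame", sort=True)):
        if len(grp) != n_atoms:
            raise FormatError(
                f"{path}: model {frame_id} has {len(grp)} atoms, expected {n_atoms}"
            )
        grp = grp.sort_values("atom")
        frames.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
        times.append(float(grp[time_col].iloc[0]) if time_col else float(k))
    return Trajectory(np.stack(frames), topology, np.asarray(times))


def load_trajectory(path: str, topology: Topology) -> Trajectory:
    """Read a multi-model PDB or columnar text file as a Trajectory.

    The dialect is sniffed from the first line.  Any model whose atom count
    differs from the topology raises an error naming the model index.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.lower().startswith("frame"):
        return _load_columnar(path, topology)
    _validate_pdb_lines(path)
    pdb_file = pdbio.PDBFile.read(path)
    n_models = pdb_file.get_model_count()
    frames = []
    for m in range(1, n_models + 1):
        array = pdb_file.get_structure(model=m)
        if array.array_length() != topology.n_atoms:
            raise FormatError(
                f"{path}: model {m} has {array.array_length()} atoms, "
                f"expected {topology.n_atoms}"
            )
        frames.append(np.asarray(array.coord, dtype=float))
    if not frames:
        raise FormatError(f"{path}: no models found")
    return Trajectory(np.stack(frames), topology)


def _atom_array_from(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.asarray(coords, dtype=np.float32)
    for i, atom in enumerate(topology.atoms):
        res = topology.residues[atom.residue_index]
        array.chain_id[i] = atom.chain_id
        array.res_id[i] = res.resseq if res.resseq else atom.residue_index + 1
        array.res_name[i] = atom.residue_name
        array.atom_name[i] = atom.name
        array.element[i] = atom.element or atom.name.lstrip("0123456789")[:1]
        array.hetero[i] = False
    return array


def write_trajectory(traj: Trajectory, path: str, dialect: str = "auto") -> None:
    """Write a Trajectory as multi-model PDB or the columnar dialect.

    ``dialect`` is "pdb", "columnar", or "auto" (by file extension; .pdb is
    PDB, anything else columnar).
    """
    if dialect == "auto":
        dialect = "pdb" if str(path).lower().endswith(".pdb") else "columnar"
    if dialect == "pdb":
        stack = struc.stack(
            [_atom_array_from(traj.topology, traj.coordinates[f])
             for f in range(traj.n_frames)]
        )
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(path)
    elif dialect == "columnar":
        n_frames, n_atoms = traj.coordinates.shape[:2]
        frame_col = np.repeat(np.arange(n_frames), n_atoms)
        df = pd.DataFrame(
            {
                "frame": frame_col,
                "time": np.repeat(traj.frame_times, n_atoms),
                "atom": np.tile(np.arange(n_atoms), n_frames),
                "x": traj.coordinates[..., 0].ravel(),
                "y": traj.coordinates[..., 1].ravel(),
                "z": traj.coordinates[..., 2].ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Atom selection


def parse_selection(expr: str) -> dict:
    """Parse a textual selection like ``residues=4,5,19,20;atoms=heavy``."""
    out: dict = {}
    for part in expr.split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        key = key.strip()
        if key == "residues":
            if value.strip() == "all":
                out["residues"] = None
            else:
                out["residues"] = [int(v) for v in value.split(",") if v.strip()]
        elif key == "atoms":
            value = value.strip()
            if value == "heavy":
                out["heavy"] = True
            else:
                out["names"] = {v.strip() for v in value.split(",")}
        else:
            raise SelectionError(f"unknown selection key {key!r}")
    return out


def select_atoms(
    topology: Topology,
    residues: list[int] | None = None,
    heavy: bool = False,
    names: set[str] | None = None,
) -> np.ndarray:
    """Return a strictly increasing array of atom indices.

    ``residues`` restricts to 0-based residue indices (None = all); ``heavy``
    drops hydrogens; ``names`` restricts to an atom-name set.  An empty
    result is an error, as is a residue index out of range.
    """
    if isinstance(residues, str):
        spec = parse_selection(residues)
        return select_atoms(
            topology,
            residues=spec.get("residues"),
            heavy=spec.get("heavy", False) or heavy,
            names=spec.get("names"),
        )
    mask = np.ones(topology.n_atoms, dtype=bool)
    if residues is not None:
        for r in residues:
            if r < 0 or r >= topology.n_residues:
                raise SelectionError(
                    f"residue index {r} out of range (0..{topology.n_residues - 1})"
                )
        res_mask = np.zeros(topology.n_atoms, dtype=bool)
        for r in residues:
            res = topology.residues[r]
            res_mask[res.start : res.stop] = True
        mask &= res_mask
    if heavy:
        mask &= topology.heavy_mask()
    if names is not None:
        mask &= np.array([a.name in names for a in topology.atoms], dtype=bool)
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise SelectionError("selection matched no atoms")
    return indices


# ---------------------------------------------------------------------------
# Strand-swap symmetry


def set_symmetry(topology: Topology, chain_swap: dict[str, str]) -> Topology:
    """Attach the strand-swap permutation of a self-complementary duplex.

    ``chain_swap`` maps each chain to its partner (e.g. ``{"A": "B"}``; the
    reverse direction is implied).  The two chains must have identical
    residue sequences and per-residue atom-name multisets.  Returns a new
    Topology whose ``symmetry_perms`` is [identity, swap].
    """
    swap = dict(chain_swap)
    for a, b in list(swap.items()):
        swap.setdefault(b, a)

    by_chain: dict[str, list[Residue]] = {}
    for res in topology.residues:
        by_chain.setdefault(res.chain_id, []).append(res)

    perm = np.arange(topology.n_atoms)
    done = set()
    for chain_a, chain_b in swap.items():
        if (chain_a, chain_b) in done or (chain_b, chain_a) in done:
            continue
        done.add((chain_a, chain_b))
        res_a = by_chain.get(chain_a)
        res_b = by_chain.get(chain_b)
        if res_a is None or res_b is None:
            missing = chain_a if res_a is None else chain_b
            raise ValueError(f"chain {missing!r} not present in topology")
        if len(res_a) != len(res_b):
            raise ValueError(
                f"chains {chain_a}/{chain_b} have different lengths "
                f"({len(res_a)} vs {len(res_b)} residues)"
            )
        for ra, rb in zip(res_a, res_b):
            if ra.name != rb.name:
                raise ValueError(
                    f"sequence mismatch at residue {ra.index}: "
                    f"{ra.name} (chain {chain_a}) vs {rb.name} (chain {chain_b})"
                )
            names_a = [topology.atoms[i].name for i in range(ra.start, ra.stop)]
            names_b = {topology.atoms[i].name: i for i in range(rb.start, rb.stop)}
            if sorted(names_a) != sorted(names_b):
                extra = set(names_a) ^ set(names_b)
                raise ValueError(
                    f"atom-name mismatch between chain {chain_a} and "
                    f"{chain_b} at residue {ra.index}: {sorted(extra)}"
                )
            for i in range(ra.start, ra.stop):
                j = names_b[topology.atoms[i].name]
                perm[i] = j
                perm[j] = i

    identity = np.arange(topology.n_atoms)
    if not np.array_equal(perm[perm], identity):
        raise ValueError("strand swap is not an involution; check chain mapping")
    return Topology(topology.atoms, topology.residues, [identity, perm])
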