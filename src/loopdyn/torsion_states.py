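"""Glycosidic torsions, syn/anti classification and loop state labels.

The glycosidic torsion chi describes the orientation of the base relative to
the sugar: O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines (IUPAC
convention).  Bases near chi ~ 0/+60 deg sit over the sugar (*syn*); bases
rotated away (chi near +-180 deg) are *anti*.  A 2x2 internal loop is
summarised by one letter per loop residue, e.g. "sa/as" (strand 1 5'->3',
"/", strand 2 5'->3'); for a self-complementary duplex the label and its
strand-swapped reading describe the same structure and are canonicalised to
their lexicographic minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import Topology, Trajectory

__all__ = [
    "ChiSeries",
    "StateLabel",
    "dihedral",
    "dihedrals",
    "chi_series",
    "classify_state",
    "classify_states",
    "loop_state_label",
    "tabulate_states",
    "survey_loop_states",
    "CHI_ATOMS",
]

# chi convention atoms per base type
CHI_ATOMS = {
    "purine": ("O4'", "C1'", "N9", "C4"),
    "pyrimidine": ("O4'", "C1'", "N1", "C2"),
}

SYN_LOW = -90.0  # syn window is [-90, +90), anti otherwise
SYN_HIGH = 90.0


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is undefined (collinear points)."""


def dihedrals(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral angles in degrees, (-180, 180], vectorised.

    Input arrays broadcast over leading dimensions; the last axis is xyz.
    Sign follows the IUPAC convention (clockwise positive viewed p2->p3).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(b2n == 0) or np.any(norm1 == 0) or np.any(norm2 == 0):
        raise DegenerateGeometryError(
            "dihedral undefined: collinear or coincident points"
        )
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / b2n
    angle = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is half-open (-180, 180]
    return np.where(angle <= -180.0 + 1e-12, 180.0, angle)


def dihedral(p1, p2, p3, p4) -> float:
    """Scalar convenience wrapper around :func:`dihedrals`."""
    return float(dihedrals(p1, p2, p3, p4))


@dataclass
class ChiSeries:
    """chi torsions for selected residues across frames (degrees)."""

    values: np.ndarray  # (n_frames, n_residues)
    residue_ids: list[int]
    conventions: list[str]  # atom-quadruple tag per residue

    def to_frame(self) -> pd.DataFrame:
        n_frames = self.values.shape[0]
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_frames), len(self.residue_ids)),
                "residue": np.tile(self.residue_ids, n_frames),
                "chi_deg": self.values.ravel(),
            }
        )


def _chi_quadruple(topology: Topology, residue: int) -> tuple[int, int, int, int]:
    btype = topology.base_types[residue]
    if btype not in CHI_ATOMS:
        raise ValueError(
            f"residue {residue} ({topology.residues[residue].name}) has unknown "
            "base type; glycosidic torsion undefined"
        )
    indices = []
    for name in CHI_ATOMS[btype]:
        idx = topology.find_atom(residue, name)
        if idx is None:
            raise ValueError(
                f"residue {residue} ({topology.residues[residue].name}) is "
                f"missing chi atom {name!r}"
            )
        indices.append(idx)
    return tuple(indices)


def chi_series(traj: Trajectory, residues: list[int]) -> ChiSeries:
    """Compute chi for the given residues in every frame.

    Purines use O4'-C1'-N9-C4, pyrimidines O4'-C1'-N1-C2.  A residue missing
    one of its convention atoms raises an error naming residue and atom.
    """
    quads = [_chi_quadruple(traj.topology, r) for r in residues]
    coords = traj.coordinates
    values = np.empty((traj.n_frames, len(residues)))
    for j, (i1, i2, i3, i4) in enumerate(quads):
        values[:, j] = dihedrals(
            coords[:, i1], coords[:, i2], coords[:, i3], coords[:, i4]
        )
    conventions = [
        "-".join(CHI_ATOMS[traj.topology.base_types[r]]) for r in residues
    ]
    return ChiSeries(values, list(residues), conventions)


def classify_state(chi: float) -> str:
    """Classify a chi angle: "s" iff chi in [-90, +90), else "a"."""
    return "s" if SYN_LOW <= chi < SYN_HIGH else "a"


def classify_states(chi: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_state`."""
    chi = np.asarray(chi)
    return np.where((chi >= SYN_LOW) & (chi < SYN_HIGH), "s", "a")


@dataclass(frozen=True)
class StateLabel:
    """Canonical per-loop-residue syn/anti label, e.g. "as/sa"."""

    canonical_string: str
    raw_string: str
    symmetric: bool  # True when canonicalised over the strand swap

    def __str__(self) -> str:
        return self.canonical_string


def loop_state_label(
    states: dict[int, str],
    loop: tuple[list[int], list[int]],
    symmetry: bool = True,
) -> StateLabel:
    """Build the loop state label from per-residue letters.

    ``loop`` gives the loop residues of strand 1 and strand 2, each 5'->3'.
    With ``symmetry`` the label and its strand-swapped reading are identified
    and the lexicographic minimum returned ("a" < "s").
    """
    strand1, strand2 = loop
    for r in list(strand1) + list(strand2):
        if r not in states:
            raise ValueError(f"loop residue {r} has no syn/anti state")
    s1 = "".join(states[r] for r in strand1)
    s2 = "".join(states[r] for r in strand2)
    raw = f"{s1}/{s2}"
    if symmetry:
        swapped = f"{s2}/{s1}"
        return StateLabel(min(raw, swapped), raw, True)
    return StateLabel(raw, raw, False)


def tabulate_states(labels) -> pd.DataFrame:
    """Tabulate state labels into counts and percentages.

    Returns a DataFrame with columns state, count, percentage, sorted by
    descending count (ties by state).  Percentages sum to 100.
    """
    labels = [str(lab) for lab in labels]
    if not labels:
        raise ValueError("empty structure collection")
    series = pd.Series(labels, name="state")
    counts = series.value_counts().sort_values(ascending=False)
    df = counts.rename("count").reset_index()
    df["percentage"] = 100.0 * df["count"] / df["count"].sum()
    return df


def survey_loop_states(
    traj: Trajectory,
    loop: tuple[list[int], list[int]],
    symmetry: bool = False,
) -> pd.DataFrame:
    """Tabulate loop states across a structure collection.

    Each frame of ``traj`` is treated as an independent structure (e.g. a
    database survey of deposited loops); chi is computed, classified and
    labelled per frame, and the label frequencies tabulated.
    """
    residues = list(loop[0]) + list(loop[1])
    chis = chi_series(traj, residues)
    letters = classify_states(chis.values)
    labels = []
    for f in range(traj.n_frames):
        states = dict(zip(residues, letters[f]))
        labels.append(loop_state_label(states, loop, symmetry=symmetry))
    return tabulate_states(labels)
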