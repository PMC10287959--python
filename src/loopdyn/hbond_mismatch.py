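"""Geometric hydrogen-bond detection and C/C mismatch state classification.

A hydrogen bond is scored geometrically: heavy-atom donor-acceptor distance
d(D...A) <= 3.5 A and, when an explicit hydrogen is attached to the donor,
angle D-H...A >= 135 deg.  Topologies without hydrogens fall back to the
distance criterion alone.  For a C/C mismatch the candidate atoms are the
cytosine Watson-Crick face: N4 donates (through H41/H42 when present), N3
and O2 accept; the classifier counts inter-residue bonds per frame and
summarises the ensemble fractions of 0, 1 and >= 2 bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import Topology, Trajectory

__all__ = ["HBond", "detect_hbonds", "classify_cc_state", "CCStateSummary"]

COVALENT_H_CUTOFF = 1.3  # A; hydrogen assigned to nearest heavy atom below this


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (atom indices into the topology)."""

    donor: int
    acceptor: int
    distance: float  # heavy-atom D...A, A
    hydrogen: int | None = None
    angle: float | None = None  # D-H...A, degrees


def _attached_hydrogens(
    frame: np.ndarray, topology: Topology, donor: int
) -> list[int]:
    res = topology.atoms[donor].residue_index
    out = []
    for i in topology.residue_atoms(res):
        if topology.atoms[i].is_hydrogen:
            if np.linalg.norm(frame[i] - frame[donor]) <= COVALENT_H_CUTOFF:
                out.append(int(i))
    return out


def detect_hbonds(
    frame: np.ndarray,
    topology: Topology,
    donors: list[int],
    acceptors: list[int],
    d_max: float = 3.5,
    a_min: float = 135.0,
) -> list[HBond]:
    """All donor-acceptor pairs meeting the geometric criteria in one frame.

    Same-residue pairs are skipped.  When a donor has attached hydrogens the
    angle criterion must hold for at least one of them (the best-angle
    hydrogen is reported); donors without hydrogens are scored on distance
    alone.
    """
    if not donors or not acceptors:
        raise ValueError("donor and acceptor sets must be nonempty")
    frame = np.asarray(frame, dtype=float)
    bonds = []
    for d in donors:
        hydrogens = _attached_hydrogens(frame, topology, d)
        for a in acceptors:
            if a == d:
                continue
            if topology.atoms[a].residue_index == topology.atoms[d].residue_index:
                continue
            dist = float(np.linalg.norm(frame[a] - frame[d]))
            if dist > d_max:
                continue
            if hydrogens:
                best_h, best_angle = None, -np.inf
                for h in hydrogens:
                    v1 = frame[d] - frame[h]
                    v2 = frame[a] - frame[h]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if angle > best_angle:
                        best_h, best_angle = h, angle
                if best_angle >= a_min:
                    bonds.append(HBond(d, a, dist, best_h, best_angle))
            else:
                bonds.append(HBond(d, a, dist))
    return bonds


CYTOSINE_DONORS = ("N4",)
CYTOSINE_ACCEPTORS = ("N3", "O2")


@dataclass
class CCStateSummary:
    """Per-frame H-bond counts for one C/C mismatch and ensemble fractions."""

    counts: np.ndarray  # (n_frames,) integer bond count
    fractions: dict[str, float]  # keys "0", "1", ">=2"; sum to 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(self.counts.size), "n_hbonds": self.counts}
        )


def classify_cc_state(
    traj: Trajectory,
    mismatch: tuple[int, int],
    d_max: float = 3.5,
    a_min: float = 135.0,
) -> CCStateSummary:
    """Count base-base hydrogen bonds of a C/C mismatch in every frame.

    Both residues must be cytosines.  Donors/acceptors are restricted to the
    Watson-Crick face (N4 donor; N3, O2 acceptors) in both directions
    (i -> j and j -> i).  Fractions over {0, 1, >=2} bonds sum to 1.
    """
    topo = traj.topology
    i, j = mismatch
    for r in (i, j):
        name = topo.residues[r].name.strip().upper()
        if name not in {"C", "RC", "DC", "CYT"}:
            raise ValueError(
                f"residue {r} ({topo.residues[r].name}) is not a cytosine"
            )

    def face(residue: int, names: tuple[str, ...]) -> list[int]:
        out = []
        for n in names:
            idx = topo.find_atom(residue, n)
            if idx is not None:
                out.append(idx)
        return out

    donors = {r: face(r, CYTOSINE_DONORS) for r in (i, j)}
    acceptors = {r: face(r, CYTOSINE_ACCEPTORS) for r in (i, j)}
    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        n = 0
        for src, dst in ((i, j), (j, i)):
            if donors[src] and acceptors[dst]:
                n += len(
                    detect_hbonds(
                        frame, topo, donors[src], acceptors[dst], d_max, a_min
                    )
                )
        counts[f] = n
    fractions = {
        "0": float(np.mean(counts == 0)),
        "1": float(np.mean(counts == 1)),
        ">=2": float(np.mean(counts >= 2)),
    }
    return CCStateSummary(counts, fractions)
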