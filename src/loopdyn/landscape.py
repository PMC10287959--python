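"""2D potential-of-mean-force surfaces and basin detection.

A free-energy landscape over two collective coordinates (typically PC1 and
PC2) is obtained by Boltzmann inversion of the occupancy histogram,

    F(i, j) = -kT ln( N(i, j) / N_max ),

so the most populated bin sits at F = 0 and empty bins are masked.  Basins
are the local minima of the surface, with shallow minima merged into their
deeper neighbours when separated by less than a persistence threshold
(lowest connecting saddle minus basin minimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PMFGrid", "Basin", "pmf2d", "pmf_from_counts", "find_minima", "KB_KCAL"]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)


@dataclass
class PMFGrid:
    """Binned free-energy surface in kT units with masked empty bins."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), kT units; NaN where masked
    mask: np.ndarray  # True where the bin is empty
    counts: np.ndarray
    temperature: float = 300.0

    @property
    def kt_kcal(self) -> float:
        """kT in kcal/mol at the grid temperature."""
        return KB_KCAL * self.temperature

    def free_energy_kcal(self) -> np.ndarray:
        return self.free_energy * self.kt_kcal

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def pmf_from_counts(
    counts: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    temperature: float = 300.0,
) -> PMFGrid:
    """Boltzmann-invert an occupancy matrix into a PMF grid (kT units)."""
    counts = np.asarray(counts, dtype=float)
    mask = counts <= 0
    if mask.all():
        raise ValueError("all bins empty")
    F = np.full(counts.shape, np.nan)
    nmax = counts.max()
    with np.errstate(divide="ignore"):
        F[~mask] = -np.log(counts[~mask] / nmax)
    return PMFGrid(np.asarray(x_edges), np.asarray(y_edges), F, mask, counts,
                   temperature)


def pmf2d(
    pc1: np.ndarray,
    pc2: np.ndarray,
    nbins: int = 100,
    temperature: float = 300.0,
    value_range=None,
) -> PMFGrid:
    """PMF over two projection coordinates by histogram Boltzmann inversion.

    The minimum over occupied bins is 0 by construction (F is measured from
    the most populated bin).
    """
    pc1 = np.asarray(pc1, dtype=float).ravel()
    pc2 = np.asarray(pc2, dtype=float).ravel()
    if pc1.size != pc2.size or pc1.size == 0:
        raise ValueError("pc1 and pc2 must be equal-length and nonempty")
    counts, x_edges, y_edges = np.histogram2d(
        pc1, pc2, bins=nbins, range=value_range
    )
    return pmf_from_counts(counts, x_edges, y_edges, temperature)


@dataclass
class Basin:
    """A free-energy basin: minimum bin, depth and population share."""

    bin_index: tuple[int, int]
    free_energy: float  # kT at the minimum
    population_pct: float  # share of all counts assigned to the basin


def _neighbors(i: int, j: int, shape) -> list[tuple[int, int]]:
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                out.append((ni, nj))
    return out


def find_minima(
    grid: PMFGrid,
    depth_threshold: float = 0.5,
    min_separation: int = 1,
    min_population_pct: float = 1.0,
) -> list[Basin]:
    """Detect basins by flooding the surface in order of increasing F.

    Bins are visited from low to high free energy; a bin with no previously
    visited neighbour (8-neighbourhood) founds a basin, a bin touching one
    basin joins it, and a bin touching several is a saddle: any adjacent
    basin whose persistence (saddle F minus basin minimum F) is below
    ``depth_threshold`` kT is merged into the deepest adjacent basin.
    Masked (empty) bins are traversed last, at a ceiling level just above
    the highest observed bin, so disconnected islands still meet the rest
    of the surface and the persistence rule applies to them too.  Basins
    holding less than ``min_population_pct`` percent of all counts are
    shot noise and merge into the deepest basin (the same spirit as the
    >= 1% cluster-reporting filter).  Basins whose minima lie within
    ``min_separation`` (Chebyshev) bins are also merged.  Returns basins
    sorted by minimum F, with population shares from the occupancy
    histogram (masked bins carry no counts, so shares sum to <= 100).
    """
    F = grid.free_energy
    valid = ~grid.mask
    if not valid.any():
        raise ValueError("fully masked grid")
    ceiling = float(np.nanmax(F[valid]))
    F = np.where(valid, F, ceiling)
    order = sorted(zip(*np.nonzero(valid)), key=lambda ij: F[ij])
    order += list(zip(*np.nonzero(~valid)))

    parent: dict[int, int] = {}
    minima: dict[int, tuple[int, int]] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    assignment = np.full(F.shape, -1, dtype=int)
    for (i, j) in order:
        roots = set()
        for ni, nj in _neighbors(i, j, F.shape):
            if assignment[ni, nj] >= 0:
                roots.add(find(assignment[ni, nj]))
        if not roots:
            b = len(parent)
            parent[b] = b
            minima[b] = (i, j)
            assignment[i, j] = b
        elif len(roots) == 1:
            assignment[i, j] = next(iter(roots))
        else:
            # saddle at F[i, j]: merge shallow basins into the deepest one
            roots = sorted(roots, key=lambda b: F[minima[b]])
            deepest = roots[0]
            for b in roots[1:]:
                if F[i, j] - F[minima[b]] < depth_threshold:
                    parent[b] = deepest
            assignment[i, j] = deepest

    def survivors_by_depth() -> list[int]:
        return sorted({find(b) for b in parent}, key=lambda b: F[minima[b]])

    survivors = survivors_by_depth()

    # basins founded on masked bins are connectivity artifacts
    real = [b for b in survivors if valid[minima[b]]]
    for b in survivors:
        if not valid[minima[b]]:
            parent[b] = real[0]
    survivors = survivors_by_depth()

    # proximity merge: minima closer than min_separation bins join the deeper
    if min_separation > 0:
        for b in list(survivors):
            for d in survivors:
                if d == b or find(b) != b or find(d) != d:
                    continue
                if F[minima[d]] <= F[minima[b]]:
                    dist = max(
                        abs(minima[b][0] - minima[d][0]),
                        abs(minima[b][1] - minima[d][1]),
                    )
                    if dist <= min_separation:
                        parent[b] = d
                        break
        survivors = survivors_by_depth()

    def populations(roots: list[int]) -> dict[int, float]:
        pops = {b: 0.0 for b in roots}
        for (i, j) in order:
            pops[find(assignment[i, j])] += grid.counts[i, j]
        return pops

    # population floor: sub-threshold basins are shot noise
    total = grid.counts.sum()
    while True:
        pops = populations(survivors)
        small = [
            b for b in survivors
            if 100.0 * pops[b] / total < min_population_pct and b != survivors[0]
        ]
        if not small:
            break
        for b in small:
            parent[b] = survivors[0]
        survivors = survivors_by_depth()

    pops = populations(survivors)
    return [
        Basin(
            (int(minima[b][0]), int(minima[b][1])),
            float(F[minima[b]]),
            float(100.0 * pops[b] / total),
        )
        for b in survivors
    ]
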