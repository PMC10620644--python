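"""Markov state models on a (d, theta) grid and 2D free-energy landscapes.

Trajectory segments are discretized on a regular grid, transition counts
are collected at a lag within contiguous segments only (never across
cycle restarts or replicate boundaries), the count graph is restricted
to its largest strongly-connected component, and the stationary
distribution of the row-normalized transition matrix yields the free
energy F_i = -ln(pi_i / pi_max) in kT, zero at the global minimum.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DegeneracyError, SizeError
from .pose_geometry import ApicalCriteria, PoseGeometry, classify_apical

__all__ = [
    "GridSpec",
    "MsmModel",
    "Fel2D",
    "Minimum",
    "MinimaReport",
    "discretize",
    "count_transitions",
    "build_msm",
    "fel_from_msm",
    "find_minima_and_barrier",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular 2D binning of the (d, theta) plane.

    Bins are half-open [lo, hi) except the final bin in each dimension,
    which is closed; out-of-range samples are clipped to edge bins.
    """

    d_range: tuple[float, float] = (2.0, 10.0)
    theta_range: tuple[float, float] = (0.0, 180.0)
    n_d: int = 30
    n_theta: int = 30

    def __post_init__(self):
        if self.d_range[0] >= self.d_range[1] or self.theta_range[0] >= self.theta_range[1]:
            raise ValueError("ranges must be (lo, hi) with lo < hi")
        if self.n_d < 2 or self.n_theta < 2:
            raise ValueError("bin counts must be >= 2")

    @property
    def n_states(self) -> int:
        return self.n_d * self.n_theta

    def state_index(self, i_d, i_theta):
        return i_d * self.n_theta + i_theta

    def bin_of_state(self, state: int) -> tuple[int, int]:
        return divmod(state, self.n_theta)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        d_edges = np.linspace(*self.d_range, self.n_d + 1)
        t_edges = np.linspace(*self.theta_range, self.n_theta + 1)
        return (d_edges[:-1] + d_edges[1:]) / 2, (t_edges[:-1] + t_edges[1:]) / 2

    def center_of_state(self, state: int) -> tuple[float, float]:
        i_d, i_t = self.bin_of_state(state)
        cd, ct = self.centers()
        return float(cd[i_d]), float(ct[i_t])


def _axis_bins(x: np.ndarray, lo: float, hi: float, n: int) -> tuple[np.ndarray, int]:
    idx = np.floor((x - lo) / (hi - lo) * n).astype(int)
    clipped = int(((x < lo) | (x > hi)).sum())
    return np.clip(idx, 0, n - 1), clipped


def discretize(d, theta, grid: GridSpec) -> np.ndarray:
    """Map observable pairs to flat state indices on the grid."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.isfinite(d).all() and np.isfinite(theta).all()):
        raise ValueError("observables must be finite")
    i_d, clip_d = _axis_bins(d, *grid.d_range, grid.n_d)
    i_t, clip_t = _axis_bins(theta, *grid.theta_range, grid.n_theta)
    if clip_d or clip_t:
        warnings.warn(
            f"{clip_d + clip_t} out-of-range frame(s) clipped to edge bins",
            stacklevel=2,
        )
    return grid.state_index(i_d, i_t)


def count_transitions(
    state_series: Iterable[np.ndarray],
    lag: int,
    n_states: int,
) -> np.ndarray:
    """Sliding-window transition counts t -> t+lag within each series.

    Each element of ``state_series`` is one contiguous segment; counts
    never cross segment boundaries.  Segments shorter than ``lag + 1``
    contribute nothing (with a warning).
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    counts = np.zeros((n_states, n_states), dtype=float)
    short = 0
    for series in state_series:
        series = np.asarray(series, dtype=int)
        if len(series) <= lag:
            short += 1
            continue
        np.add.at(counts, (series[:-lag], series[lag:]), 1.0)
    if short:
        warnings.warn(f"{short} segment(s) shorter than lag+1 ignored", stacklevel=2)
    return counts


@dataclass(frozen=True)
class MsmModel:
    """Row-stochastic transition matrix over the active state set."""

    active: np.ndarray  # flat state indices, sorted
    transition_matrix: np.ndarray  # (k, k), rows sum to 1
    stationary: np.ndarray  # (k,), sums to 1
    lag: int = 0
    detailed_balance_residual: float = float("nan")

    def __post_init__(self):
        T, pi = self.transition_matrix, self.stationary
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition-matrix rows must sum to 1")
        if (pi < -1e-12).any() or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("stationary distribution must be a probability vector")
        if np.max(np.abs(pi @ T - pi)) > 1e-8:
            raise ValueError("stationary distribution is not a fixed point")


def build_msm(counts: np.ndarray, lag: int = 0) -> MsmModel:
    """Restrict to the largest strongly-connected component, row-normalize,
    and solve for the stationary distribution (leading left eigenvector)."""
    counts = np.asarray(counts, dtype=float)
    observed = np.flatnonzero(counts.sum(axis=0) + counts.sum(axis=1))
    if observed.size == 0:
        raise DegeneracyError("empty count matrix")
    sub = counts[np.ix_(observed, observed)]
    n_comp, labels = connected_components(csr_matrix(sub > 0), connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    best = int(np.argmax(sizes))
    if sizes[best] < 2:
        raise DegeneracyError("no strongly-connected component with >= 2 states")
    keep = labels == best
    active = observed[keep]
    C = sub[np.ix_(keep, keep)]
    row_sums = C.sum(axis=1)
    T = C / row_sums[:, None]
    # leading left eigenvector of T
    eigvals, eigvecs = linalg.eig(T.T)
    i = int(np.argmin(np.abs(eigvals - 1.0)))
    pi = np.real(eigvecs[:, i])
    pi = np.abs(pi)
    pi /= pi.sum()
    # polish with a few power-iteration sweeps for a clean fixed point
    for _ in range(100):
        nxt = pi @ T
        if np.max(np.abs(nxt - pi)) < 1e-14:
            pi = nxt
            break
        pi = nxt
    pi /= pi.sum()
    db = float(np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)))
    return MsmModel(
        active=active,
        transition_matrix=T,
        stationary=pi,
        lag=lag,
        detailed_balance_residual=db,
    )


@dataclass(frozen=True)
class Fel2D:
    """Free energy per bin in kT; NaN marks inactive (unvisited) bins."""

    free_energy: np.ndarray  # (n_d, n_theta)
    grid: GridSpec

    def __post_init__(self):
        active = self.free_energy[np.isfinite(self.free_energy)]
        if active.size and not np.isclose(active.min(), 0.0, atol=1e-12):
            raise ValueError("minimum active free energy must be 0")
        if active.size and (active < -1e-12).any():
            raise ValueError("free energies must be non-negative")

    @property
    def active_mask(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_frame(self) -> pd.DataFrame:
        cd, ct = self.grid.centers()
        i_d, i_t = np.nonzero(self.active_mask)
        return pd.DataFrame(
            {
                "bin_d": i_d,
                "bin_theta": i_t,
                "d_center": cd[i_d],
                "theta_center": ct[i_t],
                "F_kBT": self.free_energy[i_d, i_t],
            }
        )


def fel_from_msm(model: MsmModel, grid: GridSpec) -> Fel2D:
    """F_i = -ln(pi_i / pi_max); the most probable bin sits at 0."""
    fel = np.full((grid.n_d, grid.n_theta), np.nan)
    pi = np.maximum(model.stationary, 1e-300)
    F = -np.log(pi / pi.max())
    for state, f in zip(model.active, F):
        fel[grid.bin_of_state(int(state))] = f
    return Fel2D(free_energy=fel, grid=grid)


_NEIGHBORS = [(di, dt) for di in (-1, 0, 1) for dt in (-1, 0, 1) if (di, dt) != (0, 0)]


@dataclass(frozen=True)
class Minimum:
    bin: tuple[int, int]
    free_energy: float
    apical: bool
    barrier_to_gm: float = float("nan")


@dataclass(frozen=True)
class MinimaReport:
    gm: Minimum
    local_minima: tuple[Minimum, ...]

    def __post_init__(self):
        for lm in self.local_minima:
            if lm.free_energy < self.gm.free_energy - 1e-12:
                raise ValueError("GM must not lie above a local minimum")
            if lm.barrier_to_gm < -1e-12:
                raise ValueError("barriers must be non-negative")


def _minimax_to_gm(fel: np.ndarray, start: tuple[int, int], gm: tuple[int, int]) -> float:
    """Minimum over 8-connected paths of the maximum F along the path."""
    n_d, n_t = fel.shape
    best = np.full(fel.shape, np.inf)
    best[start] = fel[start]
    heap = [(fel[start], start)]
    while heap:
        ceil_f, (i, j) = heapq.heappop(heap)
        if (i, j) == gm:
            return float(ceil_f)
        if ceil_f > best[i, j]:
            continue
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if not (0 <= ni < n_d and 0 <= nj < n_t) or not np.isfinite(fel[ni, nj]):
                continue
            cand = max(ceil_f, fel[ni, nj])
            if cand < best[ni, nj]:
                best[ni, nj] = cand
                heapq.heappush(heap, (cand, (ni, nj)))
    return float("inf")


def find_minima_and_barrier(
    fel: Fel2D,
    apical: ApicalCriteria | None = None,
    lm_cap: float = float("inf"),
    min_barrier: float = 0.0,
) -> MinimaReport:
    """Global and local minima of the landscape plus escape barriers.

    The GM is the argmin (ties broken by lowest flat bin index).  A
    local minimum is an active bin strictly below all of its 8-connected
    active neighbors, not the GM, with F below ``lm_cap``.  The barrier
    from a local minimum to the GM is the minimax path ceiling minus the
    local minimum's F; each minimum is flagged apical when its bin
    center satisfies the apical-zone criteria.

    ``min_barrier`` filters out sampling-noise dips: a candidate whose
    escape barrier falls below it is not reported as metastable.
    """
    apical = apical or ApicalCriteria()
    F = fel.free_energy
    mask = fel.active_mask
    if not mask.any():
        raise SizeError("no active bins in the landscape")
    flat = np.where(mask, F, np.inf).ravel()
    gm_bin = tuple(int(v) for v in np.unravel_index(int(np.argmin(flat)), F.shape))

    def is_apical_bin(b):
        cd, ct = fel.grid.centers()
        geom = PoseGeometry(d_op=float(cd[b[0]]), theta_opo=float(ct[b[1]]))
        return classify_apical(geom, apical)

    gm = Minimum(bin=gm_bin, free_energy=float(F[gm_bin]), apical=is_apical_bin(gm_bin), barrier_to_gm=0.0)
    n_d, n_t = F.shape
    lms = []
    for i, j in zip(*np.nonzero(mask)):
        if (i, j) == gm_bin or F[i, j] >= lm_cap:
            continue
        below_all = True
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < n_d and 0 <= nj < n_t and mask[ni, nj] and F[ni, nj] <= F[i, j]:
                below_all = False
                break
        if not below_all:
            continue
        ceiling = _minimax_to_gm(np.where(mask, F, np.nan), (int(i), int(j)), gm_bin)
        barrier = float(ceiling - F[i, j])
        if barrier < min_barrier:
            continue
        lms.append(
            Minimum(
                bin=(int(i), int(j)),
                free_energy=float(F[i, j]),
                apical=is_apical_bin((int(i), int(j))),
                barrier_to_gm=barrier,
            )
        )
    lms.sort(key=lambda m: m.free_energy)
    return MinimaReport(gm=gm, local_minima=tuple(lms))
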