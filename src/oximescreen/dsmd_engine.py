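"""Distance-selection adaptive sampling.

The scheme repeats fixed-length simulation cycles; each new cycle
restarts from the frame of the previous cycle with the smallest value of
the selection metric (by default the ligand-target distance ``d``).
Because frame 0 of every segment reproduces the restart state's
observables, the per-cycle selected minimum is non-increasing.

A :class:`Propagator` is any callable ``(state, n_steps, seed) ->
TrajectorySegment`` returning ``n_steps + 1`` frames whose frame 0 is
the input state, deterministic for fixed ``(state, seed)``.  The toy
Langevin propagator in :mod:`oximescreen.synthetic_data` satisfies this
contract; nothing here depends on its internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import PropagationError, SizeError

__all__ = [
    "TrajectorySegment",
    "Propagator",
    "DsmdConfig",
    "CycleRecord",
    "DsmdResult",
    "select_restart",
    "run_dsmd",
    "run_plain",
    "first_passage",
]


@dataclass(frozen=True)
class TrajectorySegment:
    """Ordered frames: full states plus the (d, theta) observable pair."""

    states: np.ndarray  # (n_frames, state_dim)
    d: np.ndarray  # (n_frames,)
    theta: np.ndarray  # (n_frames,)

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if not (len(self.states) == len(self.d) == len(self.theta)):
            raise ValueError("states, d, theta must have equal length")

    def __len__(self) -> int:
        return len(self.d)

    def metric(self, name: str) -> np.ndarray:
        if name not in ("d", "theta"):
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)


class Propagator(Protocol):
    def __call__(self, state: np.ndarray, n_steps: int, seed: int) -> TrajectorySegment: ...


@dataclass(frozen=True)
class DsmdConfig:
    """Cycle structure of one adaptive-sampling run.

    Defaults mirror the campaign setup: 100 cycles of 100 frames (one
    frame per ps at the reference timestep), 3 independent replicates,
    and a 30-cycle burn-in for downstream model building.
    """

    n_cycles: int = 100
    steps_per_cycle: int = 100
    n_replicates: int = 3
    burn_in_cycles: int = 30
    master_seed: int = 0
    metric: str = "d"

    def __post_init__(self):
        for name in ("n_cycles", "steps_per_cycle", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.burn_in_cycles < 0:
            raise ValueError("burn_in_cycles must be non-negative")
        if self.burn_in_cycles >= self.n_cycles:
            raise ValueError("burn_in_cycles must be below n_cycles")


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    segment: TrajectorySegment
    selected_frame: int
    selected_metric: float


@dataclass(frozen=True)
class DsmdResult:
    """All cycles of one replicate plus the concatenated observables."""

    replicate: int
    master_seed: int
    cycles: tuple[CycleRecord, ...]

    @property
    def selected_metrics(self) -> np.ndarray:
        return np.array([c.selected_metric for c in self.cycles])

    def observable_series(self, burn_in_cycles: int = 0) -> pd.DataFrame:
        """Frames as a long table (replicate, cycle, frame, d, theta).

        ``burn_in_cycles`` drops the first cycles (cycle indices are
        1-based, so ``burn_in_cycles=30`` keeps cycles 31 onward).
        """
        chunks = []
        for rec in self.cycles:
            if rec.cycle <= burn_in_cycles:
                continue
            chunks.append(
                pd.DataFrame(
                    {
                        "replicate": self.replicate,
                        "cycle": rec.cycle,
                        "frame": np.arange(len(rec.segment)),
                        "d": rec.segment.d,
                        "theta": rec.segment.theta,
                    }
                )
            )
        if not chunks:
            return pd.DataFrame(columns=["replicate", "cycle", "frame", "d", "theta"])
        return pd.concat(chunks, ignore_index=True)

    def segments(self, burn_in_cycles: int = 0) -> list[TrajectorySegment]:
        return [rec.segment for rec in self.cycles if rec.cycle > burn_in_cycles]


def select_restart(segment: TrajectorySegment, metric: str = "d") -> tuple[int, float]:
    """Earliest frame attaining the segment's metric minimum."""
    if len(segment) == 0:
        raise SizeError("cannot select a restart from an empty segment")
    values = segment.metric(metric)
    idx = int(np.argmin(values))  # argmin returns the earliest minimum
    return idx, float(values[idx])


def cycle_seed(master_seed: int, replicate: int, cycle: int) -> int:
    """Deterministic per-(replicate, cycle) seed derivation."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate, cycle))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def run_dsmd(
    propagator: Propagator,
    initial_state: np.ndarray,
    config: DsmdConfig,
) -> list[DsmdResult]:
    """Run every replicate of the distance-selection scheme.

    Positions are inherited across restarts while stochastic degrees of
    freedom are re-seeded each cycle, so a restart never replays the
    segment it was selected from.
    """
    results = []
    for rep in range(config.n_replicates):
        state = np.asarray(initial_state, dtype=float)
        records = []
        prev_metric = np.inf
        for cyc in range(1, config.n_cycles + 1):
            seed = cycle_seed(config.master_seed, rep, cyc)
            try:
                segment = propagator(state, config.steps_per_cycle, seed)
            except Exception as exc:  # propagator contract violation or failure
                raise PropagationError(cyc, f"cycle {cyc} (replicate {rep}): {exc}") from exc
            if len(segment) != config.steps_per_cycle + 1:
                raise PropagationError(
                    cyc,
                    f"propagator returned {len(segment)} frames, "
                    f"expected {config.steps_per_cycle + 1}",
                )
            frame, metric = select_restart(segment, config.metric)
            if metric > prev_metric + 1e-12:
                raise PropagationError(
                    cyc,
                    "selection metric increased across cycles; the propagator "
                    "does not reproduce the restart state at frame 0",
                )
            records.append(
                CycleRecord(cycle=cyc, segment=segment, selected_frame=frame, selected_metric=metric)
            )
            state = segment.states[frame]
            prev_metric = metric
        results.append(
            DsmdResult(replicate=rep, master_seed=config.master_seed, cycles=tuple(records))
        )
    return results


def run_plain(
    propagator: Propagator,
    initial_state: np.ndarray,
    total_steps: int,
    seed: int,
) -> TrajectorySegment:
    """A single uninterrupted trajectory (length-matched baseline)."""
    if total_steps < 1:
        raise SizeError("total_steps must be positive")
    try:
        return propagator(np.asarray(initial_state, dtype=float), total_steps, seed)
    except Exception as exc:
        raise PropagationError(0, str(exc)) from exc


def first_passage(
    d: np.ndarray,
    theta: np.ndarray,
    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> float:
    """Index of the first frame satisfying ``predicate`` (vectorized), or inf."""
    hits = np.flatnonzero(predicate(np.asarray(d), np.asarray(theta)))
    return float(hits[0]) if hits.size else float("inf")
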