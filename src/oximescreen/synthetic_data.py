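"""Synthetic fixtures with machine-readable ground truth.

Everything the pipeline consumes can be generated here: toy
ligand-approach dynamics on the (d, theta) plane, energy tables with
known threshold-pass counts, pose sets with known apical fractions, and
interaction matrices with known consensus sets.  kT is fixed to 1 so all
toy energies are natively in units of kT.

The two-basin scenario mimics the qualitative contrast seen in the
campaign: a deeper "side" basin near (4.4 A, 90 deg) and a shallower
"apical" basin near (3.5 A, 160 deg), with the inter-basin saddle
calibrated to a requested height above the apical minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dsmd_engine import Propagator, TrajectorySegment
from .errors import CalibrationError, GenerationError
from .pose_geometry import ApicalCriteria

__all__ = [
    "BasinSpec",
    "ToyPotential",
    "LangevinParams",
    "make_potential",
    "langevin_propagator",
    "make_energy_table",
    "make_pose_set",
    "make_interaction_matrix",
    "SIDE_CENTER",
    "APICAL_CENTER",
]

SIDE_CENTER = (4.4, 90.0)
APICAL_CENTER = (3.5, 160.0)
SIDE_WIDTHS = (0.5, 18.0)
APICAL_WIDTHS = (0.4, 14.0)

# reflecting walls for the calibrated scenarios: a bounded accessible
# region keeps a clip-free analysis grid well sampled everywhere
SCENARIO_D_WALLS = (2.0, 6.5)


@dataclass(frozen=True)
class BasinSpec:
    """One Gaussian well on the (d, theta) plane."""

    center: tuple[float, float]  # (d A, theta deg)
    depth: float  # kT
    widths: tuple[float, float]  # (sigma_d A, sigma_theta deg)

    def __post_init__(self):
        if self.depth <= 0:
            raise CalibrationError(f"basin depth must be positive, got {self.depth}")
        if min(self.widths) <= 0:
            raise CalibrationError(f"basin widths must be positive, got {self.widths}")


@dataclass(frozen=True)
class ToyPotential:
    """Gaussian wells plus a one-sided repulsive inner wall, smooth and
    bounded below.

    U(d, t) = -sum_k depth_k * exp(-[(d-c_d)^2/(2 s_d^2) + (t-c_t)^2/(2 s_t^2)])
              + k_rep * max(0, d0_rep - d)^2

    The quadratic repulsion below ``d0_rep`` mimics the steric floor of a
    real approach distance, so a minimum-distance selection ratchet meets
    a restoring force instead of piling up on the box edge.
    ``d_walls``/``theta_walls`` are reflecting boundaries for the
    propagator; the potential itself is defined everywhere.
    """

    basins: tuple[BasinSpec, ...]
    d_walls: tuple[float, float] = (2.0, 10.0)
    theta_walls: tuple[float, float] = (0.0, 180.0)
    d0_rep: float = 2.8
    k_rep: float = 10.0

    def energy(self, d, theta):
        d = np.asarray(d, dtype=float)
        theta = np.asarray(theta, dtype=float)
        u = np.zeros(np.broadcast(d, theta).shape)
        for b in self.basins:
            u -= b.depth * np.exp(
                -((d - b.center[0]) ** 2 / (2 * b.widths[0] ** 2)
                  + (theta - b.center[1]) ** 2 / (2 * b.widths[1] ** 2))
            )
        u = u + self.k_rep * np.maximum(0.0, self.d0_rep - d) ** 2
        return u if u.shape else float(u)

    def gradient(self, d: float, theta: float) -> tuple[float, float]:
        gd = gt = 0.0
        for b in self.basins:
            dx = d - b.center[0]
            dy = theta - b.center[1]
            g = b.depth * math.exp(
                -(dx * dx / (2 * b.widths[0] ** 2) + dy * dy / (2 * b.widths[1] ** 2))
            )
            gd += g * dx / b.widths[0] ** 2
            gt += g * dy / b.widths[1] ** 2
        if d < self.d0_rep:
            gd -= 2.0 * self.k_rep * (self.d0_rep - d)
        return gd, gt

    def max_curvature(self) -> tuple[float, float]:
        """Upper bound on |d2U/dx2| per coordinate (basin centers / wall)."""
        cd = max(b.depth / b.widths[0] ** 2 for b in self.basins)
        ct = max(b.depth / b.widths[1] ** 2 for b in self.basins)
        return max(cd, 2.0 * self.k_rep), ct

    def local_minimum(self, guess: tuple[float, float]) -> tuple[float, float]:
        res = optimize.minimize(lambda x: self.energy(x[0], x[1]), np.asarray(guess))
        return float(res.x[0]), float(res.x[1])


def _line_saddle(pot: ToyPotential, a: tuple[float, float], b: tuple[float, float]) -> float:
    """Max energy along the straight segment between two points (1D search)."""
    t = np.linspace(0.0, 1.0, 2001)
    d = a[0] + t * (b[0] - a[0])
    th = a[1] + t * (b[1] - a[1])
    u = pot.energy(d, th)
    i = int(np.argmax(u))
    lo, hi = max(t[i] - 1e-3, 0.0), min(t[i] + 1e-3, 1.0)
    res = optimize.minimize_scalar(
        lambda s: -pot.energy(a[0] + s * (b[0] - a[0]), a[1] + s * (b[1] - a[1])),
        bounds=(lo, hi),
        method="bounded",
    )
    return float(-res.fun)


def make_potential(
    scenario: str,
    barrier_kbt: float = 5.0,
    side_excess: float = 2.0,
) -> ToyPotential:
    """Build a calibrated toy potential.

    ``two_basin_side_GM``: the side basin is deeper than the apical one
    by ``side_excess`` kT, and the apical depth is solved so that the
    inter-basin saddle sits ``barrier_kbt`` above the apical minimum
    (1D line-search along the inter-basin path).

    ``single_basin_apical``: one apical well of depth ``barrier_kbt``.
    """
    if barrier_kbt <= 0:
        raise CalibrationError(f"barrier must be positive, got {barrier_kbt}")
    if scenario == "single_basin_apical":
        return ToyPotential(
            basins=(BasinSpec(APICAL_CENTER, barrier_kbt, APICAL_WIDTHS),),
            d_walls=SCENARIO_D_WALLS,
        )
    if scenario != "two_basin_side_GM":
        raise ValueError(f"unknown scenario {scenario!r}")

    def residual(apical_depth: float) -> float:
        pot = ToyPotential(
            basins=(
                BasinSpec(SIDE_CENTER, apical_depth + side_excess, SIDE_WIDTHS),
                BasinSpec(APICAL_CENTER, apical_depth, APICAL_WIDTHS),
            )
        )
        apical_min = pot.local_minimum(APICAL_CENTER)
        side_min = pot.local_minimum(SIDE_CENTER)
        saddle = _line_saddle(pot, apical_min, side_min)
        return (saddle - pot.energy(*apical_min)) - barrier_kbt

    try:
        depth = optimize.brentq(residual, 0.05, barrier_kbt + 10.0, xtol=1e-10)
    except ValueError as exc:
        raise CalibrationError(f"cannot calibrate barrier {barrier_kbt} kT: {exc}") from exc
    return ToyPotential(
        basins=(
            BasinSpec(SIDE_CENTER, depth + side_excess, SIDE_WIDTHS),
            BasinSpec(APICAL_CENTER, depth, APICAL_WIDTHS),
        ),
        d_walls=SCENARIO_D_WALLS,
    )


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped Euler-Maruyama parameters.

    ``gamma`` may be a scalar or a per-coordinate (gamma_d, gamma_theta)
    pair; the angular friction default compensates for the degree scale
    of theta so both coordinates diffuse at comparable rates relative to
    their basin widths.
    """

    dt: float = 0.002
    gamma: float | tuple[float, float] = (1.0, 7.7e-4)
    kT: float = 1.0

    def __post_init__(self):
        g = self.gamma if isinstance(self.gamma, tuple) else (self.gamma, self.gamma)
        if self.dt <= 0 or min(g) <= 0:
            raise ValueError("dt and gamma must be positive")
        object.__setattr__(self, "gamma", (float(g[0]), float(g[1])))

    def check_stability(self, potential: ToyPotential, limit: float = 0.1) -> None:
        """Require dt * max-curvature / gamma < limit per coordinate."""
        for curv, g, name in zip(potential.max_curvature(), self.gamma, ("d", "theta")):
            if self.dt * curv / g >= limit:
                raise ValueError(
                    f"unstable integration in {name}: dt*curvature/gamma = "
                    f"{self.dt * curv / g:.3g} >= {limit}"
                )


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold back into [lo, hi]; steps are far smaller than the box
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return x


def langevin_propagator(
    potential: ToyPotential,
    params: LangevinParams | None = None,
) -> Propagator:
    """Toy MD engine satisfying the Propagator contract.

    x_{t+1} = x_t - grad U(x_t) * dt/gamma + sqrt(2 kT dt / gamma) * xi_t
    with reflection at the d and theta walls.  Frame 0 is the input
    state; fixed (state, seed) gives a bit-identical segment.
    """
    params = params or LangevinParams()
    params.check_stability(potential)
    gd, gt = params.gamma
    drift_d = params.dt / gd
    drift_t = params.dt / gt
    noise_d = math.sqrt(2.0 * params.kT * params.dt / gd)
    noise_t = math.sqrt(2.0 * params.kT * params.dt / gt)
    d_lo, d_hi = potential.d_walls
    t_lo, t_hi = potential.theta_walls

    def propagate(state: np.ndarray, n_steps: int, seed: int) -> TrajectorySegment:
        rng = np.random.default_rng(seed)
        xi = rng.standard_normal((n_steps, 2))
        out = np.empty((n_steps + 1, 2))
        d, th = float(state[0]), float(state[1])
        out[0] = (d, th)
        for i in range(n_steps):
            fd, ft = potential.gradient(d, th)
            d = d - fd * drift_d + noise_d * xi[i, 0]
            th = th - ft * drift_t + noise_t * xi[i, 1]
            d = _reflect(d, d_lo, d_hi)
            th = _reflect(th, t_lo, t_hi)
            out[i + 1] = (d, th)
        return TrajectorySegment(states=out, d=out[:, 0], theta=out[:, 1])

    return propagate


# ---------------------------------------------------------------------------
# tabular fixture generators


def make_energy_table(
    n: int,
    n_negative_mp2: int,
    n_below_b3lyp_cut: int,
    seed: int,
    b3lyp_cut: float = -15.0,
    ref_code: str = "2-PAM",
) -> pd.DataFrame:
    """Energy table with exact threshold-pass counts plus a reference row.

    Exactly ``n_negative_mp2`` analog rows have ``d_mp2 < 0`` and exactly
    ``n_below_b3lyp_cut`` have ``d_b3lyp <= b3lyp_cut``.
    """
    if not 0 <= n_negative_mp2 <= n or not 0 <= n_below_b3lyp_cut <= n:
        raise GenerationError(
            f"counts ({n_negative_mp2}, {n_below_b3lyp_cut}) must lie in [0, {n}]"
        )
    rng = np.random.default_rng(seed)
    codes = [f"A{i:02d}" for i in range(1, n + 1)]
    d_mp2 = np.concatenate(
        [rng.uniform(-45.0, -1.0, n_negative_mp2), rng.uniform(1.0, 30.0, n - n_negative_mp2)]
    )
    d_b3lyp = np.concatenate(
        [
            rng.uniform(b3lyp_cut - 25.0, b3lyp_cut, n_below_b3lyp_cut),
            rng.uniform(b3lyp_cut + 1.0, 25.0, n - n_below_b3lyp_cut),
        ]
    )
    rng.shuffle(d_mp2)
    rng.shuffle(d_b3lyp)
    table = pd.DataFrame(
        {
            "code": codes,
            "e_oniom2": rng.uniform(-4800.0, -4300.0, n).round(2),
            "d_b3lyp": d_b3lyp.round(2),
            "d_mp2": d_mp2.round(2),
            "d_op": rng.uniform(2.8, 3.8, n).round(2),
        }
    )
    ref = pd.DataFrame(
        {
            "code": [ref_code],
            "e_oniom2": [round(float(rng.uniform(-4400.0, -4200.0)), 2)],
            "d_b3lyp": [0.0],
            "d_mp2": [0.0],
            "d_op": [round(float(rng.uniform(4.0, 4.8)), 2)],
        }
    )
    return pd.concat([table, ref], ignore_index=True)


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element):
    # fixed-column PDB ATOM record (altLoc col 17 blank, resname 18-20)
    return (
        f"ATOM  {serial:>5} {name:<4} {resname:>3} {chain}{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2}\n"
    )


def _random_rigid_transform(rng):
    # uniform rotation via QR of a Gaussian matrix, plus a random shift
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.uniform(-20.0, 20.0, 3)
    return q, shift


def make_pose_set(
    n: int,
    n_apical: int,
    criteria: ApicalCriteria | None = None,
    seed: int = 0,
    out_dir=None,
) -> tuple[list[Path], pd.DataFrame]:
    """Write ``n`` single-pose PDB files, ``n_apical`` of them apical.

    Geometry is sampled with a safety margin (>= 0.05 A / 1 deg) from
    every threshold so the 3-decimal PDB round-trip cannot flip a label.
    Returns the file paths and a truth table (pose_id, d_op, theta_opo,
    apical).
    """
    if n_apical > n:
        raise GenerationError(f"n_apical ({n_apical}) exceeds n ({n})")
    criteria = criteria or ApicalCriteria()
    out_dir = Path(out_dir or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    paths = []
    for i in range(n):
        apical = i < n_apical
        if apical:
            d = rng.uniform(2.5, criteria.d_max - 0.5)
            theta = rng.uniform(criteria.theta_min + 5.0, criteria.theta_max - 1.0)
        elif rng.random() < 0.5:  # fail on distance
            d = rng.uniform(criteria.d_max, criteria.d_max + 4.0)
            theta = rng.uniform(criteria.theta_min + 5.0, criteria.theta_max - 1.0)
        else:  # fail on angle
            d = rng.uniform(2.5, criteria.d_max - 0.5)
            theta = rng.uniform(5.0, criteria.theta_min - 5.0)
        # place P at origin, serine O along +x, oxime O at the sampled angle
        p = np.zeros(3)
        o_ser = np.array([3.0, 0.0, 0.0])
        ang = math.radians(theta)
        o_oxime = np.array([d * math.cos(ang), d * math.sin(ang), 0.0])
        rot, shift = _random_rigid_transform(rng)
        p, o_ser, o_oxime = (rot @ v + shift for v in (p, o_ser, o_oxime))
        pose_id = f"pose_{i:03d}"
        path = out_dir / f"{pose_id}.pdb"
        with open(path, "w") as fh:
            fh.write(_pdb_atom_line(1, "O1", "LIG", "A", 1, o_oxime, "O"))
            fh.write(_pdb_atom_line(2, "P", "POX", "A", 2, p, "P"))
            fh.write(_pdb_atom_line(3, "OG", "SER", "A", 3, o_ser, "O"))
            fh.write("END\n")
        paths.append(path)
        rows.append({"pose_id": pose_id, "d_op": d, "theta_opo": theta, "apical": apical})
    return paths, pd.DataFrame(rows)


def make_interaction_matrix(
    analogs: Sequence[str],
    residues: Sequence[str],
    consensus_set: Sequence[str],
    fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Boolean interaction matrix whose >= ``fraction`` consensus set is
    exactly ``consensus_set`` by construction."""
    analogs = list(analogs)
    residues = list(residues)
    consensus = set(consensus_set)
    if not consensus <= set(residues):
        raise GenerationError("consensus_set must be a subset of residues")
    n = len(analogs)
    if n == 0:
        raise GenerationError("need at least one analog row")
    need_min = math.ceil(fraction * n)
    max_other = need_min - 1
    rng = np.random.default_rng(seed)
    matrix = pd.DataFrame(False, index=analogs, columns=residues)
    for res in residues:
        if res in consensus:
            count = int(rng.integers(need_min, n + 1))
        else:
            count = int(rng.integers(0, max_other + 1))
        which = rng.choice(n, size=count, replace=False)
        matrix.iloc[which, matrix.columns.get_loc(res)] = True
    return matrix
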