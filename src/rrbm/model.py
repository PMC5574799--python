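"""Refined resource budget model (RRBM) of mast seeding.

A perennial plant banks an annual photosynthetic surplus ``Ps`` in storage
and spends it on reproduction once reserves cross a threshold.  The classic
resource budget model has a single flowering threshold; the refined model
adds a second, lower threshold for asexual (clonal) reproduction, splitting
each year into one of three regimes depending on the pre-reproduction pool
``y(t) + Ps``:

* **RA** (resource accumulation): pool below the asexual threshold ``L1`` —
  nothing is spent, the whole surplus is banked.
* **AR** (asexual reproduction): pool between ``L1`` and the sexual
  threshold ``L2`` — a fraction ``d`` of the excess over ``L1`` goes to
  clonal reproduction.
* **SAR** (sexual + asexual reproduction): pool above ``L2`` — fractions
  ``p`` (flowering) and ``q`` (clonal) of the excess are spent, and seed
  set costs ``R`` times the flowering cost, so the total outlay is
  ``(p + q + R*p) * (y + Ps - L1)``.

The map is piecewise linear, so its two candidate equilibria, their
existence conditions, and their Lyapunov exponents have closed forms; the
module computes those alongside trajectory simulation and a phase-diagram
sweep that tiles (p, q) space with integer reproductive-period codes.

Everything is deterministic double-precision arithmetic; there is no
randomness anywhere in the model itself.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "Branch",
    "DivergenceError",
    "FixedPointReport",
    "ModelParams",
    "PeriodCode",
    "PhaseDiagram",
    "RegimeReport",
    "Scenario",
    "SCENARIOS",
    "Trajectory",
    "YearRecord",
    "analyze",
    "asexual_fixed_point",
    "classify_branch",
    "classify_regime",
    "default_y0",
    "load_config",
    "lyapunov_numeric",
    "midpoint_grid",
    "period_code",
    "read_trajectory_csv",
    "resolve",
    "sexual_fixed_point",
    "simulate",
    "step",
    "sweep",
    "write_trajectory_csv",
]

# --------------------------------------------------------------------------
# Configuration defaults and logging
# --------------------------------------------------------------------------

#: Absolute reserve magnitude beyond which a trajectory is declared divergent.
DIVERGENCE_GUARD = 1e12

#: Default years discarded before long-run statistics are taken.  Long
#: enough that the slowest stable contractions sampled by the default
#: 51-point sweep grids (branch slopes up to ~0.98 in magnitude) decay
#: below the default constancy tolerance from O(1) displacements.
DEFAULT_BURN_IN = 2000

#: Default length of the post-burn-in analysis window (years).
DEFAULT_WINDOW = 2000

#: Default simulation horizon for plain trajectory runs.
DEFAULT_YEARS = 2000

#: Absolute tolerance on reserves when deciding whether an orbit is constant.
DEFAULT_TOL = 1e-9

#: Width within which a governing inequality counts as an exact boundary.
BOUNDARY_TOL = 1e-12

#: Longest reproductive period reported as its own code; anything longer or
#: irregular collapses into LONG_OR_IRREGULAR.
MAX_PERIOD = 18
LONG_OR_IRREGULAR = 19

#: Sentinel period codes outside the -1..19 convention.
DIVERGED_CODE = -9   # the orbit tripped the divergence guard
EXCLUDED_CODE = -2   # cell excluded from a simplex-restricted sweep

logger = logging.getLogger("rrbm")


def default_y0(params: "ModelParams") -> float:
    """Default initial reserve: half the asexual threshold.

    The plant starts mid-accumulation, strictly below any reproductive
    threshold.  A zero initial reserve is avoided because it makes the
    year-0 pool exactly ``Ps``, which coincides with a threshold for
    integer-valued parameter sets (e.g. ``L2 == Ps``); the inclusive
    boundary rule then routes year 0 through the asexual branch, and in a
    multistable region that measure-zero coincidence selects a
    non-representative attractor.
    """
    return params.L1 / 2.0


class DivergenceError(RuntimeError):
    """Raised when |reserve| exceeds the divergence guard.

    Attributes
    ----------
    year : int or None
        Simulation year at which the guard tripped, when known.
    """

    def __init__(self, message: str, year: int | None = None):
        super().__init__(message)
        self.year = year


# --------------------------------------------------------------------------
# Parameters and the annual map
# --------------------------------------------------------------------------

class Branch(str, enum.Enum):
    """The three annual regimes of the map."""

    RA = "RA"    # resource accumulation only
    AR = "AR"    # asexual reproduction only
    SAR = "SAR"  # sexual and asexual reproduction

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass(frozen=True)
class ModelParams:
    """The seven scalars of the refined resource budget model.

    Parameters
    ----------
    L1 : float
        Asexual-reproduction threshold (resource units).
    L2 : float
        Sexual-reproduction threshold (resource units); must exceed ``L1``.
    Ps : float
        Annual surplus remaining after growth and maintenance
        (resource units per year).
    p : float
        Flowering coefficient: fraction of the pool excess over ``L1``
        spent on flowers in an SAR year.
    q : float
        Asexual coefficient: fraction of the excess spent clonally in an
        SAR year.
    d : float
        Depletion fraction of the excess in an AR (asexual-only) year.
    R : float
        Depletion coefficient: ratio of seed-set cost to flowering cost.
    reduction : bool
        Classic single-threshold mode.  Relaxes the invariants to allow
        ``L1 == L2``, ``p == 1`` and ``q == 0`` so the map collapses to the
        original resource budget model update
        ``y + Ps - (1 + R) * (y + Ps - L)``.

    ``p + q`` may exceed 1 (the two coefficients vary independently); when
    the total SAR allocation ``p + q + R*p`` exceeds 1 the plant overdraws
    its reserve in reproduction years and a warning is logged.
    """

    L1: float
    L2: float
    Ps: float
    p: float
    q: float
    d: float
    R: float
    reduction: bool = False

    def __post_init__(self):
        for name in ("L1", "L2", "Ps", "p", "q", "d", "R"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        if self.reduction:
            if not self.L1 <= self.L2:
                raise ValueError("invariant L1 <= L2 violated "
                                 f"(L1={self.L1}, L2={self.L2})")
            if not 0 < self.p <= 1:
                raise ValueError(f"invariant 0 < p <= 1 violated (p={self.p})")
            if not 0 <= self.q < 1:
                raise ValueError(f"invariant 0 <= q < 1 violated (q={self.q})")
        else:
            if not self.L1 < self.L2:
                raise ValueError("invariant L1 < L2 violated "
                                 f"(L1={self.L1}, L2={self.L2})")
            if not 0 < self.p < 1:
                raise ValueError(f"invariant 0 < p < 1 violated (p={self.p})")
            if not 0 < self.q < 1:
                raise ValueError(f"invariant 0 < q < 1 violated (q={self.q})")
        if not self.Ps > 0:
            raise ValueError(f"invariant Ps > 0 violated (Ps={self.Ps})")
        if not 0 < self.d < 1:
            raise ValueError(f"invariant 0 < d < 1 violated (d={self.d})")
        if not self.R > 0:
            raise ValueError(f"invariant R > 0 violated (R={self.R})")
        if self.sar_allocation > 1:
            logger.warning(
                "total SAR allocation p + q + R*p = %.6g exceeds 1: "
                "reproduction years overdraw the reserve", self.sar_allocation)

    @property
    def sar_allocation(self) -> float:
        """Total SAR spending fraction ``p + q + R*p`` of the pool excess."""
        return self.p + self.q + self.R * self.p

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("L1", "L2", "Ps", "p", "q", "d", "R")}


@dataclass(frozen=True)
class YearRecord:
    """One year's transition with full cost accounting.

    ``y_next == y_start + Ps - (C_f + C_a + C_v)`` up to one rounding ulp;
    costs are zero outside the branch that incurs them.
    """

    t: int
    y_start: float
    pool: float
    branch: Branch
    C_f: float
    C_a: float
    C_v: float
    y_next: float


def classify_branch(y: float, params: ModelParams) -> Branch:
    """Classify the branch taken in a year starting with reserve ``y``.

    The pool ``y + Ps`` is compared with the two thresholds; both boundary
    equalities fall into the middle (AR) branch, where the cost vanishes at
    the lower boundary anyway.
    """
    if not math.isfinite(y):
        raise ValueError(f"non-finite reserve y={y!r}: corrupt state")
    pool = y + params.Ps
    if pool < params.L1:
        return Branch.RA
    if pool <= params.L2:
        return Branch.AR
    return Branch.SAR


def step(y: float, params: ModelParams, t: int = 0,
         guard: float = DIVERGENCE_GUARD) -> YearRecord:
    """Advance the reserve by one year.

    Returns a :class:`YearRecord`; reserves are never clamped at zero, so a
    costly SAR year may leave the plant overdrawn (negative reserve).  The
    SAR update is evaluated in the closed form
    ``pool - (p + q + R*p) * (pool - L1)`` so that the single-threshold
    reduction (``p=1, q=0, L1=L2``) reproduces the classic resource budget
    update bit for bit; the three recorded costs are computed separately.
    """
    branch = classify_branch(y, params)
    pool = y + params.Ps
    cf = ca = cv = 0.0
    if branch is Branch.RA:
        y_next = pool
    elif branch is Branch.AR:
        excess = pool - params.L1
        cv = params.d * excess
        y_next = pool - cv
    else:
        excess = pool - params.L1
        cf = params.p * excess
        ca = params.R * cf
        cv = params.q * excess
        y_next = pool - params.sar_allocation * excess
    if abs(y_next) > guard:
        raise DivergenceError(
            f"reserve diverged: |y|={abs(y_next):.3g} > {guard:.3g} at year {t}",
            year=t)
    return YearRecord(t=t, y_start=y, pool=pool, branch=branch,
                      C_f=cf, C_a=ca, C_v=cv, y_next=y_next)


@dataclass(frozen=True)
class Trajectory:
    """An iterated orbit of the annual map with per-year cost accounting."""

    params: ModelParams
    y0: float
    records: tuple[YearRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def y_series(self) -> np.ndarray:
        """Start-of-year reserves, length ``len(self) + 1`` (includes final)."""
        ys = [r.y_start for r in self.records]
        ys.append(self.records[-1].y_next)
        return np.asarray(ys)

    @property
    def branches(self) -> list[Branch]:
        return [r.branch for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": [r.t for r in self.records],
                "y_start": [r.y_start for r in self.records],
                "pool": [r.pool for r in self.records],
                "branch": [str(r.branch) for r in self.records],
                "C_f": [r.C_f for r in self.records],
                "C_a": [r.C_a for r in self.records],
                "C_v": [r.C_v for r in self.records],
                "y_next": [r.y_next for r in self.records],
            }
        )


def simulate(params: ModelParams, y0: float | None = None,
             years: int = DEFAULT_YEARS,
             guard: float = DIVERGENCE_GUARD) -> Trajectory:
    """Iterate the annual map ``years`` times from reserve ``y0``.

    ``y0`` defaults to :func:`default_y0` (half the asexual threshold).
    Deterministic: identical inputs give bit-identical trajectories.  A
    reserve magnitude beyond ``guard`` raises :class:`DivergenceError`
    carrying the offending year.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if y0 is None:
        y0 = default_y0(params)
    if not math.isfinite(y0):
        raise ValueError(f"non-finite initial reserve y0={y0!r}")
    records = []
    y = float(y0)
    for t in range(years):
        rec = step(y, params, t=t, guard=guard)
        records.append(rec)
        y = rec.y_next
    return Trajectory(params=params, y0=float(y0), records=tuple(records))


def _iterate(params: ModelParams, y0: float, burn_in: int, window: int,
             guard: float = DIVERGENCE_GUARD) -> tuple[np.ndarray, np.ndarray]:
    """Fast record-free iteration.

    Returns ``(y_window, branch_window)`` where ``y_window[t]`` is the
    start-of-year reserve and ``branch_window[t]`` is 0/1/2 for RA/AR/SAR,
    for the ``window`` years after ``burn_in``.  Arithmetic is ordered
    identically to :func:`step`, so the orbit is bit-identical.
    """
    L1, L2, Ps, d = params.L1, params.L2, params.Ps, params.d
    s = params.sar_allocation
    y = float(y0)
    for t in range(burn_in):
        pool = y + Ps
        if pool < L1:
            y = pool
        elif pool <= L2:
            y = pool - d * (pool - L1)
        else:
            y = pool - s * (pool - L1)
        if not (-guard <= y <= guard):
            raise DivergenceError(
                f"reserve diverged: |y|={abs(y):.3g} > {guard:.3g} at year {t}",
                year=t)
    ys = np.empty(window)
    br = np.empty(window, dtype=np.int8)
    for t in range(window):
        ys[t] = y
        pool = y + Ps
        if pool < L1:
            br[t] = 0
            y = pool
        elif pool <= L2:
            br[t] = 1
            y = pool - d * (pool - L1)
        else:
            br[t] = 2
            y = pool - s * (pool - L1)
        if not (-guard <= y <= guard):
            raise DivergenceError(
                f"reserve diverged: |y|={abs(y):.3g} > {guard:.3g} "
                f"at year {burn_in + t}", year=burn_in + t)
    return ys, br


# --------------------------------------------------------------------------
# Trajectory serialization
# --------------------------------------------------------------------------

_CSV_COLUMNS = ("t", "y_start", "pool", "branch", "C_f", "C_a", "C_v", "y_next")


def _g17(x: float) -> str:
    # 17 significant digits round-trip any IEEE double
    return format(x, ".17g")


def write_trajectory_csv(traj: Trajectory, dest: str | Path | TextIO) -> None:
    """Write a trajectory as CSV with round-trippable float serialization."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="") as fh:
            write_trajectory_csv(traj, fh)
        return
    dest.write(",".join(_CSV_COLUMNS) + "\n")
    for r in traj.records:
        dest.write(
            f"{r.t},{_g17(r.y_start)},{_g17(r.pool)},{r.branch},"
            f"{_g17(r.C_f)},{_g17(r.C_a)},{_g17(r.C_v)},{_g17(r.y_next)}\n")


def read_trajectory_csv(src: str | Path | TextIO) -> pd.DataFrame:
    """Read a trajectory CSV back into a DataFrame (floats parsed exactly)."""
    df = pd.read_csv(src, float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# Equilibrium analysis: closed-form fixed points, stability, regimes
# --------------------------------------------------------------------------

def _stability(lam: float) -> str:
    if abs(lam) <= BOUNDARY_TOL:
        return "marginal"
    return "stable" if lam < 0 else "unstable"


@dataclass(frozen=True)
class FixedPointReport:
    """One candidate equilibrium of the map.

    ``value`` is the branch's algebraic fixed point (reported even when the
    existence condition fails, for inspection); ``exists`` says whether the
    point actually lies on its branch.  ``lyapunov`` is the analytic
    exponent ln|slope| of the branch, in nats per year.
    """

    which: str                 # "asexual_branch" or "sexual_branch"
    value: float
    exists: bool
    stable: str                # "stable" | "unstable" | "marginal"
    lyapunov: float
    condition_lhs: float       # Ps
    condition_rhs: float       # the existence bound Ps is compared against

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def asexual_fixed_point(params: ModelParams) -> FixedPointReport:
    """Equilibrium of the asexual-only (AR) branch.

    ``y2* = L1 + Ps/d - Ps``; it lies inside the AR band iff
    ``Ps < (L2 - L1) * d`` (strict; equality within 1e-12 counts as a
    boundary and reports non-existence).  Its Lyapunov exponent
    ``ln|1 - d|`` is negative for any valid ``d``, so the point is stable
    whenever it exists.
    """
    value = params.L1 + params.Ps / params.d - params.Ps
    bound = (params.L2 - params.L1) * params.d
    exists = params.Ps < bound - BOUNDARY_TOL
    lam = math.log(abs(1.0 - params.d))
    return FixedPointReport(
        which="asexual_branch", value=value, exists=exists,
        stable=_stability(lam), lyapunov=lam,
        condition_lhs=params.Ps, condition_rhs=bound)


def sexual_fixed_point(params: ModelParams) -> FixedPointReport:
    """Equilibrium of the sexual-plus-asexual (SAR) branch.

    ``y1* = L1 - Ps + Ps / (p + q + R*p)``; it lies above the sexual
    threshold iff ``Ps > (p + q + R*p) * (L2 - L1)`` (strict).  The branch
    slope is ``1 - (p + q + R*p)``, so ``lyapunov = ln|1 - p - q - R*p|``
    and the point is stable exactly when ``R*p < 2 - p - q``.
    """
    s = params.sar_allocation
    value = params.L1 - params.Ps + params.Ps / s
    bound = s * (params.L2 - params.L1)
    exists = params.Ps > bound + BOUNDARY_TOL
    slope = abs(1.0 - s)
    lam = math.log(slope) if slope > 0 else -math.inf
    return FixedPointReport(
        which="sexual_branch", value=value, exists=exists,
        stable=_stability(lam), lyapunov=lam,
        condition_lhs=params.Ps, condition_rhs=bound)


@dataclass(frozen=True)
class RegimeReport:
    """Which of the four parameter regimes (scenes) the model sits in.

    Scene 1: the asexual equilibrium exists (and is automatically stable) —
    the plant settles into clonal reproduction every year.  Scene 2:
    neither equilibrium exists — reproduction cycles between branches.
    Scene 3: the sexual equilibrium exists and is stable — constant annual
    sexual + asexual reproduction.  Scene 4: it exists but is unstable —
    variable, possibly chaotic seed set.  Scene 0 marks a parameter set
    lying on one of the governing boundaries (within 1e-12) rather than
    silently assigning a side.
    """

    scene: int
    criteria: dict[str, dict[str, float]]
    asexual: FixedPointReport
    sexual: FixedPointReport

    def as_dict(self) -> dict:
        return {
            "scene": self.scene,
            "criteria": self.criteria,
            "fixed_points": {
                "asexual": self.asexual.as_dict(),
                "sexual": self.sexual.as_dict(),
            },
        }


def classify_regime(params: ModelParams) -> RegimeReport:
    """Assign the parameter set to one of the four scenes (or boundary 0).

    The comparisons are strict: scene 1 iff ``Ps < (L2-L1)*d``; scene 2 iff
    ``(L2-L1)*d < Ps < (p+q+R*p)*(L2-L1)``; scenes 3/4 iff ``Ps`` exceeds
    the SAR bound, split by the stability criterion ``R*p`` vs ``2-p-q``.
    Any governing equality within 1e-12 yields scene 0.
    """
    ar = asexual_fixed_point(params)
    sar = sexual_fixed_point(params)
    ar_bound = ar.condition_rhs
    sar_bound = sar.condition_rhs
    stab_lhs = params.R * params.p
    stab_rhs = 2.0 - params.p - params.q
    criteria = {
        "asexual_existence": {"Ps": params.Ps, "bound": ar_bound},
        "sexual_existence": {"Ps": params.Ps, "bound": sar_bound},
        "sexual_stability": {"Rp": stab_lhs, "two_minus_p_minus_q": stab_rhs},
    }
    if (abs(params.Ps - ar_bound) <= BOUNDARY_TOL
            or abs(params.Ps - sar_bound) <= BOUNDARY_TOL):
        scene = 0
    elif params.Ps < ar_bound:
        scene = 1
    elif params.Ps < sar_bound:
        scene = 2
    elif abs(stab_lhs - stab_rhs) <= BOUNDARY_TOL:
        scene = 0
    elif stab_lhs < stab_rhs:
        scene = 3
    else:
        scene = 4
    return RegimeReport(scene=scene, criteria=criteria, asexual=ar, sexual=sar)


_BRANCH_SLOPES = ("RA", "AR", "SAR")  # index order of _iterate branch codes


def lyapunov_numeric(params: ModelParams, y0: float | None = None,
                     burn_in: int = DEFAULT_BURN_IN,
                     window: int = DEFAULT_WINDOW) -> float:
    """Estimate the Lyapunov exponent from an orbit.

    The map is piecewise linear, so the exponent is the mean of
    ``ln|slope|`` over the branches visited after burn-in: slope 1 on the
    RA branch, ``1 - d`` on AR, ``1 - (p + q + R*p)`` on SAR.  Returns
    ``-inf`` if a visited branch has slope exactly zero (superstable).
    """
    if window < 100:
        raise ValueError(f"window must be >= 100, got {window}")
    if y0 is None:
        y0 = default_y0(params)
    _, br = _iterate(params, y0, burn_in, window)
    slopes = np.array([1.0, 1.0 - params.d, 1.0 - params.sar_allocation])
    visited = slopes[br]
    if np.any(visited == 0.0):
        return -math.inf
    return float(np.mean(np.log(np.abs(visited))))


def analyze(params: ModelParams, y0: float | None = None,
            burn_in: int = DEFAULT_BURN_IN,
            window: int = DEFAULT_WINDOW) -> dict:
    """Full equilibrium report as a JSON-ready dict.

    Combines the regime classification, both fixed-point reports and the
    numeric Lyapunov estimate from an orbit started at ``y0``.
    """
    regime = classify_regime(params)
    try:
        lam_num = lyapunov_numeric(params, y0=y0, burn_in=burn_in,
                                   window=window)
    except DivergenceError as exc:
        lam_num = None
        logger.warning("numeric Lyapunov estimate unavailable: %s", exc)
    report = {"params": params.as_dict()}
    report.update(regime.as_dict())
    report["lyapunov_numeric"] = lam_num
    return report


# --------------------------------------------------------------------------
# Period classification and phase-diagram sweeps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodCode:
    """Integer encoding of long-run reproductive behaviour.

    * ``-1`` — no sexual reproduction in the window (asexual every year or
      pure accumulation).
    * ``0`` — sexual reproduction every year on a constant orbit (fixed
      point).
    * ``1``–``18`` — sexual events recur at that constant interval in
      years; ``1`` also covers annual sexual reproduction on a
      non-constant orbit.
    * ``19`` — interval longer than 18 years, or no regular interval.

    ``cycle_length`` is the detected orbit period of the reserve sequence
    (None if none up to twice the maximum reproductive period);
    ``intervals`` are the distinct inter-event gaps observed.
    """

    code: int
    cycle_length: int | None
    intervals: tuple[int, ...]
    flags: tuple[str, ...]


def _window_code(sar: np.ndarray, ys: np.ndarray, tol: float) -> tuple[int, tuple[int, ...], tuple[str, ...]]:
    """Shared window classifier: (code, distinct intervals, flags)."""
    idx = np.flatnonzero(sar)
    if idx.size == 0:
        return -1, (), ("no_sexual_events",)
    if idx.size == sar.size:
        if float(ys.max() - ys.min()) <= tol:
            return 0, (1,), ()
        return 1, (1,), ()
    if idx.size == 1:
        return LONG_OR_IRREGULAR, (), ("exceeded_max_period",)
    gaps = np.diff(idx)
    first = int(gaps[0])
    if np.all(gaps == first):
        if first <= MAX_PERIOD:
            return first, (first,), ()
        return LONG_OR_IRREGULAR, (first,), ("exceeded_max_period",)
    distinct = tuple(sorted(int(g) for g in set(gaps.tolist())))
    return LONG_OR_IRREGULAR, distinct, ("aperiodic",)


def _orbit_cycle_length(ys: np.ndarray, tol: float,
                        max_len: int = 2 * MAX_PERIOD) -> int | None:
    for m in range(1, min(max_len, ys.size - 1) + 1):
        if np.all(np.abs(ys[m:] - ys[:-m]) <= tol):
            return m
    return None


def period_code(params: ModelParams, y0: float | None = None,
                burn_in: int = DEFAULT_BURN_IN, window: int = DEFAULT_WINDOW,
                tol: float = DEFAULT_TOL) -> PeriodCode:
    """Classify the long-run reproductive period of a parameter set.

    Simulates ``burn_in + window`` years from ``y0`` and inspects the SAR
    years inside the window: none gives code -1; annual sexual
    reproduction gives 0 on a constant reserve orbit (within ``tol``) and
    1 otherwise; a constant inter-event interval of 2-18 years gives that
    interval; everything else (single event, unequal intervals, interval
    beyond 18) gives 19.  Deterministic; divergence propagates.
    """
    if window < 4 * MAX_PERIOD:
        raise ValueError(f"window must be >= {4 * MAX_PERIOD}, got {window}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if y0 is None:
        y0 = default_y0(params)
    ys, br = _iterate(params, y0, burn_in, window)
    sar = br == 2
    code, intervals, flags = _window_code(sar, ys, tol)
    return PeriodCode(code=code, cycle_length=_orbit_cycle_length(ys, tol),
                      intervals=intervals, flags=flags)


def midpoint_grid(n: int) -> np.ndarray:
    """``n`` evenly spaced interior points of (0, 1): ``i/(n+1)``, i=1..n.

    The endpoints 0 and 1 lie outside the valid coefficient ranges and are
    never sampled.
    """
    if n < 1:
        raise ValueError(f"grid size must be >= 1, got {n}")
    return np.arange(1, n + 1) / (n + 1)


@dataclass(frozen=True)
class PhaseDiagram:
    """Grid of period codes over (p, q) at a fixed depletion coefficient R.

    ``codes[j, i]`` is the period code at ``p = p_grid[i]``,
    ``q = q_grid[j]``.  Cells excluded by a simplex restriction carry -2;
    cells whose orbit diverged carry -9.
    """

    R: float
    base: dict[str, float]            # L1, L2, Ps, d
    p_grid: np.ndarray
    q_grid: np.ndarray
    codes: np.ndarray                 # int, shape (len(q_grid), len(p_grid))
    provenance: dict = field(default_factory=dict)

    def non_annual_count(self) -> int:
        """Number of evaluated cells not reproducing sexually every year
        on a fixed point (code != 0)."""
        mask = self.codes != EXCLUDED_CODE
        return int(np.sum(mask & (self.codes != 0)))

    def to_long_dataframe(self) -> pd.DataFrame:
        jj, ii = np.meshgrid(np.arange(self.q_grid.size),
                             np.arange(self.p_grid.size), indexing="ij")
        return pd.DataFrame({
            "R": self.R,
            "p": self.p_grid[ii.ravel()],
            "q": self.q_grid[jj.ravel()],
            "code": self.codes.ravel(),
        })


def _sweep_one(L1: float, L2: float, Ps: float, d: float,
               p: np.ndarray, q: np.ndarray, R: float,
               y0: float, burn_in: int, window: int, tol: float,
               guard: float) -> np.ndarray:
    """Vectorised period codes for flattened cell arrays ``p``, ``q``.

    The update is evaluated with the same elementwise operation order as
    the scalar map, so each cell's orbit is bit-identical to a pointwise
    :func:`period_code` call.
    """
    n = p.size
    s = p + q + R * p
    y = np.full(n, y0, dtype=float)
    alive = np.ones(n, dtype=bool)

    def advance(y):
        pool = y + Ps
        excess = pool - L1
        ra = pool < L1
        sar = pool > L2
        ar = ~ra & ~sar
        out = pool.copy()
        out[ar] = pool[ar] - d * excess[ar]
        out[sar] = pool[sar] - s[sar] * excess[sar]
        return out, sar

    for _ in range(burn_in):
        y, _sar = advance(y)
        bad = alive & (np.abs(y) > guard)
        if bad.any():
            alive &= ~bad
            y[bad] = 0.0
    ys = np.empty((window, n))
    sars = np.empty((window, n), dtype=bool)
    for t in range(window):
        ys[t] = y
        y, sar = advance(y)
        sars[t] = sar
        bad = alive & (np.abs(y) > guard)
        if bad.any():
            alive &= ~bad
            y[bad] = 0.0
    codes = np.full(n, DIVERGED_CODE, dtype=np.int64)
    for i in np.flatnonzero(alive):
        codes[i] = _window_code(sars[:, i], ys[:, i], tol)[0]
    return codes


def sweep(base: ModelParams | Mapping[str, float],
          p_grid: Sequence[float] | np.ndarray,
          q_grid: Sequence[float] | np.ndarray,
          R_values: Iterable[float],
          y0: float | None = None, burn_in: int = DEFAULT_BURN_IN,
          window: int = DEFAULT_WINDOW, tol: float = DEFAULT_TOL,
          simplex: bool = False,
          guard: float = DIVERGENCE_GUARD) -> list[PhaseDiagram]:
    """Tile (p, q) space with period codes, one phase diagram per R.

    ``base`` supplies the fixed scalars L1, L2, Ps, d (a full parameter
    set or any mapping with those keys).  Cells are mutually independent;
    a divergent cell is coded -9 and logged instead of aborting the sweep.
    With ``simplex=True`` only cells with ``p + q <= 1`` are simulated
    (total reproductive allocation at most the whole excess); the rest are
    coded -2.
    """
    if isinstance(base, ModelParams):
        base = base.as_dict()
    fixed = {k: float(base[k]) for k in ("L1", "L2", "Ps", "d")}
    if y0 is None:
        y0 = fixed["L1"] / 2.0
    p_grid = np.asarray(p_grid, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    if not (np.all(p_grid > 0) and np.all(p_grid < 1)
            and np.all(q_grid > 0) and np.all(q_grid < 1)):
        raise ValueError("p and q grids must lie strictly inside (0, 1)")
    if p_grid.size > 1 and not np.all(np.diff(p_grid) > 0):
        raise ValueError("p_grid must be strictly increasing")
    if q_grid.size > 1 and not np.all(np.diff(q_grid) > 0):
        raise ValueError("q_grid must be strictly increasing")
    jj, ii = np.meshgrid(np.arange(q_grid.size), np.arange(p_grid.size),
                         indexing="ij")
    pp = p_grid[ii.ravel()]
    qq = q_grid[jj.ravel()]
    active = pp + qq <= 1.0 if simplex else np.ones(pp.size, dtype=bool)
    diagrams = []
    provenance = {"y0": y0, "burn_in": burn_in, "window": window,
                  "tol": tol, "simplex": simplex}
    for R in R_values:
        R = float(R)
        if R <= 0:
            raise ValueError(f"R values must be positive, got {R}")
        codes = np.full(pp.size, EXCLUDED_CODE, dtype=np.int64)
        codes[active] = _sweep_one(
            fixed["L1"], fixed["L2"], fixed["Ps"], fixed["d"],
            pp[active], qq[active], R, y0, burn_in, window, tol, guard)
        n_div = int(np.sum(codes == DIVERGED_CODE))
        if n_div:
            logger.warning("sweep at R=%g: %d divergent cell(s) coded %d",
                           R, n_div, DIVERGED_CODE)
        diagrams.append(PhaseDiagram(
            R=R, base=fixed, p_grid=p_grid, q_grid=q_grid,
            codes=codes.reshape(q_grid.size, p_grid.size),
            provenance=dict(provenance)))
    return diagrams


def phase_diagrams_to_dataframe(diagrams: Iterable[PhaseDiagram]) -> pd.DataFrame:
    """Concatenate sweeps into one long-format table (R, p, q, code)."""
    return pd.concat([d.to_long_dataframe() for d in diagrams],
                     ignore_index=True)


def plot_phase_diagram(diagram: PhaseDiagram, path: str | Path) -> None:
    """Render one phase diagram as a heatmap image (write-only).

    Distinct colors for the asexual-only (-1) and annual-sexual (0) codes,
    a graded ramp for periods 1-18, and a saturated color for 19.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    ramp = plt.get_cmap("viridis")(np.linspace(0.15, 0.85, MAX_PERIOD))
    colors = (["#bbbbbb", "#555555", "#1f78b4"]  # excluded, asexual, annual
              + [tuple(c) for c in ramp] + ["#d62728"])
    cmap = ListedColormap(colors)
    bounds = np.arange(-2.5, LONG_OR_IRREGULAR + 1.0, 1.0)
    norm = BoundaryNorm(bounds, cmap.N)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    mesh = ax.pcolormesh(diagram.p_grid, diagram.q_grid,
                         np.where(diagram.codes == DIVERGED_CODE,
                                  LONG_OR_IRREGULAR, diagram.codes),
                         cmap=cmap, norm=norm, shading="nearest")
    fig.colorbar(mesh, ax=ax, label="reproductive period code",
                 ticks=[-1, 0, 5, 10, 15, 19])
    ax.set_xlabel("flowering coefficient p")
    ax.set_ylabel("asexual coefficient q")
    ax.set_title(f"R = {diagram.R:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Scenario registry and configuration resolution
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named bundled parameter set (possibly partial)."""

    name: str
    values: dict[str, float]
    source: str

    def is_complete(self) -> bool:
        return all(k in self.values for k in ("L1", "L2", "Ps", "p", "q", "d", "R"))


SCENARIOS: dict[str, Scenario] = {
    s.name: s for s in (
        Scenario("table1_default",
                 {"L1": 4.0, "L2": 6.0, "Ps": 3.0},
                 "default thresholds and surplus; the allocation "
                 "coefficients p, q, d and the depletion coefficient R "
                 "must be supplied"),
        Scenario("fig1a",
                 {"L1": 2.0, "Ps": 3.0, "L2": 8.0, "d": 0.6,
                  "p": 0.1, "q": 0.9, "R": 6.0},
                 "asexual-only steady state: the surplus never lifts the "
                 "pool over the sexual threshold"),
        Scenario("fig1b",
                 {"L1": 2.0, "Ps": 3.0, "L2": 6.0, "d": 0.6,
                  "p": 0.1, "q": 0.9, "R": 6.0},
                 "periodic mixed reproduction: no equilibrium exists and "
                 "sexual years recur on a multi-year cycle"),
        Scenario("fig1c",
                 {"L1": 2.0, "Ps": 3.0, "L2": 3.0, "d": 0.6,
                  "p": 0.1, "q": 0.9, "R": 6.0},
                 "constant annual sexual + asexual reproduction at a "
                 "stable equilibrium"),
        Scenario("fig1d",
                 {"L1": 2.0, "Ps": 3.0, "L2": 3.0, "d": 0.6,
                  "p": 0.1, "q": 0.9, "R": 12.0},
                 "unstable sexual equilibrium: seed set varies "
                 "irregularly"),
        Scenario("fig2_base",
                 {"L1": 2.0, "Ps": 3.0, "L2": 3.0, "d": 0.6},
                 "phase-diagram template: thresholds, surplus and asexual "
                 "depletion fixed; p, q and R swept"),
    )
}

_PARAM_KEYS = ("L1", "L2", "Ps", "p", "q", "d", "R")
_SETTING_KEYS = ("y0", "years", "burn_in", "window", "tol")


def load_config(path: str | Path) -> dict[str, float]:
    """Load a flat YAML key/value config (model parameters and settings)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    unknown = set(data) - set(_PARAM_KEYS) - set(_SETTING_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return {k: float(v) for k, v in data.items()}


def resolve(scenario: str | None = None,
            config: Mapping[str, float] | None = None,
            overrides: Mapping[str, float] | None = None,
            require_complete: bool = True,
            ) -> tuple[ModelParams | None, dict[str, float]]:
    """Merge scenario < config < explicit overrides into parameters.

    Returns ``(params, settings)`` where ``settings`` holds any of
    y0/years/burn_in/window/tol found in the config or overrides.  With
    ``require_complete=False`` a partial merge returns ``params=None``
    together with the merged raw values under settings key ``"_partial"``.
    """
    merged: dict[str, float] = {}
    if scenario is not None:
        if scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {scenario!r}; available: "
                f"{', '.join(sorted(SCENARIOS))}")
        merged.update(SCENARIOS[scenario].values)
    for src in (config, overrides):
        if src:
            merged.update({k: v for k, v in src.items() if v is not None})
    settings = {k: merged.pop(k) for k in list(merged) if k in _SETTING_KEYS}
    missing = [k for k in _PARAM_KEYS if k not in merged]
    if missing:
        if require_complete:
            raise ValueError(f"missing model parameters: {', '.join(missing)}")
        settings["_partial"] = dict(merged)
        return None, settings
    params = ModelParams(**{k: merged[k] for k in _PARAM_KEYS})
    logger.info("resolved parameters: %s", params.as_dict())
    return params, settings
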