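"""The efficient-enantioseparation (EES) metric.

EES condenses a chromatographic run into a single number by penalizing
enantioresolution (Rs) for impractically long retention:

    EES = Rs - p * max(0, k2 - k2lim)

where ``k2`` is the retention factor of the more-retained enantiomer,
``k2lim`` the largest retention the analyst is willing to accept and
``p`` a dimensionless penalty factor.  Practical rules wrap the bare
formula: inputs are rounded to one decimal, Rs is capped (default 6)
and k2 truncated (default 30), and the result is floored (default -1),
so the working range of EES is [-1, 6].  Whenever the rounded k2 is
within the acceptable limit, EES equals the capped Rs.

A separation counts as *acceptable* when EES >= 1.3, the conventional
baseline-resolution criterion.  The penalty factor is chosen by
simulation so that "false positives" -- grid points scored acceptable
although k2 exceeds the limit -- are vanishingly rare; exhaustive
enumeration of the one-decimal (Rs, k2) grid makes that simulation
exact and reproducible.

All arithmetic is carried out on integer multiples of the rounding
step (tenths by default), which keeps grid comparisons such as
``EES >= 1.3`` exact in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ChromatogramRecord, MobilePhaseGrid, N_MOBILE_PHASES, TargetMatrix

__all__ = [
    "EESParameters",
    "FalsePositiveReport",
    "CompletenessError",
    "PenaltyNotFoundError",
    "compute_ees",
    "is_acceptable",
    "build_target_matrix",
    "simulate_false_positive_rate",
    "select_penalty_factor",
]


class CompletenessError(ValueError):
    """A chromatographic table lacks (or repeats) a compound/MP combination."""


class PenaltyNotFoundError(LookupError):
    """No candidate penalty factor satisfies the false-positive bound."""


@dataclass(frozen=True)
class EESParameters:
    """Constants governing the EES computation.

    Attributes
    ----------
    p : float
        Penalty per unit of excess retention (default 45).
    k2lim : float
        Largest acceptable k2 (default 20); retention beyond it is
        penalized.
    k2_cap : float
        Truncation of k2 before the formula is applied (default 30).
    rs_cap : float
        Cap on Rs (default 6).
    floor : float
        Minimum reportable EES (default -1).
    decimals : int
        Rounding of the raw Rs and k2 inputs (default 1 decimal).
    threshold : float
        EES at or above which a separation is deemed acceptable
        (default 1.3).
    """

    p: float = 45.0
    k2lim: float = 20.0
    k2_cap: float = 30.0
    rs_cap: float = 6.0
    floor: float = -1.0
    decimals: int = 1
    threshold: float = 1.3

    def __post_init__(self):
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if not 0 < self.k2lim <= self.k2_cap:
            raise ValueError("require 0 < k2lim <= k2_cap")
        if not self.rs_cap > self.threshold > 0:
            raise ValueError("require rs_cap > threshold > 0")
        if not self.floor < self.threshold:
            raise ValueError("require floor < threshold")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")

    @property
    def _step(self) -> int:
        return 10 ** self.decimals


def _to_grid(x: np.ndarray, step: int) -> np.ndarray:
    """Round nonnegative values half-away-from-zero onto the 1/step grid,
    returned as integer multiples of the step."""
    return np.floor(np.asarray(x, dtype=float) * step + 0.5)


def compute_ees(rs, k2, params: EESParameters = EESParameters()):
    """Evaluate EES for resolution/retention pairs.

    Accepts scalars or arrays (broadcast together).  The pipeline is:
    round both inputs to ``params.decimals`` -> cap Rs at ``rs_cap`` and
    truncate k2 at ``k2_cap`` -> apply the penalized formula -> floor.
    Internally works on integer grid units so threshold comparisons on
    rounded data are exact.
    """
    rs_arr = np.asarray(rs, dtype=float)
    k2_arr = np.asarray(k2, dtype=float)
    if (rs_arr < 0).any():
        raise ValueError("rs must be >= 0")
    if (k2_arr < 0).any():
        raise ValueError("k2 must be >= 0")
    step = params._step
    rs_t = np.minimum(_to_grid(rs_arr, step), round(params.rs_cap * step))
    k2_t = np.minimum(_to_grid(k2_arr, step), round(params.k2_cap * step))
    excess_t = np.maximum(0.0, k2_t - round(params.k2lim * step))
    ees_t = np.maximum(rs_t - params.p * excess_t, params.floor * step)
    out = ees_t / step
    if np.isscalar(rs) and np.isscalar(k2):
        return float(out)
    return out


def is_acceptable(ees, params: EESParameters = EESParameters()):
    """True where EES meets the acceptability threshold (inclusive)."""
    out = np.asarray(ees, dtype=float) >= params.threshold
    if np.isscalar(ees):
        return bool(out)
    return out


def build_target_matrix(
    records: Sequence[ChromatogramRecord],
    params: EESParameters = EESParameters(),
    grid: MobilePhaseGrid = MobilePhaseGrid(),
) -> TargetMatrix:
    """Assemble the EES response matrix (compounds x 9 mobile phases).

    Every compound must contribute exactly one record per mobile-phase
    index; gaps or duplicates raise :class:`CompletenessError` naming
    the offending combination.  Compound order follows first appearance
    in ``records``.
    """
    by_compound: dict[str, dict[int, ChromatogramRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.compound_id not in by_compound:
            by_compound[rec.compound_id] = {}
            order.append(rec.compound_id)
        if rec.mp_index in by_compound[rec.compound_id]:
            raise CompletenessError(
                f"duplicate record for compound {rec.compound_id!r} at MP {rec.mp_index}"
            )
        by_compound[rec.compound_id][rec.mp_index] = rec
    values = np.empty((len(order), N_MOBILE_PHASES))
    for i, cid in enumerate(order):
        for mp in grid.indices:
            if mp not in by_compound[cid]:
                raise CompletenessError(f"compound {cid!r} is missing MP {mp}")
            rec = by_compound[cid][mp]
            values[i, mp - 1] = compute_ees(rec.rs, rec.k2, params)
    return TargetMatrix(tuple(order), values)


@dataclass(frozen=True)
class FalsePositiveReport:
    """Outcome of a false-positive simulation at one penalty factor."""

    p: float
    rate_percent: float
    n_evaluated: int
    n_false_positive: int
    mode: str

    def __post_init__(self):
        if not 0 <= self.rate_percent <= 100:
            raise ValueError("rate_percent must lie in [0, 100]")


def _grid_axes(params: EESParameters) -> tuple[np.ndarray, np.ndarray]:
    step = params._step
    rs = np.arange(round(params.rs_cap * step) + 1) / step
    k2 = np.arange(round(params.k2_cap * step) + 1) / step
    return rs, k2


def simulate_false_positive_rate(
    p: float,
    params: EESParameters = EESParameters(),
    mode: str = "enumerate",
    n_draws: int = 0,
    seed: int | None = None,
) -> FalsePositiveReport:
    """Fraction of (Rs, k2) inputs wrongly scored acceptable.

    A *false positive* is an input whose EES reaches the acceptability
    threshold although the rounded k2 exceeds ``k2lim``.  In
    ``enumerate`` mode every one-decimal pair with Rs in [0, rs_cap]
    and k2 in [0, k2_cap] is evaluated exactly once (61 x 301 = 18361
    cells at the defaults); the result is exact and deterministic.
    ``montecarlo`` mode draws uniformly from the same two grids with
    the given seed.
    """
    trial = EESParameters(
        p=p, k2lim=params.k2lim, k2_cap=params.k2_cap, rs_cap=params.rs_cap,
        floor=params.floor, decimals=params.decimals, threshold=params.threshold,
    )
    rs_axis, k2_axis = _grid_axes(params)
    if mode == "enumerate":
        rs_g, k2_g = np.meshgrid(rs_axis, k2_axis, indexing="ij")
        rs_v, k2_v = rs_g.ravel(), k2_g.ravel()
    elif mode == "montecarlo":
        if n_draws < 1:
            raise ValueError("montecarlo mode requires n_draws >= 1")
        rng = np.random.default_rng(seed)
        rs_v = rng.choice(rs_axis, size=n_draws)
        k2_v = rng.choice(k2_axis, size=n_draws)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected enumerate|montecarlo")
    ees = compute_ees(rs_v, k2_v, trial)
    step = params._step
    over_limit = _to_grid(k2_v, step) > round(params.k2lim * step)
    fp = int(np.count_nonzero(is_acceptable(ees, trial) & over_limit))
    n = rs_v.size
    return FalsePositiveReport(
        p=float(p), rate_percent=100.0 * fp / n, n_evaluated=int(n),
        n_false_positive=fp, mode=mode,
    )


def select_penalty_factor(
    candidates: Sequence[int],
    target_rate_percent: float,
    params: EESParameters = EESParameters(),
) -> int:
    """Smallest candidate penalty factor whose exhaustive-enumeration
    false-positive percentage does not exceed the bound."""
    cand = list(candidates)
    if cand != sorted(cand):
        raise ValueError("candidates must be sorted ascending")
    for p in cand:
        report = simulate_false_positive_rate(p, params, mode="enumerate")
        if report.rate_percent <= target_rate_percent:
            return p
    raise PenaltyNotFoundError(
        f"no candidate in {cand[0]}..{cand[-1]} reaches a false-positive rate "
        f"<= {target_rate_percent}%"
    )
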