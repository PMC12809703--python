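"""Penalized quality metrics driving the model search.

Model selection for small chromatographic datasets has to reward fit
quality while punishing overfitting and gross errors.  Three pieces do
that here:

* ``q_index`` -- a signed, bias-penalized determination index for one
  subset: Q = R*|R| - |1 - b1| - |b0|, where R is the Pearson
  correlation between predictions and targets and (b1, b0) the OLS
  slope/intercept of predictions regressed on targets.  Q is 1 only
  for a perfect, unbiased fit.
* ``pq_metric`` -- aggregates the three subset Q values (training,
  validation, internal test): pQ = 100 * (mean - p_overfit * sd), so
  subset-to-subset instability (a symptom of overfitting) is
  penalized.
* ``pe_metric`` -- a weighted count of absolute prediction errors,
  graded into three severity levels and weighted more heavily for the
  validation and internal-test subsets:
  pE = 0.1*(Tr1+Va1+IT1) + 0.2*Tr2 + 0.3*Tr3 + 1*Va2 + 1.5*Va3 + 2*IT2 + 3*IT3.

The combined objective is Fobj = W*pQ - (1-W)*pE (higher is better);
a configuration flag restores the additive variant for comparison.
Errors and correlations are evaluated on back-transformed (EES-unit)
values, where the 0.2/0.4/0.6 level boundaries are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObjectiveWeights",
    "SubsetQuality",
    "ErrorLevelCounts",
    "q_index",
    "pq_metric",
    "error_levels",
    "pe_metric",
    "fobj",
]

#: Q assigned when the correlation is undefined (constant targets or
#: predictions); chosen below any attainable real Q so degenerate
#: candidates stay comparable instead of crashing the optimizer.
WORST_Q = -3.0

SUBSET_LABELS = ("tr", "va", "it")


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights combining the two objective terms.

    ``w`` weighs pQ against pE (default 0.5, equal weighting);
    ``p_overfit`` scales the subset-instability penalty inside pQ;
    ``literal_pe_sign`` switches Fobj from the penalty convention
    (W*pQ - (1-W)*pE, default) to the additive variant.
    """

    w: float = 0.5
    p_overfit: float = 2.0
    literal_pe_sign: bool = False

    def __post_init__(self):
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")
        if self.p_overfit < 0:
            raise ValueError("p_overfit must be >= 0")


@dataclass(frozen=True)
class SubsetQuality:
    """Per-subset Q values and their pQ aggregate."""

    q_tr: float
    q_va: float
    q_it: float
    p_overfit: float = 2.0

    @property
    def mq(self) -> float:
        return float(np.mean([self.q_tr, self.q_va, self.q_it]))

    @property
    def sq(self) -> float:
        return float(np.std([self.q_tr, self.q_va, self.q_it], ddof=1))

    @property
    def pq(self) -> float:
        return 100.0 * (self.mq - self.p_overfit * self.sq)


def q_index(y, t, worst: float = WORST_Q) -> float:
    """Bias-penalized determination index of predictions ``y`` against
    targets ``t``.

    Returns ``worst`` when either vector is constant (correlation and
    slope undefined).
    """
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if y.shape != t.shape:
        raise ValueError("y and t must have the same length")
    if y.size < 3:
        raise ValueError("q_index requires at least 3 paired values")
    st = t.std()
    sy = y.std()
    if st == 0 or sy == 0:
        return float(worst)
    r = float(np.corrcoef(y, t)[0, 1])
    # OLS of y on t
    b1 = float(np.cov(y, t, ddof=1)[0, 1] / t.var(ddof=1))
    b0 = float(y.mean() - b1 * t.mean())
    return r * abs(r) - abs(1.0 - b1) - abs(b0)


def pq_metric(q_tr: float, q_va: float, q_it: float, p_overfit: float = 2.0) -> float:
    """Overfitting-penalized aggregate of the three subset Q values."""
    qs = np.array([q_tr, q_va, q_it], dtype=float)
    if not np.isfinite(qs).all():
        raise ValueError("Q values must be finite")
    return 100.0 * (float(qs.mean()) - p_overfit * float(qs.std(ddof=1)))


@dataclass(frozen=True)
class ErrorLevelCounts:
    """Counts of absolute prediction errors per severity level and subset.

    Level 1: 0.2 < |e| < 0.4; Level 2: 0.4 <= |e| < 0.6;
    Level 3: |e| >= 0.6.  Errors of at most 0.2 are not counted.
    """

    tr1: int = 0
    tr2: int = 0
    tr3: int = 0
    va1: int = 0
    va2: int = 0
    va3: int = 0
    it1: int = 0
    it2: int = 0
    it3: int = 0

    def __post_init__(self):
        for name in ("tr1", "tr2", "tr3", "va1", "va2", "va3", "it1", "it2", "it3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Error-level boundaries (EES units): (low, high) half-open style per level.
LEVEL_1 = (0.2, 0.4)   # 0.2 < |e| < 0.4
LEVEL_2 = (0.4, 0.6)   # 0.4 <= |e| < 0.6
LEVEL_3 = 0.6          # |e| >= 0.6


def error_levels(y, t, subset_of_each_cell) -> ErrorLevelCounts:
    """Classify every prediction cell into an error level per subset.

    ``subset_of_each_cell`` holds a 'tr'/'va'/'it' label per cell,
    aligned with the flattened ``y`` and ``t``.  Each cell contributes
    to at most one level; boundary values 0.4 and 0.6 fall upward into
    levels 2 and 3 respectively.
    """
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    labels = np.asarray(subset_of_each_cell, dtype=object).ravel()
    if not (y.shape == t.shape == labels.shape):
        raise ValueError("y, t and subset labels must be aligned")
    unknown = set(labels) - set(SUBSET_LABELS)
    if unknown:
        raise ValueError(f"unknown subset label(s): {sorted(map(str, unknown))}")
    e = np.abs(y - t)
    counts = {}
    for sub in SUBSET_LABELS:
        m = labels == sub
        counts[f"{sub}1"] = int(np.count_nonzero(m & (e > LEVEL_1[0]) & (e < LEVEL_1[1])))
        counts[f"{sub}2"] = int(np.count_nonzero(m & (e >= LEVEL_2[0]) & (e < LEVEL_2[1])))
        counts[f"{sub}3"] = int(np.count_nonzero(m & (e >= LEVEL_3)))
    return ErrorLevelCounts(**counts)


def pe_metric(counts: ErrorLevelCounts) -> float:
    """Weighted error count; heavier weights for validation and
    internal-test errors and for larger errors."""
    return (
        0.1 * (counts.tr1 + counts.va1 + counts.it1)
        + 0.2 * counts.tr2
        + 0.3 * counts.tr3
        + 1.0 * counts.va2
        + 1.5 * counts.va3
        + 2.0 * counts.it2
        + 3.0 * counts.it3
    )


def fobj(pq: float, pe: float, weights: ObjectiveWeights = ObjectiveWeights()) -> float:
    """Combined objective; the optimizer maximizes this.

    Default convention treats pE as a penalty entering negatively so
    that higher Fobj always means better fit with lower error;
    ``weights.literal_pe_sign`` restores the additive form.
    """
    if not (np.isfinite(pq) and np.isfinite(pe)):
        raise ValueError("pq and pe must be finite")
    if weights.literal_pe_sign:
        return weights.w * pq + (1.0 - weights.w) * pe
    return weights.w * pq - (1.0 - weights.w) * pe
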