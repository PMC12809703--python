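"""Ranking of optimized networks and median/MADe consensus prediction.

A handful of independently optimized networks is more reliable than
any single one on a moderate-size dataset: individual networks differ
in their splits, topologies and descriptor subsets, so their
idiosyncratic errors tend to cancel.  The consensus prediction at each
compound/mobile-phase cell is the median of the member predictions,
with uncertainty expressed as the scaled median absolute deviation
MADe = 1.4826 * median(|v - median(v)|), a robust estimator of the
standard deviation.

Ranking is deterministic: ascending misclassification count against
the EES acceptability threshold, ties broken by descending objective,
then ascending error penalty, then model id.  (Model selection in
this kind of workflow is often aided by visual inspection of
validation plots; the tiebreak chain replaces that step so results
are reproducible.)

A profile prediction also carries feasibility calls (median >= 1.3
per mobile phase) and, when any phase is feasible, nominates the one
with the largest median EES — the single-shot condition to try first
at the bench.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ann_engine import TrainedANN, load_model, predict_ann, save_model
from .cclnna import OptimizationArchive
from .data_model import DescriptorMatrix, MobilePhaseGrid
from .ees_metric import EESParameters

__all__ = [
    "RankedModel",
    "ModelRanking",
    "ConsensusModel",
    "ProfilePrediction",
    "misclassification_count",
    "rank_models",
    "build_consensus",
    "mad_e",
    "consensus_predict",
    "profiles_to_frame",
    "save_consensus",
    "load_consensus",
]

MADE_SCALE = 1.4826  # consistency factor: MADe estimates sigma for normal data


def misclassification_count(y, t, threshold: float = 1.3) -> int:
    """Cells where prediction and target fall on opposite sides of the
    acceptability threshold (boundary counts as acceptable for both)."""
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if y.shape != t.shape:
        raise ValueError("y and t must have the same length")
    return int(np.count_nonzero((y >= threshold) != (t >= threshold)))


@dataclass(frozen=True)
class RankedModel:
    model_id: int
    model: TrainedANN
    misclassifications: int
    fobj: float
    pe: float


@dataclass(frozen=True)
class ModelRanking:
    entries: tuple

    def __len__(self) -> int:
        return len(self.entries)


def rank_models(archive: OptimizationArchive, subset: str = "all") -> ModelRanking:
    """Deterministic total order over archived models.

    ``subset`` selects which misclassification count ranks first:
    'tr', 'va', 'it' or 'all' (the sum).  Sort key: misclassifications
    ascending, objective descending, error penalty ascending, model id
    ascending.
    """
    if subset not in ("tr", "va", "it", "all"):
        raise ValueError(f"unknown subset {subset!r}")
    if not archive.runs:
        raise ValueError("archive is empty")
    key = "misclass_total" if subset == "all" else f"misclass_{subset}"
    entries = []
    for i, run in enumerate(archive.runs):
        m = run.model.metrics
        entries.append(RankedModel(
            model_id=i,
            model=run.model,
            misclassifications=int(m[key]),
            fobj=float(m["fobj"]),
            pe=float(m["pe"]),
        ))
    entries.sort(key=lambda e: (e.misclassifications, -e.fobj, e.pe, e.model_id))
    return ModelRanking(tuple(entries))


@dataclass
class ConsensusModel:
    """Top-k networks aggregated by median with MADe uncertainty."""

    members: list
    params: EESParameters = field(default_factory=EESParameters)

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a consensus model needs at least 2 members")
        masks = {m.feature_mask.size for m in self.members}
        if len(masks) != 1:
            raise ValueError("members disagree on the descriptor schema width")


def build_consensus(ranking: ModelRanking, k: int = 5,
                    params: EESParameters = EESParameters()) -> ConsensusModel:
    """Retain the top-k ranked networks as consensus members."""
    if not 2 <= k <= len(ranking):
        raise ValueError(f"k must lie in 2..{len(ranking)}, got {k}")
    return ConsensusModel(members=[e.model for e in ranking.entries[:k]], params=params)


def mad_e(values) -> float:
    """Scaled median absolute deviation: 1.4826 * median(|v - median|)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("mad_e requires at least one value")
    return float(MADE_SCALE * np.median(np.abs(v - np.median(v))))


@dataclass(frozen=True)
class ProfilePrediction:
    """Consensus EES profile for one compound across the 9 mobile phases."""

    compound_id: str
    median_profile: np.ndarray
    made_profile: np.ndarray
    feasibility: np.ndarray       # per-MP: median >= threshold
    nominated_mp: int | None      # 1-based MP index of the best feasible phase


def member_predictions(model: ConsensusModel, x_new: DescriptorMatrix) -> np.ndarray:
    """Stacked member predictions, shape (n_members, n_compounds, 9)."""
    clip_range = (model.params.floor, model.params.rs_cap)
    return np.stack([
        predict_ann(m, x_new, clip=True, clip_range=clip_range) for m in model.members
    ])


def consensus_predict(model: ConsensusModel, x_new: DescriptorMatrix) -> list:
    """Median/MADe EES profiles with feasibility calls.

    Per compound and mobile phase the member predictions are reduced
    to their median (even member counts use the midpoint) and MADe.
    A phase is feasible when the median reaches the acceptability
    threshold; among feasible phases the one with maximal median EES
    is nominated (ties resolved to the lowest index).
    """
    stack = member_predictions(model, x_new)            # (k, n, 9)
    med = np.median(stack, axis=0)                      # (n, 9)
    made = MADE_SCALE * np.median(np.abs(stack - np.median(stack, axis=0)), axis=0)
    thr = model.params.threshold
    out = []
    for i, cid in enumerate(x_new.compound_ids):
        feasible = med[i] >= thr
        nominated = int(np.argmax(np.where(feasible, med[i], -np.inf))) + 1 if feasible.any() else None
        out.append(ProfilePrediction(
            compound_id=cid,
            median_profile=med[i],
            made_profile=made[i],
            feasibility=feasible,
            nominated_mp=nominated,
        ))
    return out


def profiles_to_frame(predictions: Sequence[ProfilePrediction],
                      grid: MobilePhaseGrid = MobilePhaseGrid()) -> pd.DataFrame:
    """Long-format table of consensus profiles:
    compound_id, mp_index, acn_percent, ees_median, ees_made, feasible, nominated."""
    rows = []
    for p in predictions:
        for j, mp in enumerate(grid.indices):
            rows.append({
                "compound_id": p.compound_id,
                "mp_index": mp,
                "acn_percent": grid.acn_percent[j],
                "ees_median": p.median_profile[j],
                "ees_made": p.made_profile[j],
                "feasible": bool(p.feasibility[j]),
                "nominated": p.nominated_mp == mp,
            })
    return pd.DataFrame(rows)


def save_consensus(model: ConsensusModel, directory) -> None:
    d = Path(directory)
    if d.exists():
        shutil.rmtree(d)
    d.mkdir(parents=True)
    for i, m in enumerate(model.members):
        save_model(m, d / f"member_{i:02d}")
    (d / "consensus.json").write_text(json.dumps({
        "n_members": len(model.members),
        "params": model.params.__dict__,
    }, indent=1, sort_keys=True))


def load_consensus(directory) -> ConsensusModel:
    d = Path(directory)
    meta = json.loads((d / "consensus.json").read_text())
    members = [load_model(d / f"member_{i:02d}") for i in range(meta["n_members"])]
    return ConsensusModel(members=members, params=EESParameters(**meta["params"]))
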