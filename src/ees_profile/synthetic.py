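"""Seeded synthetic benchmark with known ground truth.

Real chiral-HPLC screening data (descriptor tables plus per-compound
Rs/k2 measurements at nine acetonitrile fractions) cannot ship with
the package, so this module fabricates datasets with the same
*structure* and a known informative-descriptor subset, which makes
feature-recovery and consensus properties testable.

The generative mechanism mirrors reversed-phase behavior in broad
strokes:

* descriptors mix small-integer counts (topological-style), binary
  flags and continuous values; the first ``n_informative`` columns are
  continuous and carry all signal;
* a latent retention score r and a chiral-recognition score c are
  linear in the informative descriptors;
* retention decays exponentially with organic fraction:
  k2(mp) = exp(a0 + r - b * acn_fraction) (+ lognormal noise);
* resolution follows Rs(mp) = amp * softplus(c') * hump(k2) for
  compounds whose recognition score passes a gate, where hump(k2)
  peaks at moderate retention and vanishes as k2 -> 0 (no retention,
  no separation); gated-off compounds get near-zero Rs everywhere.
  The gate threshold is the normal quantile of the recognition score
  at (1 - resolved_fraction), so the realized share of separable
  compounds approximates the configured one.

Only a minority of compounds (default 30 %) is separable, matching
the class imbalance typical of a single cellulose-type column.  All
Rs and k2 values are rounded to one decimal, as reported in practice.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from statistics import NormalDist

import numpy as np

from .data_model import (
    ChromatogramRecord,
    DescriptorMatrix,
    MobilePhaseGrid,
    TargetMatrix,
    write_chromatograms,
    write_descriptors,
    write_target,
)
from .ees_metric import EESParameters, build_target_matrix

__all__ = [
    "FixtureConfig",
    "FixtureDataset",
    "generate_descriptors",
    "generate_chromatograms",
    "generate_dataset",
    "write_dataset_bundle",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic benchmark.

    Defaults reproduce the reference study geometry: 76 compounds by
    62 descriptors with 5 informative columns and roughly 30 % of
    compounds separable at one or more mobile phases.  ``noise_sd``
    applies to Rs and to log-k2.
    """

    n_compounds: int = 76
    n_descriptors: int = 62
    n_informative: int = 5
    resolved_fraction: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative must not exceed n_descriptors")
        if not 0 <= self.resolved_fraction <= 1:
            raise ValueError("resolved_fraction must lie in [0, 1]")
        if self.n_compounds < 1 or self.n_descriptors < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class FixtureDataset:
    descriptors: DescriptorMatrix
    chromatograms: tuple
    target: TargetMatrix
    informative_mask: np.ndarray


# retention model constants: k2 at 30 % ACN is around exp(a0 - b*0.3) ~ 9
# times exp(r), decaying to ~0.15*exp(r) at 98 % — spanning the practical
# range including impractically retained cases (k2 > 20) at low ACN
RETENTION_A0 = 4.0
RETENTION_B = 6.0
RS_AMPLITUDE = 3.0
HUMP_K_HALF = 1.0
HUMP_DECAY = 20.0


def _rng_for(cfg: FixtureConfig, stream: str) -> np.random.Generator:
    # stable cross-process stream key (Python's str hash is salted)
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, key)))


def generate_descriptors(cfg: FixtureConfig) -> tuple[DescriptorMatrix, np.ndarray]:
    """Descriptor matrix plus the ground-truth informative mask.

    Informative columns (the first ``n_informative``) are continuous
    standard normals; the remaining columns cycle through small-integer
    counts, binary flags and continuous noise, none of which enters the
    chromatographic mechanism.
    """
    rng = np.random.default_rng(cfg.seed)
    n, v = cfg.n_compounds, cfg.n_descriptors
    values = np.empty((n, v))
    for j in range(v):
        if j < cfg.n_informative:
            values[:, j] = rng.normal(size=n)
        elif (j - cfg.n_informative) % 3 == 0:
            values[:, j] = rng.poisson(2.0, size=n)          # count-style
        elif (j - cfg.n_informative) % 3 == 1:
            values[:, j] = rng.binomial(1, 0.4, size=n)      # flag-style
        else:
            values[:, j] = rng.normal(size=n)                # continuous
    mask = np.zeros(v, dtype=bool)
    mask[:cfg.n_informative] = True
    ids = tuple(f"S{i + 1:03d}" for i in range(n))
    cols = tuple(f"x{j + 1}" for j in range(v))
    return DescriptorMatrix(ids, cols, values), mask


def _softplus(u):
    return np.log1p(np.exp(-np.abs(u))) + np.maximum(u, 0.0)


def _hump(k2):
    """Resolution envelope: zero at no retention, peak at moderate k2,
    slow decay at long retention."""
    return (k2 / (k2 + HUMP_K_HALF)) * np.exp(-k2 / HUMP_DECAY)


def generate_chromatograms(
    descriptors: DescriptorMatrix,
    informative_mask: np.ndarray,
    cfg: FixtureConfig,
    grid: MobilePhaseGrid = MobilePhaseGrid(),
) -> list:
    """Nine (Rs, k2) records per compound from the latent mechanism."""
    rng = _rng_for(cfg, "chromatograms")
    info = descriptors.values[:, np.asarray(informative_mask, dtype=bool)]
    n_info = info.shape[1]
    # fixed latent weights (per seed): retention and recognition scores
    w_r = rng.normal(size=n_info)
    w_r *= 0.8 / max(np.linalg.norm(w_r), 1e-12)
    w_c = rng.normal(size=n_info)
    w_c *= 1.0 / max(np.linalg.norm(w_c), 1e-12)
    r = info @ w_r                       # ~ N(0, 0.8) over compounds
    c = info @ w_c                       # ~ N(0, 1)
    # population gate: top resolved_fraction of the recognition score
    if cfg.resolved_fraction <= 0:
        gate = np.zeros(len(r), dtype=bool)
        c_shift = c
    elif cfg.resolved_fraction >= 1:
        gate = np.ones(len(r), dtype=bool)
        c_shift = c
    else:
        thresh = NormalDist(0.0, 1.0).inv_cdf(1.0 - cfg.resolved_fraction)
        gate = c > thresh
        c_shift = c - thresh
    records = []
    for i, cid in enumerate(descriptors.compound_ids):
        for mp in grid.indices:
            f_acn = grid.acn_fraction(mp)
            log_k2 = RETENTION_A0 + r[i] - RETENTION_B * f_acn + rng.normal(0, cfg.noise_sd)
            k2 = float(np.exp(log_k2))
            if gate[i]:
                rs = RS_AMPLITUDE * float(_softplus(c_shift[i] + 0.5)) * float(_hump(k2))
                rs += rng.normal(0, cfg.noise_sd)
            else:
                rs = abs(rng.normal(0, cfg.noise_sd))
            rs = max(0.0, round(rs, 1))
            k2 = max(0.0, round(k2, 1))
            k1 = round(k2 / (1.1 + 0.05 * rs), 1)
            records.append(ChromatogramRecord(cid, mp, rs, k2, k1=min(k1, k2)))
    return records


def generate_dataset(
    cfg: FixtureConfig = FixtureConfig(),
    params: EESParameters = EESParameters(),
) -> FixtureDataset:
    """Compose descriptors, chromatograms and the derived EES target
    matrix into one reproducible dataset."""
    descriptors, mask = generate_descriptors(cfg)
    chroms = generate_chromatograms(descriptors, mask, cfg)
    target = build_target_matrix(chroms, params)
    return FixtureDataset(
        descriptors=descriptors,
        chromatograms=tuple(chroms),
        target=target,
        informative_mask=mask,
    )


def write_dataset_bundle(dataset: FixtureDataset, directory, cfg: FixtureConfig | None = None) -> None:
    """Write descriptors.csv, chromatograms.csv, target.csv and the
    ground-truth JSON into a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_descriptors(dataset.descriptors, d / "descriptors.csv")
    write_chromatograms(list(dataset.chromatograms), d / "chromatograms.csv")
    write_target(dataset.target, d / "target.csv")
    truth = {
        "informative_columns": [
            c for c, m in zip(dataset.descriptors.columns, dataset.informative_mask) if m
        ],
    }
    if cfg is not None:
        truth["config"] = cfg.__dict__
    (d / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
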