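"""Population-based chaotic search over splits, topologies and features.

Each candidate solution is one continuous genome in [0,1]^74 (for 62
descriptors): ten split slots assigning compounds to the validation
(7) and internal-test (3) subsets, two topology genes, and one switch
gene per descriptor, binarized at a 0.8 cutoff.  Decoding is total:
any genome yields a valid disjoint split (rank decoding with
forward-cyclic collision repair), a legal topology, and a non-empty
feature mask (the single best switch is forced on if none pass the
cutoff).

The search itself follows a chaotic competitive-learning scheme:
offspring are built around the population best (shifted by a scaled
difference of two random members, perturbed by a logistic-map chaotic
signal whose amplitude anneals over iterations, and recombined
gene-wise with the parent) and compete pairwise with their parents —
the worse of each pair is discarded; stragglers far behind the field
are regenerated around the best.  Elitism keeps the incumbent best, so the best-so-far
trajectory is monotone.  The update constants are this package's own,
fixed by benchmarking on analytic surrogates, and the objective is
pluggable — the scientific content lives in the encoding and the
penalized objective, not in one metaheuristic's constants.

Candidate evaluation trains one network per genome and scores it with
the penalized objective on back-transformed predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .ann_engine import (
    ANNTopology,
    TrainedANN,
    TrainingConfig,
    load_model,
    predict_ann,
    save_model,
    train_ann,
)
from .data_model import (
    DescriptorMatrix,
    SubsetSplit,
    TargetMatrix,
    autoscale,
    validate_split,
)
from .ees_metric import EESParameters
from .objective import ObjectiveWeights, error_levels, fobj, pe_metric, pq_metric, q_index

__all__ = [
    "OptimizerConfig",
    "DecodedCandidate",
    "OptimizationRun",
    "OptimizationArchive",
    "decode_solution",
    "evaluate_candidate",
    "optimize_genomes",
    "optimize",
    "run_batch",
    "save_archive",
    "load_archive",
]

N_SPLIT_SLOTS = 10
N_TOPOLOGY_GENES = 2


@dataclass(frozen=True)
class OptimizerConfig:
    """Search-control parameters.

    Reference-scale values are population 250 and 500 iterations; the
    reduced defaults used in examples and tests trade thoroughness for
    wall time without changing semantics.
    """

    population: int = 250
    iterations: int = 500
    seed: int = 0
    binarize_cutoff: float = 0.8
    elitism: bool = True
    va_size: int = 7
    it_size: int = 3
    # internal search constants: differential weight toward the best,
    # per-gene crossover rate, logistic-map rate, chaotic amplitude
    # annealed geometrically start -> end, straggler-regeneration share
    de_f: float = 0.8
    de_cr: float = 0.7
    chaos_rate: float = 4.0
    chaos_amp_start: float = 0.3
    chaos_amp_end: float = 0.01
    regenerate_fraction: float = 0.1

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.binarize_cutoff < 1:
            raise ValueError("binarize_cutoff must lie in (0, 1)")


@dataclass(frozen=True)
class DecodedCandidate:
    split: SubsetSplit
    topology: ANNTopology
    feature_mask: np.ndarray

    @property
    def nv(self) -> int:
        return int(np.count_nonzero(self.feature_mask))


def genome_length(n_descriptors: int) -> int:
    return N_SPLIT_SLOTS + N_TOPOLOGY_GENES + n_descriptors


def decode_solution(
    vec: np.ndarray,
    n_compounds: int,
    n_descriptors: int,
    bounds: tuple = (30, 30),
    cutoff: float = 0.8,
    va_size: int = 7,
    it_size: int = 3,
) -> DecodedCandidate:
    """Decode a continuous genome into a split, topology and feature mask.

    Split slots map through ``floor(g * n)`` to compound indices, with
    forward-cyclic repair on collisions so the ten indices are always
    distinct: the first ``va_size`` become the validation subset, the
    next ``it_size`` the internal test, the remainder the training
    subset.  Topology genes map linearly: n1 = 1 + round(g * (n1_max-1)),
    n2 = round(g * n2_max).  Switch genes at or above ``cutoff`` select
    a descriptor; if none passes, the single highest gene is forced on.
    """
    vec = np.asarray(vec, dtype=float).ravel()
    expected = genome_length(n_descriptors)
    if vec.size != expected:
        raise ValueError(f"genome length {vec.size}, expected {expected}")
    if ((vec < 0) | (vec > 1)).any():
        raise ValueError("genes must lie in [0, 1]")
    if n_compounds <= N_SPLIT_SLOTS:
        raise ValueError(f"need more than {N_SPLIT_SLOTS} compounds, got {n_compounds}")

    # split slots: rank-unique decoding with forward-cyclic collision repair
    taken = np.zeros(n_compounds, dtype=bool)
    slots = []
    for g in vec[:N_SPLIT_SLOTS]:
        idx = min(int(np.floor(g * n_compounds)), n_compounds - 1)
        while taken[idx]:
            idx = (idx + 1) % n_compounds
        taken[idx] = True
        slots.append(idx)
    va = tuple(slots[:va_size])
    it = tuple(slots[va_size:va_size + it_size])
    tr = tuple(i for i in range(n_compounds) if not taken[i])

    n1_max, n2_max = bounds
    g1, g2 = vec[N_SPLIT_SLOTS:N_SPLIT_SLOTS + N_TOPOLOGY_GENES]
    topology = ANNTopology(n1=1 + round(g1 * (n1_max - 1)), n2=round(g2 * n2_max))

    switches = vec[N_SPLIT_SLOTS + N_TOPOLOGY_GENES:]
    mask = switches >= cutoff
    if not mask.any():
        mask = np.zeros(n_descriptors, dtype=bool)
        mask[int(np.argmax(switches))] = True

    split = validate_split(SubsetSplit(tr, va, it), n_compounds, sizes=(va_size, it_size))
    return DecodedCandidate(split=split, topology=topology, feature_mask=mask)


def evaluate_candidate(
    vec: np.ndarray,
    x: DescriptorMatrix,
    t: TargetMatrix,
    train_cfg: TrainingConfig = TrainingConfig(),
    weights: ObjectiveWeights = ObjectiveWeights(),
    params: EESParameters = EESParameters(),
    cutoff: float = 0.8,
    va_size: int = 7,
    it_size: int = 3,
) -> tuple[TrainedANN, float]:
    """Decode a genome, train the encoded network, and score it.

    Autoscales descriptors and targets over all compounds, trains on
    the decoded split, back-transforms predictions to EES units and
    computes per-subset Q, pQ, the graded error penalty pE,
    misclassification counts against the acceptability threshold, and
    the combined objective.  Deterministic given the genome and seeds.
    """
    if x.compound_ids != t.compound_ids:
        raise ValueError("descriptor and target matrices must list the same compounds in order")
    cand = decode_solution(
        vec, x.n_compounds, x.n_descriptors, cutoff=cutoff, va_size=va_size, it_size=it_size
    )
    x_scaled, x_scaler = autoscale(x.values)
    t_scaled, t_scaler = autoscale(t.values)
    model = train_ann(
        x_scaled[:, cand.feature_mask],
        t_scaled,
        cand.split,
        cand.topology,
        train_cfg,
        feature_mask=cand.feature_mask,
        x_scaler=x_scaler,
        t_scaler=t_scaler,
    )

    y = predict_ann(model, x.values, clip=False)  # unclipped inside the objective
    t_true = t.values
    qs = {}
    misclass = {}
    n = x.n_compounds
    row_labels = cand.split.labels(n)
    cell_labels = np.repeat(row_labels, t_true.shape[1])
    for sub in ("tr", "va", "it"):
        rows = [i for i in range(n) if row_labels[i] == sub]
        qs[sub] = q_index(y[rows], t_true[rows])
        pred_ok = y[rows] >= params.threshold
        true_ok = t_true[rows] >= params.threshold
        misclass[sub] = int(np.count_nonzero(pred_ok != true_ok))
    pq = pq_metric(qs["tr"], qs["va"], qs["it"], p_overfit=weights.p_overfit)
    counts = error_levels(y, t_true, cell_labels)
    pe = pe_metric(counts)
    f = fobj(pq, pe, weights)
    model.metrics = {
        "q_tr": qs["tr"], "q_va": qs["va"], "q_it": qs["it"],
        "pq": pq, "pe": pe, "fobj": f,
        "misclass_tr": misclass["tr"], "misclass_va": misclass["va"],
        "misclass_it": misclass["it"],
        "misclass_total": misclass["tr"] + misclass["va"] + misclass["it"],
        "error_levels": counts.__dict__.copy(),
        "nv": cand.nv,
    }
    return model, f


def optimize_genomes(
    objective: Callable[[np.ndarray], float],
    n_genes: int,
    cfg: OptimizerConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Maximize an arbitrary objective over [0,1]^n_genes.

    Returns (best genome, best value, best-so-far history with one
    entry per iteration).  This is the search core; ANN evaluation is
    just one objective that can be plugged in, which also makes the
    optimizer testable against analytic surrogates.
    """
    rng = np.random.default_rng(cfg.seed)
    P, G = cfg.population, n_genes
    pop = rng.uniform(0.0, 1.0, size=(P, G))
    # chaos states away from the logistic map's fixed points
    chaos = rng.uniform(0.05, 0.95, size=(P, G))
    fitness = np.array([objective(pop[i]) for i in range(P)])
    best_i = int(np.argmax(fitness))
    best_vec = pop[best_i].copy()
    best_f = float(fitness[best_i])

    history = []
    n_regen = max(1, int(cfg.regenerate_fraction * P))
    for it in range(cfg.iterations):
        frac = it / max(1, cfg.iterations - 1)
        amp = cfg.chaos_amp_start * (cfg.chaos_amp_end / cfg.chaos_amp_start) ** frac
        chaos = cfg.chaos_rate * chaos * (1.0 - chaos)
        stragglers = set(np.argsort(fitness)[:n_regen].tolist())
        for i in range(P):
            if i in stragglers:
                # local regeneration around the incumbent best
                trial = best_vec + amp * rng.uniform(-1.0, 1.0, size=G)
            else:
                # best-guided differential move with chaotic perturbation,
                # recombined gene-wise with the parent
                r1, r2 = rng.choice(P, 2, replace=False)
                mutant = (
                    best_vec
                    + cfg.de_f * (pop[r1] - pop[r2])
                    + amp * (chaos[i] - 0.5)
                )
                cross = rng.uniform(0.0, 1.0, size=G) < cfg.de_cr
                cross[rng.integers(G)] = True
                trial = np.where(cross, mutant, pop[i])
            np.clip(trial, 0.0, 1.0, out=trial)
            trial_f = objective(trial)
            # parent-offspring competition: the worse of the pair is dropped
            if trial_f > fitness[i] or (not cfg.elitism and trial_f == fitness[i]):
                pop[i] = trial
                fitness[i] = trial_f
                if trial_f > best_f:
                    best_f = float(trial_f)
                    best_vec = trial.copy()
        if not cfg.elitism:
            gen_best = int(np.argmax(fitness))
            best_f = float(fitness[gen_best])
            best_vec = pop[gen_best].copy()
        history.append(best_f)
    return best_vec, best_f, history


@dataclass
class OptimizationRun:
    """Outcome of one optimizer run: the best model and its provenance."""

    model: TrainedANN
    best_genome: np.ndarray
    best_fobj: float
    history: list
    seed: int


@dataclass
class OptimizationArchive:
    """Batch of independently optimized networks, sorted by objective."""

    runs: list = field(default_factory=list)

    @property
    def models(self) -> list:
        return [r.model for r in self.runs]

    def sorted_by_fobj(self) -> "OptimizationArchive":
        return OptimizationArchive(sorted(self.runs, key=lambda r: -r.best_fobj))


def optimize(
    x: DescriptorMatrix,
    t: TargetMatrix,
    cfg: OptimizerConfig = OptimizerConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
    weights: ObjectiveWeights = ObjectiveWeights(),
    params: EESParameters = EESParameters(),
) -> OptimizationRun:
    """Run one seeded search over splits, topologies and feature masks.

    The network trainer is seeded from the optimizer seed so a run is
    fully reproducible end to end.
    """
    t_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2 ** 31))
    tcfg = replace(train_cfg, seed=t_seed)

    def fobj_of(vec: np.ndarray) -> float:
        _, f = evaluate_candidate(
            vec, x, t, tcfg, weights, params,
            cutoff=cfg.binarize_cutoff, va_size=cfg.va_size, it_size=cfg.it_size,
        )
        return f

    n_genes = genome_length(x.n_descriptors)
    best_vec, best_f, history = optimize_genomes(fobj_of, n_genes, cfg)
    model, f = evaluate_candidate(
        best_vec, x, t, tcfg, weights, params,
        cutoff=cfg.binarize_cutoff, va_size=cfg.va_size, it_size=cfg.it_size,
    )
    return OptimizationRun(
        model=model, best_genome=best_vec, best_fobj=f, history=history, seed=cfg.seed
    )


def run_batch(
    x: DescriptorMatrix,
    t: TargetMatrix,
    n_runs: int,
    base_seed: int,
    cfg: OptimizerConfig = OptimizerConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
    weights: ObjectiveWeights = ObjectiveWeights(),
    params: EESParameters = EESParameters(),
) -> OptimizationArchive:
    """Independent optimizer runs with distinct derived seeds.

    The archive is returned sorted by objective, best first; rerunning
    with the same base seed reproduces it exactly.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n_runs) % (2 ** 31)
    runs = []
    for s in child_seeds:
        run = optimize(x, t, replace(cfg, seed=int(s)), train_cfg, weights, params)
        runs.append(run)
    return OptimizationArchive(runs).sorted_by_fobj()


def save_archive(archive: OptimizationArchive, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    index = []
    for i, run in enumerate(archive.runs):
        sub = d / f"model_{i:03d}"
        save_model(run.model, sub)
        (sub / "run.json").write_text(json.dumps({
            "seed": run.seed,
            "best_fobj": run.best_fobj,
            "best_genome": run.best_genome.tolist(),
            "history": run.history,
        }, sort_keys=True))
        index.append({"path": sub.name, "seed": run.seed, "best_fobj": run.best_fobj})
    (d / "archive.json").write_text(json.dumps({"runs": index}, indent=1, sort_keys=True))


def load_archive(directory) -> OptimizationArchive:
    d = Path(directory)
    index = json.loads((d / "archive.json").read_text())
    runs = []
    for entry in index["runs"]:
        sub = d / entry["path"]
        model = load_model(sub)
        meta = json.loads((sub / "run.json").read_text())
        runs.append(OptimizationRun(
            model=model,
            best_genome=np.asarray(meta["best_genome"], dtype=float),
            best_fobj=meta["best_fobj"],
            history=meta["history"],
            seed=meta["seed"],
        ))
    return OptimizationArchive(runs)
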