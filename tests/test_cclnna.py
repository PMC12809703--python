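import numpy as np
import pytest

from ees_profile.ann_engine import TrainingConfig
from ees_profile.cclnna import (
    OptimizerConfig,
    decode_solution,
    evaluate_candidate,
    genome_length,
    load_archive,
    optimize_genomes,
    run_batch,
    save_archive,
)

G74 = genome_length(62)


def _genome(**overrides):
    v = np.full(G74, 0.5)
    for pos, val in overrides.items():
        v[int(pos)] = val
    return v


class TestDecode:
    def test_genome_length_is_74_for_62_descriptors(self):
        assert G74 == 74

    def test_switch_cutoff(self):
        v = np.zeros(G74)
        v[12] = 0.85   # first descriptor switch
        v[13] = 0.79
        cand = decode_solution(v, 76, 62)
        assert cand.feature_mask[0] and not cand.feature_mask[1]

    def test_topology_lower_bound(self):
        v = np.zeros(G74)
        v[12] = 0.9
        cand = decode_solution(v, 76, 62)
        assert (cand.topology.n1, cand.topology.n2) == (1, 0)

    def test_topology_upper_bound(self):
        v = np.zeros(G74)
        v[10] = v[11] = 1.0
        v[12] = 0.9
        cand = decode_solution(v, 76, 62)
        assert (cand.topology.n1, cand.topology.n2) == (30, 30)

    def test_empty_mask_repaired_to_highest_switch(self):
        v = np.zeros(G74)
        v[12:] = np.linspace(0.0, 0.5, 62)[::-1]  # max at first switch
        cand = decode_solution(v, 76, 62)
        assert cand.feature_mask[0] and cand.feature_mask.sum() == 1

    def test_split_collision_repair(self):
        v = np.zeros(G74)  # all split genes hit index 0 -> cyclic repair
        v[12] = 0.9
        cand = decode_solution(v, 76, 62)
        assert cand.split.va == (0, 1, 2, 3, 4, 5, 6)
        assert cand.split.it == (7, 8, 9)

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError, match="compounds"):
            decode_solution(np.full(G74, 0.5), 10, 62)

    def test_random_genomes_always_decode_to_valid_disjoint_splits(self, rng):
        """10,000 random genomes all yield 7/3/66 disjoint splits."""
        genomes = rng.uniform(0, 1, size=(10_000, G74))
        for v in genomes:
            cand = decode_solution(v, 76, 62)
            assert len(cand.split.va) == 7
            assert len(cand.split.it) == 3
            assert len(cand.split.tr) == 66
            combined = set(cand.split.tr) | set(cand.split.va) | set(cand.split.it)
            assert len(combined) == 76
            assert cand.nv >= 1


class TestEvaluate:
    def test_deterministic_given_seeds(self, small_dataset):
        v = np.random.default_rng(3).uniform(0, 1, G74)
        cfg = TrainingConfig(seed=5, max_epochs=50)
        _, f1 = evaluate_candidate(v, small_dataset.descriptors, small_dataset.target, cfg)
        _, f2 = evaluate_candidate(v, small_dataset.descriptors, small_dataset.target, cfg)
        assert f1 == f2

    def test_metrics_attached(self, small_dataset):
        v = np.random.default_rng(3).uniform(0, 1, G74)
        model, f = evaluate_candidate(
            v, small_dataset.descriptors, small_dataset.target, TrainingConfig(seed=5, max_epochs=50)
        )
        m = model.metrics
        assert m["fobj"] == f
        assert set(m) >= {"q_tr", "q_va", "q_it", "pq", "pe", "misclass_total", "nv"}
        assert m["nv"] == model.nv

    def test_informative_descriptor_beats_noise(self, small_dataset):
        """A model allowed only the signal-carrying descriptors outscores one
        restricted to pure-noise descriptors."""
        cfg = TrainingConfig(seed=5, max_epochs=200)
        v_info = np.full(G74, 0.1)
        v_info[12:17] = 0.9           # the 5 informative switches
        v_noise = np.full(G74, 0.1)
        v_noise[40:45] = 0.9          # 5 noise switches
        x, t = small_dataset.descriptors, small_dataset.target
        _, f_info = evaluate_candidate(v_info, x, t, cfg)
        _, f_noise = evaluate_candidate(v_noise, x, t, cfg)
        assert f_info > f_noise


class TestOptimizeGenomes:
    def test_sphere_surrogate_convergence(self):
        """Seeded search localizes the known optimum of a separable
        quadratic within 0.05 per gene."""
        def sphere(v):
            return -float(np.sum((v - 0.5) ** 2))

        for seed in (1, 2, 3):
            best, _, history = optimize_genomes(
                sphere, 74, OptimizerConfig(population=30, iterations=200, seed=seed)
            )
            assert np.abs(best - 0.5).max() < 0.05
            assert len(history) == 200
            assert all(b >= a for a, b in zip(history, history[1:]))

    def test_genomes_stay_in_unit_cube(self):
        seen = []

        def spy(v):
            seen.append(v.copy())
            return -float(np.sum(v ** 2))

        optimize_genomes(spy, 10, OptimizerConfig(population=5, iterations=20, seed=0))
        stacked = np.stack(seen)
        assert stacked.min() >= 0.0 and stacked.max() <= 1.0


@pytest.fixture(scope="module")
def tiny_archive(small_dataset):
    cfg = OptimizerConfig(population=6, iterations=4)
    tcfg = TrainingConfig(max_epochs=30)
    return run_batch(
        small_dataset.descriptors, small_dataset.target,
        n_runs=3, base_seed=9, cfg=cfg, train_cfg=tcfg,
    )


class TestRunBatch:
    def test_distinct_seeds_and_descending_order(self, tiny_archive):
        seeds = [r.seed for r in tiny_archive.runs]
        assert len(set(seeds)) == 3
        fobjs = [r.best_fobj for r in tiny_archive.runs]
        assert fobjs == sorted(fobjs, reverse=True)

    def test_rerun_reproduces_archive(self, small_dataset, tiny_archive):
        again = run_batch(
            small_dataset.descriptors, small_dataset.target,
            n_runs=3, base_seed=9,
            cfg=OptimizerConfig(population=6, iterations=4),
            train_cfg=TrainingConfig(max_epochs=30),
        )
        for a, b in zip(tiny_archive.runs, again.runs):
            assert a.best_fobj == b.best_fobj
            assert np.array_equal(a.best_genome, b.best_genome)

    def test_archive_serialization_round_trip(self, tiny_archive, tmp_path):
        save_archive(tiny_archive, tmp_path / "arch")
        back = load_archive(tmp_path / "arch")
        assert len(back.runs) == 3
        for a, b in zip(tiny_archive.runs, back.runs):
            assert a.best_fobj == pytest.approx(b.best_fobj)
            assert a.model.metrics["misclass_total"] == b.model.metrics["misclass_total"]
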