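"""Binary field decoding, clonal expansion bookkeeping, elitism, and
optimizer behavior on surrogate and SVM affinities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunotexture import (
    IaConfig,
    clone_and_mutate,
    decode_field,
    encode_field,
    init_population,
    run_optimization,
    select_next_generation,
)
from immunotexture.errors import ParameterError, StateError
from immunotexture.immune import SvmAffinityEvaluator, make_antibody


class TestDecodeField:
    def test_all_zero_gives_lower(self):
        assert decode_field(np.zeros(8, dtype=int), -5.0, 15.0) == -5.0

    def test_all_one_gives_upper(self):
        assert decode_field(np.ones(8, dtype=int), -5.0, 15.0) == 15.0

    def test_three_bit_example(self):
        # first bit least significant: (1,0,1) -> 1 + 4 = 5 on a 0..7 grid
        assert decode_field(np.array([1, 0, 1]), 0.0, 7.0) == pytest.approx(5.0)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ParameterError):
            decode_field(np.array([1, 0]), 3.0, 1.0)

    def test_bijection_over_all_8bit_patterns(self):
        """Every pattern maps to a distinct grid value; round-trip is identity."""
        values = set()
        for k in range(256):
            bits = (k >> np.arange(8)) & 1
            x = decode_field(bits, -2.0, 2.0)
            values.add(round(x, 12))
            np.testing.assert_array_equal(encode_field(x, -2.0, 2.0, 8), bits)
        assert len(values) == 256

    @given(
        st.integers(min_value=1, max_value=12),
        st.integers(min_value=0),
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0.5, max_value=100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_integer_value(self, l, k, lower, width):
        k = k % (2**l)
        bits_k = (k >> np.arange(l)) & 1
        x = decode_field(bits_k, lower, lower + width)
        assert lower <= x <= lower + width
        if k + 1 < 2**l:
            bits_next = ((k + 1) >> np.arange(l)) & 1
            assert decode_field(bits_next, lower, lower + width) > x


class TestPopulation:
    def test_reproducible_from_seed(self):
        cfg = IaConfig(seed=3)
        p1 = init_population(cfg, np.random.default_rng(3))
        p2 = init_population(cfg, np.random.default_rng(3))
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.bits, b.bits)

    def test_default_protocol_size(self):
        cfg = IaConfig()
        pop = init_population(cfg, np.random.default_rng(0))
        assert len(pop) == 5
        assert all(ab.bits.size == 32 * 8 for ab in pop)

    def test_decoded_bounds_and_mask(self):
        cfg = IaConfig()
        for ab in init_population(cfg, np.random.default_rng(1)):
            assert 2.0**-5 <= ab.c <= 2.0**15
            assert 2.0**-15 <= ab.r <= 2.0**3
            assert ab.feature_mask.sum() >= 1

    def test_empty_mask_repaired(self):
        cfg = IaConfig()
        bits = np.zeros(cfg.n_bits, dtype=np.uint8)  # all features off
        ab = make_antibody(bits, cfg, np.random.default_rng(0))
        assert ab.feature_mask.sum() == 1


class TestCloneAndSelect:
    def _evaluated_pop(self, cfg, affs):
        pop = init_population(cfg, np.random.default_rng(0))
        for ab, a in zip(pop, affs):
            ab.affinity = a
        return pop

    def test_protocol_clone_count(self):
        """5 parents at 10x/30x yield exactly 30 + 4*10 = 70 clones."""
        cfg = IaConfig()
        pop = self._evaluated_pop(cfg, [0.5, 0.9, 0.4, 0.3, 0.2])
        clones = clone_and_mutate(pop, cfg, np.random.default_rng(0))
        assert len(clones) == 70
        assert sum(c.parent_index == 1 for c in clones) == 30

    def test_parents_unmutated(self):
        cfg = IaConfig()
        pop = self._evaluated_pop(cfg, [0.5, 0.9, 0.4, 0.3, 0.2])
        before = [ab.bits.copy() for ab in pop]
        clone_and_mutate(pop, cfg, np.random.default_rng(0))
        for ab, b in zip(pop, before):
            np.testing.assert_array_equal(ab.bits, b)

    def test_expected_mutation_rate(self):
        """Per-bit flip rate 1/n: with n=8 a 256-bit clone flips ~32 bits."""
        cfg = IaConfig()
        pop = self._evaluated_pop(cfg, [0.5, 0.9, 0.4, 0.3, 0.2])
        rng = np.random.default_rng(5)
        clones = clone_and_mutate(pop, cfg, rng)
        flips = [
            np.sum(c.bits != pop[c.parent_index].bits) for c in clones
        ]
        assert np.mean(flips) == pytest.approx(256 / 8, rel=0.15)

    def test_deterministic_given_seed(self):
        cfg = IaConfig()
        pop = self._evaluated_pop(cfg, [0.5, 0.9, 0.4, 0.3, 0.2])
        c1 = clone_and_mutate(pop, cfg, np.random.default_rng(9))
        c2 = clone_and_mutate(pop, cfg, np.random.default_rng(9))
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.bits, b.bits)

    def test_unevaluated_rejected(self):
        cfg = IaConfig()
        pop = init_population(cfg, np.random.default_rng(0))
        with pytest.raises(StateError):
            clone_and_mutate(pop, cfg, np.random.default_rng(0))

    def test_selection_keeps_better_clone_and_parent(self):
        cfg = IaConfig()
        pop = self._evaluated_pop(cfg, [0.5, 0.9, 0.4, 0.3, 0.2])
        clones = clone_and_mutate(pop, cfg, np.random.default_rng(0))
        for c in clones:
            c.affinity = 0.1  # all clones worse
        nxt = select_next_generation(pop, clones, cfg)
        assert len(nxt) == 5
        assert [ab.affinity for ab in nxt] == [0.5, 0.9, 0.4, 0.3, 0.2]

        better = clones[0]
        better.affinity = 0.95
        nxt = select_next_generation(pop, clones, cfg)
        assert nxt[better.parent_index].affinity == 0.95


def _surrogate(optimum=(7.0, -3.0)):
    def fn(ab):
        x, y = np.log2(ab.c), np.log2(ab.r)
        val = 1.0 - ((x - optimum[0]) ** 2 + (y - optimum[1]) ** 2) / (20**2 + 18**2)
        ab.affinity = val
        return val

    return fn


class TestRunOptimization:
    def test_elitism_monotone_over_many_generations(self):
        cfg = IaConfig(seed=2, max_generations=500)
        _, hist = run_optimization(None, cfg, affinity_fn=_surrogate())
        best = np.array(hist.best_affinity)
        assert (np.diff(best) >= 0).all()
        assert len(best) <= 500

    def test_target_affinity_stops_immediately(self):
        cfg = IaConfig(seed=0, max_generations=100, target_affinity=1e-9)
        _, hist = run_optimization(None, cfg, affinity_fn=_surrogate())
        assert len(hist.generation) == 1

    def test_surrogate_convergence_within_one_percent(self):
        """Decoded C parameter converges to the analytic optimum."""
        for seed in range(5):
            cfg = IaConfig(seed=seed, max_generations=200)
            best, _ = run_optimization(None, cfg, affinity_fn=_surrogate())
            rel_err = abs(np.log2(best.c) - 7.0) / 20.0
            assert rel_err < 0.01

    def test_beats_random_search_equal_budget(self):
        cfg_proto = IaConfig(max_generations=50)
        wins = 0
        for seed in range(5):
            cfg = IaConfig(seed=seed, max_generations=50)
            best, hist = run_optimization(None, cfg, affinity_fn=_surrogate())
            budget = cfg.n_groups + (len(hist.generation) - 1) * 70
            rng = np.random.default_rng(10_000 + seed)
            fn = _surrogate()
            rand_best = max(
                fn(make_antibody(rng.integers(0, 2, cfg.n_bits, dtype=np.uint8), cfg, rng))
                for _ in range(budget)
            )
            wins += best.affinity >= rand_best
        assert wins >= 4

    def test_population_size_and_length_conserved(self):
        cfg = IaConfig(seed=1, max_generations=20)
        pops = []

        fn = _surrogate()

        def spy(ab):
            return fn(ab)

        best, hist = run_optimization(None, cfg, affinity_fn=spy)
        assert all(s.bits.size == cfg.n_bits for s in hist.best_snapshot)


class TestSvmAffinity:
    def test_separable_data_high_affinity(self, blob_dataset):
        cfg = IaConfig(seed=0)
        ab = make_antibody(np.ones(cfg.n_bits, dtype=np.uint8), cfg)
        ab.c, ab.r = 1.0, 0.1
        assert SvmAffinityEvaluator(blob_dataset)(ab) >= 0.95

    def test_permuted_labels_chance_level(self, blob_dataset):
        from immunotexture import LabeledDataset, assign_folds

        cfg = IaConfig(seed=0)
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = rng.permutation(blob_dataset.labels)
            data = LabeledDataset(
                features=blob_dataset.features,
                labels=labels,
                fold_id=assign_folds(labels, seed=seed),
            )
            ab = make_antibody(np.ones(cfg.n_bits, dtype=np.uint8), cfg)
            ab.c, ab.r = 1.0, 1.0 / 30
            accs.append(SvmAffinityEvaluator(data)(ab))
        assert np.mean(accs) == pytest.approx(1.0 / 3.0, abs=0.1)

    def test_cached_evaluation_identical(self, blob_dataset):
        cfg = IaConfig(seed=0)
        ev = SvmAffinityEvaluator(blob_dataset)
        ab = make_antibody(np.ones(cfg.n_bits, dtype=np.uint8), cfg)
        v1 = ev(ab)
        fits = ev.n_fits
        v2 = ev(ab)
        assert v1 == v2
        assert ev.n_fits == fits  # cache hit, no extra SVM trainings
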