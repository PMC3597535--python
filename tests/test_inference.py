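import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deap_pathways.expression import (ExpressionStudy, expression_summary)
from deap_pathways.inference import (NullSample, RotationConfig,
                                     random_rotation, rotate_study,
                                     rotated_summaries, rotation_pvalue,
                                     storey_qvalues)
from deap_pathways.scoring import deap_statistic
from deap_pathways.simulation import SimulationSpec, simulate_study

from conftest import chain_graph


def paired_study(matrix, proteins=None):
    matrix = np.asarray(matrix, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(matrix.shape[0])]
    columns = [f"S{j}" for j in range(matrix.shape[1])]
    values = pd.DataFrame(matrix, index=proteins, columns=columns)
    design = pd.DataFrame({"condition": "log-ratio"}, index=columns)
    return ExpressionStudy(values, design, mode="paired")


class TestRandomRotation:
    def test_dimension_one_is_plus_or_minus_one(self):
        rng = np.random.default_rng(0)
        draws = {float(random_rotation(1, rng)[0, 0]) for _ in range(50)}
        assert draws <= {1.0, -1.0}
        assert len(draws) == 2  # sign-fixing keeps both signs reachable

    def test_orthogonality(self):
        rng = np.random.default_rng(1)
        for dim in (2, 5, 10, 17):
            q = random_rotation(dim, rng)
            assert np.abs(q @ q.T - np.eye(dim)).max() < 1e-10

    def test_uniformity_on_the_sphere(self):
        # Q v has mean ~0 for a fixed unit vector when Q is Haar.
        rng = np.random.default_rng(2)
        v = np.zeros(5)
        v[0] = 1.0
        total = np.zeros(5)
        n = 10_000
        for _ in range(n):
            total += random_rotation(5, rng) @ v
        assert np.abs(total / n).max() < 0.03

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            random_rotation(0, np.random.default_rng(0))


class TestRotateStudy:
    def test_identity_rotation_returns_study_unchanged(self):
        study = paired_study(np.arange(12.0).reshape(3, 4))
        config = RotationConfig(n_rotations=1)
        rotated = rotate_study(study, config, np.random.default_rng(0),
                               rotation=np.eye(4))
        assert np.allclose(rotated.values.to_numpy(),
                           study.values.to_numpy())

    def test_intercept_nuisance_preserves_row_means(self):
        rng = np.random.default_rng(3)
        study = paired_study(rng.standard_normal((6, 8)))
        config = RotationConfig(n_rotations=1, nuisance=np.ones((8, 1)))
        rotated = rotate_study(study, config, rng)
        assert np.allclose(rotated.values.mean(axis=1),
                           study.values.mean(axis=1))

    def test_residual_variance_preserved(self):
        rng = np.random.default_rng(4)
        study = paired_study(rng.standard_normal((5, 10)))
        config = RotationConfig(n_rotations=1, nuisance=np.ones((10, 1)))
        rotated = rotate_study(study, config, rng)
        original = study.values.to_numpy()
        new = rotated.values.to_numpy()
        var0 = original.var(axis=1)
        var1 = new.var(axis=1)
        assert np.abs(var0 - var1).max() < 1e-8

    def test_rank_deficient_nuisance_rejected(self):
        study = paired_study(np.zeros((2, 6)))
        nuisance = np.ones((6, 2))  # duplicated column
        config = RotationConfig(n_rotations=1, nuisance=nuisance)
        with pytest.raises(ValueError, match="rank"):
            rotate_study(study, config, np.random.default_rng(0))

    def test_fast_paired_stream_matches_full_rotation(self):
        rng_a = np.random.default_rng(9)
        rng_b = np.random.default_rng(9)
        study = paired_study(np.random.default_rng(5).standard_normal((4, 6)))
        config = RotationConfig(n_rotations=3, seed=9)
        summaries = rotated_summaries(study, config, rng_a)
        for summary in summaries:
            rotated = rotate_study(study, config, rng_b)
            expected = expression_summary(rotated)
            got = np.array([summary.values[p] for p in study.values.index])
            want = np.array([expected.values[p] for p in study.values.index])
            assert np.allclose(got, want)


class TestRotationPvalue:
    def test_plus_one_formula(self):
        # A statistic strictly dominating every rotation gives 1/(R+1).
        graph = chain_graph(3, "++")
        study = paired_study(np.zeros((3, 6)) + [[50.0], [50.0], [50.0]],
                             proteins=["N1", "N2", "N3"])
        config = RotationConfig(n_rotations=99, seed=0)
        p, nulls = rotation_pvalue(graph, study, config=config)
        assert p == pytest.approx(1.0 / 100.0)
        assert len(nulls) == 99
        assert np.all(nulls.statistics >= 0)

    def test_zero_statistic_has_pvalue_one(self):
        graph = chain_graph(3, "++")
        study = paired_study(np.zeros((3, 6)), proteins=["N1", "N2", "N3"])
        config = RotationConfig(n_rotations=50, seed=1)
        p, _ = rotation_pvalue(graph, study, config=config)
        assert p == 1.0

    def test_plain_proportion_flag(self):
        graph = chain_graph(3, "++")
        study = paired_study(np.full((3, 6), 50.0),
                             proteins=["N1", "N2", "N3"])
        config = RotationConfig(n_rotations=99, seed=0, plus_one=False)
        p, _ = rotation_pvalue(graph, study, config=config)
        assert p == 0.0

    def test_generic_summary_fn_path_agrees(self):
        graph = chain_graph(3, "++")
        rng = np.random.default_rng(6)
        study = paired_study(rng.standard_normal((3, 8)),
                             proteins=["N1", "N2", "N3"])
        config = RotationConfig(n_rotations=40, seed=7)
        p_fast, _ = rotation_pvalue(graph, study, config=config)
        p_slow, _ = rotation_pvalue(graph, study,
                                    summary_fn=expression_summary,
                                    config=config)
        assert p_fast == p_slow


class TestStoreyQvalues:
    def test_all_ones_stay_one(self):
        assert np.all(storey_qvalues([1.0, 1.0, 1.0]) == 1.0)

    def test_empty_input(self):
        assert storey_qvalues([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=200))
    def test_qvalue_order_matches_pvalue_order_and_range(self, pvals):
        q = storey_qvalues(pvals)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_near_one_for_uniform_pvalues(self):
        # q(max p) = pi0 * max p ~ pi0; on uniform p-values the estimate is
        # noisy by construction, so check the median over seeded draws.
        estimates = []
        for seed in range(11):
            p = np.random.default_rng(seed).uniform(size=1000)
            q = storey_qvalues(p)
            estimates.append(q[np.argmax(p)] / p.max())
        assert 0.85 <= float(np.median(estimates)) <= 1.0

    def test_signal_mixture_yields_small_qvalues(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(size=900),
                            rng.uniform(0, 1e-4, size=100)])
        q = storey_qvalues(p)
        assert q[900:].max() < 0.01
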