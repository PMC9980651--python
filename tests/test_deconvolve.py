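import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import methyldeconv as md


def make_model(a: np.ndarray, cell_types=None, probes=None):
    a = np.asarray(a, dtype=float)
    cell_types = cell_types or [f"T{k}" for k in range(a.shape[1])]
    probes = probes or [f"p{j}" for j in range(a.shape[0])]
    return md.DeconvolutionModel(
        pd.DataFrame(a, index=probes, columns=cell_types)
    )


def simplex_grid(n: int, step: float = 0.01):
    """All points on the unit simplex with coordinates in multiples of step."""
    units = int(round(1.0 / step))
    if n == 2:
        for i in range(units + 1):
            yield np.array([i, units - i]) / units
    elif n == 3:
        for i in range(units + 1):
            for j in range(units - i + 1):
                yield np.array([i, j, units - i - j]) / units
    else:
        raise NotImplementedError


class TestProjectProportions:
    def test_pure_cell_type_bulk(self, model):
        for ct in model.cell_types:
            bulk = model.mean_profiles[ct]
            props = md.project_proportions(model, bulk)
            assert props[ct] == pytest.approx(1.0, abs=1e-6)
            others = props.drop(ct)
            assert (others.abs() < 1e-6).all()

    def test_two_probe_closed_form(self):
        model = make_model([[0.0, 1.0], [1.0, 0.0]])
        bulk = pd.Series([0.3, 0.7], index=["p0", "p1"])
        props = md.project_proportions(model, bulk)
        assert props.to_numpy() == pytest.approx([0.7, 0.3], abs=1e-9)

    def test_three_type_mixture_recovery(self, model):
        weights = np.array([0.2, 0.5, 0.3])
        cols = model.cell_types[:3]
        bulk = (model.mean_profiles[cols] @ weights).rename("mix")
        props = md.project_proportions(model, bulk)
        expected = pd.Series(0.0, index=model.cell_types)
        expected[cols] = weights
        assert np.abs(props - expected).max() < 1e-6

    @pytest.mark.parametrize("mode", [md.NONNEG, md.NONNEG_SUM_LE_1])
    @pytest.mark.parametrize("n_types,n_probes,seed", [
        (2, 4, 0), (2, 10, 1), (3, 6, 2), (3, 10, 3), (3, 10, 4),
    ])
    def test_beats_simplex_grid_search(self, mode, n_types, n_probes, seed):
        """The constrained solution is at least as good as every point of a
        1e-2 simplex grid (brute-force optimality oracle)."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(n_probes, n_types))
        b = rng.uniform(size=n_probes)
        model = make_model(a)
        bulk = pd.Series(b, index=model.mean_profiles.index)
        props = md.project_proportions(model, bulk, constraint_mode=mode)
        achieved = np.sum((a @ props.to_numpy() - b) ** 2)
        best_grid = min(
            np.sum((a @ p - b) ** 2) for p in simplex_grid(n_types)
        )
        assert achieved <= best_grid + 1e-9

    def test_nonneg_matches_independent_bounded_solver(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(size=(12, 4))
        b = rng.uniform(size=12)
        model = make_model(a)
        bulk = pd.Series(b, index=model.mean_profiles.index)
        props = md.project_proportions(model, bulk)
        oracle = optimize.lsq_linear(a, b, bounds=(0.0, np.inf))
        assert props.to_numpy() == pytest.approx(oracle.x, abs=1e-8)

    def test_sum_constraint_binds(self):
        # bulk scaled above the hull forces the unconstrained sum past 1
        model = make_model([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]])
        bulk = pd.Series([1.0, 1.0, 0.8], index=["p0", "p1", "p2"])
        free = md.project_proportions(model, bulk, md.NONNEG)
        assert free.sum() > 1.0
        capped = md.project_proportions(model, bulk, md.NONNEG_SUM_LE_1)
        assert capped.sum() <= 1.0 + 1e-8
        assert (capped >= -1e-12).all()
        # optimal among the simplex grid too
        a = model.mean_profiles.to_numpy()
        achieved = np.sum((a @ capped.to_numpy() - bulk.to_numpy()) ** 2)
        best_grid = min(
            np.sum((a @ p - bulk.to_numpy()) ** 2) for p in simplex_grid(2)
        )
        assert achieved <= best_grid + 1e-9

    def test_permutation_equivariance(self, model):
        rng = np.random.default_rng(5)
        bulk = pd.Series(
            rng.uniform(size=model.n_sites), index=model.mean_profiles.index
        )
        base = md.project_proportions(model, bulk)
        perm = list(reversed(model.cell_types))
        permuted_model = md.DeconvolutionModel(model.mean_profiles[perm])
        swapped = md.project_proportions(permuted_model, bulk)
        assert swapped.loc[base.index].to_numpy() == pytest.approx(
            base.to_numpy(), abs=1e-9
        )

    def test_zero_shared_probes_is_an_error(self, model):
        bulk = pd.Series([0.5], index=["not_a_probe"])
        with pytest.raises(ValueError, match="no marker probe"):
            md.project_proportions(model, bulk)

    def test_low_coverage_warns(self, model):
        keep = model.mean_profiles.index[: model.n_sites // 2]
        bulk = model.mean_profiles.loc[keep, model.cell_types[0]]
        with pytest.warns(UserWarning, match="marker probes"):
            md.project_proportions(model, bulk)

    def test_rank_deficiency_warns(self):
        a = np.array([[0.2, 0.2], [0.8, 0.8], [0.5, 0.5]])
        model = make_model(a)
        bulk = pd.Series([0.2, 0.8, 0.5], index=["p0", "p1", "p2"])
        with pytest.warns(UserWarning, match="rank deficient"):
            md.project_proportions(model, bulk)

    def test_unknown_mode_rejected(self, model):
        bulk = model.mean_profiles[model.cell_types[0]]
        with pytest.raises(ValueError, match="constraint_mode"):
            md.project_proportions(model, bulk, constraint_mode="simplex")


class TestExpectedProfile:
    def test_zero_proportions_give_zero_profile(self, model):
        out = md.expected_profile(model, np.zeros(6))
        assert (out == 0).all()

    def test_one_hot_returns_column(self, model):
        ct = model.cell_types[2]
        p = pd.Series(0.0, index=model.cell_types)
        p[ct] = 1.0
        out = md.expected_profile(model, p)
        assert out.to_numpy() == pytest.approx(
            model.mean_profiles[ct].to_numpy()
        )

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(5, 3))
        model = make_model(a)
        p = rng.uniform(size=3)
        out = md.expected_profile(model, p)
        for j in range(5):
            assert out.iloc[j] == pytest.approx(
                sum(p[k] * a[j, k] for k in range(3)), abs=1e-12
            )

    def test_length_mismatch_and_negative_rejected(self, model):
        with pytest.raises(ValueError, match="proportions"):
            md.expected_profile(model, np.zeros(3))
        with pytest.raises(ValueError, match="non-negative"):
            md.expected_profile(model, np.array([-0.1, 0.3, 0.2, 0.2, 0.2, 0.2]))


class TestCetygoScore:
    def test_perfect_fit_scores_zero(self):
        assert md.cetygo_score([0.2, 0.4], [0.2, 0.4]) == 0.0

    def test_hand_worked_value(self):
        value = md.cetygo_score([0.5, 0.5], [0.1, 0.3])
        assert value == pytest.approx(np.sqrt((0.16 + 0.04) / 2), abs=1e-12)
        assert round(value, 5) == 0.31623

    @given(
        delta=st.floats(-0.5, 0.5),
        m=st.integers(1, 40),
    )
    @settings(deadline=None, max_examples=50)
    def test_constant_offset_scores_its_magnitude(self, delta, m):
        obs = np.full(m, 0.5)
        assert md.cetygo_score(obs, obs + delta) == pytest.approx(
            abs(delta), abs=1e-12
        )

    def test_empty_and_mismatched_vectors_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            md.cetygo_score([], [])
        with pytest.raises(ValueError, match="equal-length"):
            md.cetygo_score([0.1], [0.1, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.data())
    @settings(deadline=None, max_examples=50)
    def test_always_non_negative(self, obs, data):
        exp = data.draw(
            st.lists(st.floats(0, 1), min_size=len(obs), max_size=len(obs))
        )
        assert md.cetygo_score(obs, exp) >= 0.0


class TestBatchDeconvolution:
    def test_failure_isolation(self, model):
        rng = np.random.default_rng(0)
        bulk = pd.DataFrame(
            rng.uniform(size=(model.n_sites, 3)),
            index=model.mean_profiles.index,
            columns=["s1", "s2", "s3"],
        )
        bulk["s2"] = np.nan  # all marker probes missing for s2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = md.deconvolve_with_error(model, bulk)
        assert [r.ok for r in results] == [True, False, True]
        assert "no marker probe" in results[1].error
        assert results[1].sample_id == "s2"

    def test_single_sample_equals_atomic_composition(self, model):
        rng = np.random.default_rng(1)
        bulk = pd.Series(
            rng.uniform(size=model.n_sites),
            index=model.mean_profiles.index,
            name="s",
        )
        (result,) = md.deconvolve_with_error(model, bulk)
        props = md.project_proportions(model, bulk)
        expected = md.expected_profile(model, props)
        score = md.cetygo_score(
            bulk.loc[expected.index], expected
        )
        assert result.proportions.to_numpy() == pytest.approx(
            props.to_numpy(), abs=1e-12
        )
        assert result.cetygo == pytest.approx(score, abs=1e-12)
        assert result.n_sites_used == model.n_sites

    def test_batch_scores_match_atomic_recomputation(self, model):
        rng = np.random.default_rng(7)
        bulk = pd.DataFrame(
            rng.uniform(size=(model.n_sites, 20)),
            index=model.mean_profiles.index,
            columns=[f"s{i}" for i in range(20)],
        )
        results = md.deconvolve_with_error(model, bulk)
        for r in results:
            expected = md.expected_profile(model, r.proportions)
            assert r.cetygo == pytest.approx(
                md.cetygo_score(bulk[r.sample_id], expected), abs=1e-12
            )

    def test_results_frame_layout(self, model):
        bulk = model.mean_profiles[model.cell_types[0]].rename("pure")
        frame = md.results_to_frame(md.deconvolve_with_error(model, bulk))
        assert list(frame["sample_id"]) == ["pure"]
        for ct in model.cell_types:
            assert ct in frame.columns
        assert {"proportion_sum", "cetygo", "n_sites_used",
                "constraint_mode"} <= set(frame.columns)
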