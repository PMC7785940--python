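"""Fuzzification geometry, spline fitting, SRM selection, rule extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phytomedia import datasets
from phytomedia.neurofuzzy import (
    LABELS,
    NeurofuzzyRegressor,
    SubModelStructure,
    fuzzify,
    model_anova,
    ridge_fit,
    srm_score,
    submodel_design_matrix,
    train_r2,
)
from phytomedia.stoichiometry import ION_NAMES, round_half_away
from phytomedia.synthetic import independent_ion_table


class TestFuzzify:
    def test_unit_interval_density2_symmetry(self):
        part = fuzzify(0.0, 1.0, 2)
        assert part.boundaries() == pytest.approx([0.5])
        ranges = part.dominance_ranges()
        assert ranges[0] == ("Low", 0.0, 0.5)
        assert ranges[1] == ("High", 0.5, 1.0)

    def test_ammonium_boundaries_match_published_ranges(self, ion_matrix):
        lo, hi = ion_matrix["NH4+"].min(), ion_matrix["NH4+"].max()
        d2 = fuzzify(lo, hi, 2, ion="NH4+")
        assert round_half_away(d2.boundaries()[0], 2) == 12.37
        d3 = fuzzify(lo, hi, 3, ion="NH4+")
        assert round_half_away(d3.boundaries()[0], 2) == 8.25
        assert round_half_away(d3.boundaries()[1], 2) == 16.49

    def test_nitrate_density3_boundaries(self, ion_matrix):
        lo, hi = ion_matrix["NO3-"].min(), ion_matrix["NO3-"].max()
        part = fuzzify(lo, hi, 3, ion="NO3-")
        assert round_half_away(part.boundaries(), 2) == pytest.approx(
            [14.35, 31.06])

    # every fuzzified (ion, density) range printed in the study's
    # dominance table, at that table's decimals
    PUBLISHED = [
        ("NH4+", 2, 2, [12.37]), ("NH4+", 3, 2, [8.25, 16.49]),
        ("NO3-", 2, 2, [22.71]), ("NO3-", 3, 2, [14.35, 31.06]),
        ("K+", 2, 2, [12.37]),
        ("Mg2+", 3, 2, [1.41, 3.47]),
        ("PO43-", 3, 2, [1.17, 2.89]),
        ("SO42-", 2, 2, [2.85]), ("SO42-", 3, 2, [1.67, 4.02]),
        ("Cl-", 2, 2, [9.73]),
        ("Fe2+", 2, 2, [0.30]),
        ("BO3-", 2, 2, [0.08]), ("BO3-", 3, 2, [0.05, 0.12]),
        ("MoO22-", 2, 4, [0.0008]),
        ("Na+", 2, 2, [0.60]),
        ("I-", 2, 3, [0.004]), ("I-", 3, 3, [0.002, 0.006]),
    ]

    @pytest.mark.parametrize("ion, density, decimals, expected", PUBLISHED)
    def test_all_published_dominance_boundaries(self, ion, density, decimals,
                                                expected, ion_matrix):
        lo, hi = ion_matrix[ion].min(), ion_matrix[ion].max()
        got = fuzzify(lo, hi, density, ion=ion).boundaries()
        for g, e in zip(got, expected):
            assert abs(round_half_away(g, decimals) - e) <= 10 ** (-decimals) + 1e-12

    @settings(max_examples=30, deadline=None)
    @given(lo=st.floats(-5, 5), span=st.floats(0.1, 10),
           density=st.sampled_from([2, 3]))
    def test_partition_of_unity(self, lo, span, density):
        part = fuzzify(lo, lo + span, density)
        x = np.linspace(lo, lo + span, 97)
        mu = part.membership(x)
        assert np.allclose(mu.sum(axis=1), 1.0)
        assert (mu >= 0).all()

    def test_dominance_intervals_tile_domain(self):
        for density in (2, 3):
            part = fuzzify(1.0, 7.0, density)
            ranges = part.dominance_ranges()
            assert ranges[0][1] == 1.0 and ranges[-1][2] == 7.0
            for (_, _, hi_a), (_, lo_b, _) in zip(ranges, ranges[1:]):
                assert hi_a == lo_b

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            fuzzify(1.0, 1.0, 2)
        with pytest.raises(ValueError):
            fuzzify(0.0, 1.0, 4)


class TestBases:
    def _parts(self, density=2):
        return {("a", density): fuzzify(0.0, 1.0, density, ion="a"),
                ("b", density): fuzzify(0.0, 1.0, density, ion="b")}

    def test_univariate_one_hot_at_domain_min(self):
        s = SubModelStructure(("a",), (2,))
        B = submodel_design_matrix(pd.DataFrame({"a": [0.0]}), s, self._parts())
        assert B.tolist() == [[1.0, 0.0]]

    def test_univariate_midpoint_half(self):
        s = SubModelStructure(("a",), (2,))
        B = submodel_design_matrix(pd.DataFrame({"a": [0.5]}), s, self._parts())
        assert B.tolist() == [[0.5, 0.5]]

    def test_tensor_midpoints_quarter(self):
        s = SubModelStructure(("a", "b"), (2, 2))
        B = submodel_design_matrix(pd.DataFrame({"a": [0.5], "b": [0.5]}),
                                   s, self._parts())
        assert np.allclose(B, 0.25)

    def test_rows_sum_to_one(self):
        s = SubModelStructure(("a", "b"), (2, 2))
        X = pd.DataFrame({"a": np.linspace(0, 1, 13),
                          "b": np.linspace(1, 0, 13)})
        B = submodel_design_matrix(X, s, self._parts())
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_structure_invariants(self):
        with pytest.raises(ValueError):
            SubModelStructure(("a", "b", "c", "d", "e"), (2,) * 5)
        with pytest.raises(ValueError):
            SubModelStructure(("a",), (2, 3))


class TestRidgeFit:
    def test_constant_response_gives_constant_cells(self):
        B = fuzzify(0, 1, 2).membership(np.linspace(0, 1, 20))
        beta = ridge_fit(B, np.full(20, 3.0), 1e-6)
        assert beta == pytest.approx([3.0, 3.0], rel=1e-4)

    def test_interpolates_as_ridge_vanishes(self):
        B = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        y = np.array([1.0, 3.0, 2.0])
        beta = ridge_fit(B, y, 1e-10)
        assert np.allclose(B @ beta, y, atol=1e-6)

    def test_coefficients_shrink_with_ridge(self):
        rng = np.random.default_rng(0)
        B = rng.uniform(size=(30, 4))
        y = rng.uniform(size=30)
        norms = [np.linalg.norm(ridge_fit(B, y, r)) for r in (1e-6, 1e-2, 1.0)]
        assert norms[0] >= norms[1] >= norms[2]


class TestSrmScore:
    def test_zero_mse_zero_score(self):
        assert srm_score(0.0, 4, 34, 0.868, 4.8) == 0.0

    def test_monotone_in_p_and_mse(self):
        s = [srm_score(1.0, p, 34, 0.868, 4.8) for p in range(1, 30)]
        assert all(a < b for a, b in zip(s, s[1:]))
        assert srm_score(2.0, 4, 34, 0.868, 4.8) > srm_score(1.0, 4, 34,
                                                             0.868, 4.8)

    def test_matches_independent_rederivation(self):
        # closed form recomputed independently of the implementation
        mse, p, n, c1, c2 = 1.0, 4, 34, 0.868, 4.8
        expected = mse * (1 - c1) ** (-c2 * p / (3 * n))
        assert srm_score(mse, p, n, c1, c2) == pytest.approx(expected)

    def test_saturated_model_inadmissible(self):
        assert srm_score(0.5, 34, 34, 0.868, 4.8) == np.inf

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            srm_score(1.0, 2, 34, 1.2, 4.8)
        with pytest.raises(ValueError):
            srm_score(1.0, 0, 34, 0.868, 4.8)


class TestTrainR2:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 5.0])
        assert train_r2(y, y) == 100.0
        assert train_r2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        assert train_r2([1, 2, 3], [1, 2, 4]) == pytest.approx(50.0)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            train_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestModelAnova:
    def test_study_convention_reproduces_published_critical_values(self):
        for df1, expected in [(16, 3.558), (9, 4.255), (5, 5.382),
                              (11, 3.975), (7, 4.675)]:
            _, f_crit, _ = model_anova([1, 2, 3, 4], [1, 2, 3, 4.1],
                                       df1=df1, df2=33, convention="study")
            assert f_crit == pytest.approx(expected, abs=0.01)

    def test_f_ratio_consistent_with_published_r2(self):
        # published leaf-area fit: R^2 = 75.629%, df1 = 5, df2 = 33
        r2 = 0.75629
        f = (r2 / 5) / ((1 - r2) / (33 - 5))
        assert f == pytest.approx(17.378, abs=0.01)

    def test_pass_flag_flips_at_critical(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        f, crit, ok = model_anova(y, y * 0.9, df1=3, df2=19)
        assert ok == (f > crit)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            model_anova([1, 2], [1, 2], df1=0, df2=5)
        with pytest.raises(ValueError):
            model_anova([1, 2], [1, 2], df1=5, df2=5)


class TestAsmodSearch:
    def test_single_input_recovered_noise_free(self):
        X = independent_ion_table(n_runs=34, seed=3)
        part = fuzzify(X["Fe2+"].min(), X["Fe2+"].max(), 2, ion="Fe2+")
        y = 2.0 + 3.0 * part.membership(X["Fe2+"].to_numpy())[:, 1]
        model = NeurofuzzyRegressor().fit(X, y)
        assert model.active_ions_ == ("Fe2+",)
        assert model.r2_ > 99.9

    def test_submodel_size_respects_cap(self, ion_models):
        for model in ion_models.values():
            assert all(len(s.inputs) <= 4 for s in model.structures_)

    def test_study_fits_reach_the_reported_quality_floor(self, ion_models):
        for out, model in ion_models.items():
            assert model.r2_ >= 70.0, f"{out}: R^2 = {model.r2_:.1f}"

    def test_intercept_only_on_pure_replication_noise(self):
        """A constant truth observed through replicate noise should come
        back as intercept-only in the large majority of replicates."""
        import warnings

        from phytomedia.synthetic import sample_ground_truth, simulate

        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            truth = sample_ground_truth(seed=seed, n_active_ions=0,
                                        output="SN", noise_sd=0.7)
            ion = independent_ion_table(n_runs=34, seed=seed + 5000)
            design = pd.DataFrame(index=pd.RangeIndex(34, name="treatment"))
            exp = simulate(design, truth, seed=seed + 10000, ion_table=ion)
            vm = (exp.explant_values
                  .groupby(["treatment", "round", "vessel"])["value"].mean())
            pe = float((vm.groupby("treatment").var(ddof=1)
                        / vm.groupby("treatment").size()).mean())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = NeurofuzzyRegressor().fit(
                    exp.ion_table, exp.treatment_table["SN_mean"],
                    pure_error=pe)
            hits += len(m.submodels_) == 0
        assert hits / n_rep >= 0.8

    def test_too_few_runs_rejected(self):
        X = independent_ion_table(n_runs=5, seed=0)
        with pytest.raises(ValueError):
            NeurofuzzyRegressor().fit(X, np.arange(5.0))

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = NeurofuzzyRegressor(c1=0.8, ridge=1e-5)
        params = est.get_params()
        assert params["c1"] == 0.8
        cloned = clone(est)
        assert cloned.get_params() == params


class TestRules:
    def test_linear_univariate_rules_have_unit_membership(self):
        X = independent_ion_table(n_runs=34, seed=7)
        part = fuzzify(X["K+"].min(), X["K+"].max(), 2, ion="K+")
        y = 1.0 + 4.0 * part.membership(X["K+"].to_numpy())[:, 1]
        model = NeurofuzzyRegressor().fit(X, y)
        rules = model.extract_rules()
        by_label = {r["antecedent"]["K+"]: r for _, r in rules.iterrows()}
        assert by_label["Low"]["consequent"] == "Low"
        assert by_label["Low"]["MD"] == pytest.approx(1.0, abs=1e-6)
        assert by_label["High"]["consequent"] == "High"
        assert by_label["High"]["MD"] == pytest.approx(1.0, abs=1e-6)

    def test_corner_maximal_surface_yields_corner_rule(self):
        # a surface maximal at (Low, Low) must emit IF Low AND Low THEN High
        X = independent_ion_table(n_runs=34, seed=9)
        pa = fuzzify(X["Na+"].min(), X["Na+"].max(), 2, ion="Na+")
        pb = fuzzify(X["MoO22-"].min(), X["MoO22-"].max(), 2, ion="MoO22-")
        mu_a = pa.membership(X["Na+"].to_numpy())
        mu_b = pb.membership(X["MoO22-"].to_numpy())
        y = 1.0 + 5.0 * mu_a[:, 0] * mu_b[:, 0]
        model = NeurofuzzyRegressor().fit(X, y)
        rules = model.extract_rules()
        corner = rules[rules["antecedent"].map(
            lambda a: a.get("Na+") == "Low" and a.get("MoO22-") == "Low")]
        assert len(corner) == 1
        assert corner.iloc[0]["consequent"] == "High"
        assert corner.iloc[0]["MD"] == pytest.approx(1.0, abs=1e-6)

    def test_memberships_match_bruteforce_normalization(self, ion_models):
        for model in ion_models.values():
            rules = model.extract_rules()
            for s_idx, (s, coef) in enumerate(model.submodels_):
                sub = rules[rules["submodel"] == s_idx]
                lo, hi = coef.min(), coef.max()
                if np.isclose(hi, lo):
                    continue
                labels_product = list(itertools.product(
                    *[LABELS[d] for d in s.densities]))
                for (labels, pred), (_, row) in zip(
                        zip(labels_product, coef), sub.iterrows()):
                    t = (pred - lo) / (hi - lo)
                    expected = t if t >= 0.5 else 1 - t
                    assert abs(row["MD"] - expected) < 1e-9
                    assert 0.0 <= row["MD"] <= 1.0

    def test_dominance_ranges_cover_used_ions(self, ion_models):
        for model in ion_models.values():
            table = model.dominance_ranges()
            assert set(table["ion"]) == set(model.active_ions_)
            for (_, dens), grp in table.groupby(["ion", "density"]):
                assert list(grp["label"]) == list(LABELS[dens])
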