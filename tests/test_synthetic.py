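"""Ground-truth sampling and hierarchical experiment simulation."""

import numpy as np
import pandas as pd
import pytest

from phytomedia import datasets
from phytomedia.synthetic import (
    ORDINAL_LEVELS,
    RESPONSE_RANGES,
    independent_ion_table,
    recovery_benchmark,
    sample_ground_truth,
    simulate,
)


def _design(n=34):
    return pd.DataFrame(index=pd.RangeIndex(n, name="treatment"))


class TestGroundTruth:
    def test_seed_determinism(self):
        a = sample_ground_truth(seed=5)
        b = sample_ground_truth(seed=5)
        assert a.active_ions == b.active_ions
        for (sa, ca), (sb, cb) in zip(a.submodels, b.submodels):
            assert sa == sb and np.array_equal(ca, cb)

    def test_zero_active_ions_is_constant(self):
        truth = sample_ground_truth(seed=1, n_active_ions=0, output="SL")
        X = independent_ion_table(n_runs=10, seed=2)
        vals = truth.evaluate(X)
        assert np.allclose(vals, vals[0])

    def test_declared_active_set_retrievable(self):
        truth = sample_ground_truth(seed=3, n_active_ions=4, max_order=2)
        assert len(truth.active_ions) == 4
        assert truth.active_subsets  # non-empty partition of the set

    def test_forced_submodel_sizes(self):
        truth = sample_ground_truth(seed=0, n_active_ions=4,
                                    submodel_sizes=(2, 2))
        assert sorted(len(s.inputs) for s, _ in truth.submodels) == [2, 2]
        with pytest.raises(ValueError):
            sample_ground_truth(seed=0, n_active_ions=4,
                                submodel_sizes=(2, 3))

    def test_response_range_scaling(self):
        truth = sample_ground_truth(seed=7, output="LA", n_active_ions=3)
        X = independent_ion_table(n_runs=512, seed=8)
        vals = truth.evaluate(X)
        lo, hi = RESPONSE_RANGES["LA"]
        # span calibrated on a probe sample, so allow sampling slack
        assert 0.5 * (hi - lo) <= np.ptp(vals) <= 1.3 * (hi - lo)
        assert lo - 5 < vals.mean() < hi + 5


class TestSimulate:
    def test_zero_noise_zero_sd(self):
        truth = sample_ground_truth(seed=0, output="SL", noise_sd=0.0)
        exp = simulate(_design(8), truth, seed=1,
                       ion_table=independent_ion_table(8, seed=1))
        assert np.allclose(exp.treatment_table["SL_sd"], 0.0)

    def test_replicate_hierarchy_counts(self):
        truth = sample_ground_truth(seed=0, output="SL")
        exp = simulate(_design(4), truth, seed=1,
                       ion_table=independent_ion_table(4, seed=1))
        counts = exp.explant_values.groupby("treatment").size()
        assert (counts == 3 * 5 * 3).all()  # rounds x vessels x explants

    def test_sd_column_matches_explant_values(self):
        truth = sample_ground_truth(seed=2, output="SL", noise_sd=0.2)
        exp = simulate(_design(6), truth, seed=3,
                       ion_table=independent_ion_table(6, seed=3))
        by_hand = exp.explant_values.groupby("treatment")["value"].std()
        assert np.allclose(exp.treatment_table["SL_sd"], by_hand)

    @pytest.mark.parametrize("output", ["SQ", "BC", "H"])
    def test_ordinal_outputs_stay_on_their_scales(self, output):
        lo, hi = RESPONSE_RANGES[output]
        truth = sample_ground_truth(seed=4, output=output, noise_sd=1.0)
        exp = simulate(_design(6), truth, seed=5,
                       ion_table=independent_ion_table(6, seed=5))
        vals = exp.explant_values["value"]
        assert vals.between(1, ORDINAL_LEVELS[output]).all()
        assert vals.dtype.kind in "if"

    def test_treatment_means_converge_to_truth(self):
        """Law of large numbers: with many explants the treatment mean
        approaches the noise-free truth within 3 standard errors."""
        truth = sample_ground_truth(seed=6, output="SL", noise_sd=0.3)
        ion = independent_ion_table(3, seed=7)
        exp = simulate(_design(3), truth, seed=8, ion_table=ion,
                       n_vessels=40, n_explants=10, n_rounds=3)
        mu = truth.evaluate(ion)
        n_vessel_groups = 40 * 3
        se = np.sqrt(0.3 ** 2 / (40 * 10 * 3)
                     + (0.15 ** 2) / n_vessel_groups)
        got = exp.treatment_table["SL_mean"].to_numpy()
        assert np.all(np.abs(got - mu) < 3 * se + 1e-9)

    def test_table_schema_is_dropin_for_study_table(self):
        truth = sample_ground_truth(seed=0, output="SN")
        exp = simulate(_design(5), truth, seed=1,
                       ion_table=independent_ion_table(5, seed=1))
        cols = list(exp.treatment_table.columns)
        study_cols = list(datasets.load_treatments().columns)
        assert cols[0] == "media"
        assert cols[1:19] == study_cols[1:19]  # the 18 ion columns
        assert cols[19:] == ["SN_mean", "SN_sd"]


class TestRecovery:
    def test_noise_free_separable_univariates_recovered(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = recovery_benchmark(seeds=range(8), noise_grid=(0.0,),
                                     n_active_ions=2, max_order=1)
        assert rep["covered"].mean() >= 0.85

    def test_recovery_degrades_with_noise(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = recovery_benchmark(seeds=range(8), noise_grid=(0.05, 0.5))
        rate = rep.groupby("noise")["recovered"].mean()
        assert rate.loc[0.5] <= rate.loc[0.05] + 1e-9

    def test_report_reproducible_per_seed(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = recovery_benchmark(seeds=[3], noise_grid=(0.1,))
            b = recovery_benchmark(seeds=[3], noise_grid=(0.1,))
        pd.testing.assert_frame_equal(a, b)
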