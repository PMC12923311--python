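"""Group statistics: closed-form examples, null calibration, invariances."""

import numpy as np
import pandas as pd
import pytest

from nbceus.stats import (
    PhaseConfig,
    compare_groups,
    correlation_matrix,
    glass_delta,
    pearson_corr,
    phase_average,
    welch_t,
)


class TestWelchT:
    def test_identical_groups_null(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_example(self):
        a = [1, 2, 3, 4, 5]
        b = [2, 4, 6, 8, 10]
        t, df, p = welch_t(a, b)
        assert t == pytest.approx(3.0 / np.sqrt(2.5), rel=1e-12)  # 1.897367
        assert df == pytest.approx(6.25 / 1.0625, rel=1e-12)  # 5.882353
        from scipy import stats as sstats

        ref = sstats.ttest_ind(b, a, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_large_equal_variance_limit_matches_pooled(self, rng):
        from scipy import stats as sstats

        a = rng.normal(0, 1, 500)
        b = rng.normal(0.1, 1, 500)
        _, _, p_welch = welch_t(a, b)
        p_pooled = sstats.ttest_ind(b, a, equal_var=True).pvalue
        assert p_welch == pytest.approx(p_pooled, abs=1e-3)

    def test_degenerate_inputs(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_calibrated_under_null(self):
        """Empirical rejection rate at alpha=0.05 within 0.05 +/- 0.02."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 1, 10)
            _, _, p = welch_t(a, b)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestGlassDelta:
    def test_equal_means_zero(self):
        assert glass_delta([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_example(self):
        assert glass_delta([8.0, 10.0, 12.0], [2.0, 4.0, 6.0]) == pytest.approx(3.0)

    def test_sign_convention(self):
        assert glass_delta([0.0, 1.0], [5.0, 6.0, 7.0]) < 0

    def test_shift_invariance_and_control_scaling(self, rng):
        treated = rng.normal(3, 1, 8)
        control = rng.normal(0, 2, 8)
        d = glass_delta(treated, control)
        assert glass_delta(treated + 10, control + 10) == pytest.approx(d, rel=1e-12)
        assert glass_delta(treated * 2, control * 2) == pytest.approx(d, rel=1e-12)

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValueError):
            glass_delta([1.0, 2.0], [3.0, 3.0])


class TestPearson:
    def test_perfect_linear(self):
        r = pearson_corr([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert r.r == pytest.approx(1.0)

    def test_hand_example(self):
        r = pearson_corr([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0])
        assert r.r == pytest.approx(0.8, rel=1e-12)

    def test_constant_variable_missing(self):
        r = pearson_corr([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert np.isnan(r.r)

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.uniform(0, 1, 20)
        y = rng.uniform(0, 1, 20)
        assert pearson_corr(x, y).r == pytest.approx(pearson_corr(y, x).r, rel=1e-12)
        assert pearson_corr(3 * x + 2, y).r == pytest.approx(pearson_corr(x, y).r, rel=1e-12)

    def test_log10_drops_nonpositive_pairs(self):
        x = [1.0, 10.0, 100.0, -1.0]
        y = [1.0, 10.0, 100.0, 50.0]
        r = pearson_corr(x, y, transform="log10")
        assert r.n == 3
        assert r.r == pytest.approx(1.0)

    def test_spearman_escape_hatch(self, rng):
        x = rng.uniform(0, 1, 15)
        y = x**3  # monotone, nonlinear
        r = pearson_corr(x, y, method="spearman")
        assert r.r == pytest.approx(1.0)


def _metric_table():
    rows = []
    for animal, group, values in (
        ("s1", "sham", [1, 2, 3, 4, 5, 6]),
        ("s2", "sham", [2, 2, 2, 4, 4, 4]),
        ("i1", "iri", [1, 2, 3, 10, 11, 12]),
        ("i2", "iri", [2, 3, 4, 12, 13, 14]),
    ):
        for aq, v in enumerate(values, start=1):
            rows.append(
                {"animal_id": animal, "group": group, "acquisition": aq, "metric": "m", "value": float(v)}
            )
    return pd.DataFrame(rows)


class TestPhaseAverage:
    def test_hand_example(self):
        table = _metric_table()
        ph = phase_average(table)
        early_s1 = ph.query("animal_id=='s1' and acquisition=='early'")["value"].item()
        assert early_s1 == pytest.approx(2.0)

    def test_partial_acquisitions_averaged_over_available(self):
        table = _metric_table()
        # animal i2 dies after acquisition 5
        table = table[~((table.animal_id == "i2") & (table.acquisition == 6))]
        ph = phase_average(table)
        late_i2 = ph.query("animal_id=='i2' and acquisition=='late'")["value"].item()
        assert late_i2 == pytest.approx((12 + 13) / 2)

    def test_matches_groupby_oracle(self, rng):
        table = _metric_table()
        ph = phase_average(table)
        oracle = (
            table.assign(phase=np.where(table.acquisition <= 3, "early", "late"))
            .groupby(["animal_id", "phase"])["value"]
            .mean()
        )
        for _, row in ph.iterrows():
            assert row["value"] == pytest.approx(oracle[row["animal_id"], row["acquisition"]])

    def test_phases_must_be_disjoint(self):
        with pytest.raises(ValueError):
            PhaseConfig(early_acquisitions={1, 2}, late_acquisitions={2, 3})


class TestCompareGroups:
    def test_identical_groups_zero_delta(self):
        rows = []
        for animal, group in (("a", "sham"), ("b", "sham"), ("c", "iri"), ("d", "iri")):
            for v in (1.0, 2.0):
                rows.append({"animal_id": animal, "group": group, "metric": "m", "value": v})
        # same per-animal values in both groups
        table = pd.DataFrame(rows).groupby(["animal_id", "group", "metric"], as_index=False).mean()
        out = compare_groups(table)
        assert out["glass_delta"].iloc[0] == pytest.approx(0.0)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_row_order_invariance(self):
        table = _metric_table()
        a = compare_groups(table)
        b = compare_groups(table.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(a, b)

    def test_late_phase_separates_synthetic_groups(self):
        ph = phase_average(_metric_table())
        out = compare_groups(ph).set_index("acquisition")
        assert out.loc["late", "p_value"] < 0.05
        assert out.loc["late", "glass_delta"] > 0.8
        assert out.loc["early", "p_value"] > 0.05


class TestCorrelationMatrix:
    def _tables(self, rng, noise=0.0):
        sev = np.array([0.02, 0.05, 0.1, 0.2, 0.3, 0.4])
        imaging = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(6)],
                "group": ["sham"] * 3 + ["iri"] * 3,
                "acquisition": ["late"] * 6,
                "metric": "mean_dt_s",
                "value": 20 * sev,
            }
        )
        histology = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(6)],
                "group": imaging["group"],
                "neutrophil_density": 100 * sev * np.exp(noise * rng.standard_normal(6)),
                "extravascular_signal_density": 40 * sev,
                "tubular_injury_score": 1 + 9 * sev,
            }
        )
        return imaging, histology

    def test_noiseless_coupling_gives_unit_correlation(self, rng):
        imaging, histology = self._tables(rng)
        out = correlation_matrix(imaging, histology, transform="log10")
        sub = out[out.histology_metric == "neutrophil_density"]
        assert sub["r"].item() == pytest.approx(1.0, abs=1e-12)

    def test_permuted_labels_destroy_correlation(self, rng):
        imaging, histology = self._tables(rng)
        rs = []
        for seed in range(60):
            perm = histology.copy()
            perm["animal_id"] = np.random.default_rng(seed).permutation(
                perm["animal_id"].to_numpy()
            )
            out = correlation_matrix(imaging, perm, transform="log10")
            rs.append(out[out.histology_metric == "neutrophil_density"]["r"].item())
        assert abs(np.mean(rs)) < 0.15  # permutation null centred at zero
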