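"""Pearson estimator, per-gene correlation records and Table-style filters."""

import numpy as np
import pytest
from scipy import stats

from eqtm.core import (
    AnalysisConfig,
    DegenerateInputError,
    InsufficientDataError,
    OmicsMatrix,
)
from eqtm.correlation import (
    correlate_gene,
    feature_breakdown,
    pearson,
    pearson_rows,
    promoter_count,
    scatter_data,
    significant_records,
    table1_style_report,
)


def oracle_r(x, y):
    """Explicit covariance-formula Pearson coefficient."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))


class TestPearson:
    def test_perfect_correlation(self):
        r, p, n = pearson([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert (r, p, n) == (1.0, 0.0, 5)

    def test_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson(x, -x)[0] == -1.0

    def test_hand_oracle(self):
        x = [1, 2, 3, 4]
        y = [1.1, 1.9, 3.2, 3.8]
        assert pearson(x, y)[0] == pytest.approx(oracle_r(x, y), abs=1e-12)

    def test_matches_scipy_cor_test(self, rng):
        # scipy.stats.pearsonr as the independent cross-check
        for _ in range(50):
            n = rng.integers(3, 50)
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p, _ = pearson(x, y)
            rr, pp = stats.pearsonr(x, y)
            assert r == pytest.approx(rr, abs=1e-12)
            assert p == pytest.approx(pp, abs=1e-10)

    def test_affine_invariance_and_sign_flip(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = pearson(x, y)[0]
        assert pearson(3.5 * x + 2, y)[0] == pytest.approx(r0, abs=1e-12)
        assert pearson(x, 0.1 * y - 7)[0] == pytest.approx(r0, abs=1e-12)
        assert pearson(-x, y)[0] == pytest.approx(-r0, abs=1e-12)

    def test_pairwise_complete_dropping(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.2, 2.1, 3.0, 3.9, np.nan]
        r, p, n = pearson(x, y)
        assert n == 3
        assert r == pytest.approx(oracle_r([1, 2, 4], [1.2, 2.1, 3.9]), abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            pearson([1, 2], [3, 4])

    def test_zero_variance_is_error_not_nan(self):
        with pytest.raises(DegenerateInputError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_null_p_uniformity_at_cohort_size(self, rng):
        # two-sided p under rho=0 at n=24: rejection rate ~ alpha
        hits = 0
        sims = 2000
        for _ in range(sims):
            if pearson(rng.normal(size=24), rng.normal(size=24))[1] < 0.05:
                hits += 1
        assert 0.03 <= hits / sims <= 0.07


class TestPearsonRows:
    def test_matches_scalar_path(self, rng):
        M = rng.normal(size=(6, 15))
        y = rng.normal(size=15)
        r = pearson_rows(M, y)
        for i in range(6):
            assert r[i] == pytest.approx(pearson(M[i], y)[0], abs=1e-12)

    def test_nan_fallback(self, rng):
        M = rng.normal(size=(3, 10))
        M[1, 4] = np.nan
        y = rng.normal(size=10)
        r = pearson_rows(M, y)
        mask = np.isfinite(M[1])
        assert r[1] == pytest.approx(pearson(M[1][mask], y[mask])[0], abs=1e-12)


class TestCorrelateGene:
    def test_three_records_per_probe(self, small_cohort):
        meth, expr, sheet, annotations, _ = small_cohort
        records = correlate_gene("GENEA", meth, expr, annotations, sheet)
        assert len(records) == 3 * 3
        strata = {r.stratum for r in records}
        assert strata == {"POOLED", "GROUP1", "GROUP2"}

    def test_pooled_n_is_group_sum(self, small_cohort):
        meth, expr, sheet, annotations, _ = small_cohort
        records = correlate_gene("GENEA", meth, expr, annotations, sheet)
        by = {(r.probe_id, r.stratum): r for r in records}
        for probe in ("cgA1", "cgA2", "cgA3"):
            assert by[(probe, "POOLED")].n == by[(probe, "GROUP1")].n + by[(probe, "GROUP2")].n

    def test_absent_gene_is_lookup_error(self, small_cohort):
        meth, expr, sheet, annotations, _ = small_cohort
        with pytest.raises(LookupError, match="NOPE"):
            correlate_gene("NOPE", meth, expr, annotations, sheet)

    def test_constant_expression_yields_missing_records(self, small_cohort):
        meth, expr, sheet, annotations, _ = small_cohort
        expr.data.loc["GENEA"] = 5.0
        records = correlate_gene("GENEA", meth, expr, annotations, sheet)
        assert all(r.r is None and "variance" in r.note for r in records)

    def test_recovers_configured_sign(self, small_cohort):
        meth, expr, sheet, annotations, _ = small_cohort
        records = correlate_gene("GENEA", meth, expr, annotations, sheet)
        pooled = {r.probe_id: r.r for r in records if r.stratum == "POOLED"}
        assert pooled["cgA1"] > 0.4
        assert pooled["cgA2"] < -0.4

    def test_group_order_override(self, small_cohort):
        meth, expr, sheet, annotations, _ = small_cohort
        cfg = AnalysisConfig(group_order=("grp2", "grp1"))
        records = correlate_gene("GENEA", meth, expr, annotations, sheet, cfg)
        by = {(r.probe_id, r.stratum): r for r in records}
        assert by[("cgA1", "GROUP1")].n == 10  # grp2 has 10 samples


class TestFilters:
    def test_mobp_significant_negative_pooled(self, table1):
        annotations, records = table1
        mobp = [r for r in records if r.gene == "MOBP"]
        sig = significant_records(mobp, alpha=0.05, stratum="POOLED", sign="negative")
        assert len(sig) == 6
        bd = feature_breakdown(sig, annotations)
        assert bd == {"TSS1500": 4, "Body": 2}
        assert promoter_count(bd) == 4

    def test_hip1_significant_positive_pooled(self, table1):
        annotations, records = table1
        hip1 = [r for r in records if r.gene == "HIP1"]
        sig = significant_records(hip1, alpha=0.05, stratum="POOLED", sign="positive")
        assert len(sig) == 4
        assert feature_breakdown(sig, annotations) == {"Body": 4}

    def test_sorted_by_ascending_p(self, table1):
        _, records = table1
        sig = significant_records(records, alpha=0.05, stratum="MSA", sign="any")
        ps = [r.p for r in sig]
        assert ps == sorted(ps)

    def test_alpha_zero_is_empty(self, table1):
        _, records = table1
        assert significant_records(records, alpha=1e-300, stratum="POOLED") == []

    def test_feature_breakdown_empty_and_missing(self, table1):
        annotations, records = table1
        assert feature_breakdown([], annotations) == {}
        with pytest.raises(LookupError):
            feature_breakdown([records[0]], annotations[1:2])


class TestReporting:
    def test_table_style_report_layout(self, table1):
        annotations, records = table1
        rep = table1_style_report(records, annotations)
        assert len(rep) == 23
        assert {"r_POOLED", "p_MSA", "n_CTRL", "feature_cgi"} <= set(rep.columns)
        row = rep[rep.probe_id == "cg27103603"].iloc[0]
        assert row["feature_cgi"] == "Body-shore"
        assert row["r_POOLED"] == pytest.approx(-0.513)

    def test_scatter_data_shape(self, small_cohort):
        meth, expr, sheet, annotations, _ = small_cohort
        df = scatter_data("cgA1", "GENEA", meth, expr, sheet)
        assert list(df.columns) == ["sample_id", "group", "mvalue", "expression"]
        assert len(df) == 24
        assert set(df["group"]) == {"grp1", "grp2"}
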