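"""Opposite-correlation-sign statistic and its permutation null."""

import numpy as np
import pandas as pd
import pytest

from eqtm.core import (
    AnalysisConfig,
    ConfigError,
    CorrelationRecord,
    DiscordanceSummary,
    OmicsMatrix,
    SampleSheet,
    ValidationError,
)
from eqtm.discordance import gene_discordance, is_discordant, permutation_null


def records_from_pairs(pairs, gene="G"):
    """(r1, r2) per probe -> GROUP1/GROUP2 record list."""
    out = []
    for i, (r1, r2) in enumerate(pairs):
        out.append(CorrelationRecord(f"cg{i:03d}", gene, "GROUP1", r1, None, 10))
        out.append(CorrelationRecord(f"cg{i:03d}", gene, "GROUP2", r2, None, 10))
    return out


class TestIsDiscordant:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            (-0.48, 0.72, True),   # worked example: sign flip, both above cutoff
            (-0.69, 0.61, True),   # second worked example
            (0.8, 0.9, False),     # same sign
            (-0.3, 0.72, False),   # one magnitude below cutoff (both_exceed)
            (0.0, 0.9, False),     # exact zero never discordant
            (0.41, -0.40, True),
        ],
    )
    def test_both_exceed_rule(self, r1, r2, expected):
        assert is_discordant(r1, r2, cutoff=0.4, rule="both_exceed") is expected

    def test_either_exceeds_rule(self):
        assert is_discordant(-0.3, 0.72, cutoff=0.4, rule="either_exceeds")
        assert not is_discordant(-0.3, 0.35, cutoff=0.4, rule="either_exceeds")

    def test_missing_is_never_discordant(self):
        assert not is_discordant(None, 0.9)
        assert not is_discordant(0.9, float("nan"))

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            is_discordant(0.5, -0.5, rule="bogus")
        with pytest.raises(ValidationError):
            is_discordant(1.5, -0.5)


class TestGeneDiscordance:
    def test_seven_of_sixtyeight(self):
        # 7 sign-flipping CpGs above cutoff among 68
        pairs = [(-0.5, 0.6)] * 7 + [(0.5, 0.6)] * 61
        summary = gene_discordance(records_from_pairs(pairs))
        assert (summary.n_cpgs, summary.n_discordant) == (68, 7)
        assert summary.proportion == pytest.approx(0.103, abs=5e-4)

    def test_all_concordant_is_zero(self):
        summary = gene_discordance(records_from_pairs([(0.5, 0.6)] * 5))
        assert summary.proportion == 0.0

    def test_single_discordant_probe_is_one(self):
        summary = gene_discordance(records_from_pairs([(-0.9, 0.9)]))
        assert summary.proportion == 1.0
        assert summary.discordant_probe_ids == ["cg000"]

    def test_missing_r_counts_in_n_missing(self):
        recs = records_from_pairs([(-0.5, 0.6), (None, 0.9)])
        summary = gene_discordance(recs)
        assert (summary.n_cpgs, summary.n_discordant, summary.n_missing) == (2, 1, 1)

    def test_printed_reference_rows(self, table1):
        # the published per-group coefficients for the 17 printed HIP1 CpGs
        _, records = table1
        hip1 = [r for r in records if r.gene == "HIP1"]
        summary = gene_discordance(hip1, group_labels=("MSA", "CTRL"))
        assert summary.n_cpgs == 17
        assert summary.n_discordant == 5
        # both CpGs the publication quotes as examples are flagged
        assert {"cg03437706", "cg27409251"} <= set(summary.discordant_probe_ids)

    def test_mixed_gene_records_rejected(self):
        recs = records_from_pairs([(0.5, -0.6)], gene="A") + records_from_pairs(
            [(0.5, -0.6)], gene="B"
        )
        with pytest.raises(ValidationError):
            gene_discordance(recs)

    def test_cutoff_monotonicity(self, rng):
        cutoffs = np.linspace(0, 1, 21)
        for _ in range(50):
            pairs = list(zip(rng.uniform(-1, 1, 20), rng.uniform(-1, 1, 20)))
            recs = records_from_pairs(pairs)
            props = [
                gene_discordance(recs, AnalysisConfig(discordance_cutoff=c)).proportion
                for c in cutoffs
            ]
            assert all(a >= b for a, b in zip(props, props[1:]))


def _engineered_pool(n_discordant_by_gene: dict[str, int], n_cpgs=10, n_per_group=6):
    """Deterministic cohort whose genes have exact discordance proportions.

    Expression is a ramp; concordant CpGs copy it (r = 1 in both groups),
    discordant CpGs copy it in group1 and mirror it in group2 (r = +1 / -1).
    """
    n = 2 * n_per_group
    samples = [f"s{i}" for i in range(n)]
    g1 = np.arange(n) < n_per_group
    ramp = np.linspace(0.0, 1.0, n)
    meth_rows, expr_rows, annotations = {}, {}, []
    from eqtm.core import ProbeAnnotation

    for gi, (gene, k) in enumerate(n_discordant_by_gene.items()):
        expr_rows[gene] = ramp + gi  # distinct rows, same shape
        for j in range(n_cpgs):
            pid = f"{gene}_cg{j}"
            row = ramp.copy()
            if j < k:
                row[~g1] = 1.0 - ramp[~g1]  # mirrored in group2
            meth_rows[pid] = row
            annotations.append(ProbeAnnotation(pid, "1", 1000 + 100 * gi + j, gene, "Body", "opensea"))
    meth = OmicsMatrix("mvalue", pd.DataFrame(meth_rows, index=samples).T)
    expr = OmicsMatrix("expression", pd.DataFrame(expr_rows, index=samples).T)
    sheet = SampleSheet(
        groups=pd.Series(np.where(g1, "grp1", "grp2"), index=samples),
        covariates=pd.DataFrame(index=samples),
    )
    return meth, expr, sheet, annotations


class TestPermutationNull:
    def setup_method(self):
        self.pool_spec = {"GA": 0, "GB": 1, "GC": 2, "GD": 5, "GE": 6}
        self.inputs = _engineered_pool(self.pool_spec)

    def _observed(self, proportion):
        return DiscordanceSummary("T", 10, int(proportion * 10), proportion)

    def _run(self, observed, seed=1, n_perm=5):
        meth, expr, sheet, annotations = self.inputs
        cfg = AnalysisConfig(n_permutations=n_perm, seed=seed)
        return permutation_null(
            self._observed(observed), list(self.pool_spec), annotations, meth, expr, sheet, cfg
        )

    def test_exhaustive_pool_enumeration(self):
        # whole pool sampled without replacement: proportions {0,.1,.2,.5,.6}
        res = self._run(0.4)
        assert not res.with_replacement
        assert sorted(res.null_proportions) == [0.0, 0.1, 0.2, 0.5, 0.6]
        assert res.empirical_p == pytest.approx(2 / 5)

    def test_observed_zero_gives_p_one(self):
        assert self._run(0.0).empirical_p == 1.0

    def test_impossible_observed_gives_p_zero(self):
        meth, expr, sheet, annotations = self.inputs
        cfg = AnalysisConfig(n_permutations=5, seed=1)
        target = DiscordanceSummary("T", 10, 10, 1.0)
        target.proportion = 1.1  # above any attainable proportion
        res = permutation_null(target, list(self.pool_spec), annotations, meth, expr, sheet, cfg)
        assert res.empirical_p == 0.0

    def test_empirical_p_is_k_over_n(self):
        res = self._run(0.15, n_perm=5)
        assert res.empirical_p in {i / 5 for i in range(6)}

    def test_seed_reproducibility(self):
        a = self._run(0.4, seed=9, n_perm=3)
        b = self._run(0.4, seed=9, n_perm=3)
        c = self._run(0.4, seed=10, n_perm=3)
        assert a.null_proportions == b.null_proportions
        assert a.observed_proportion == c.observed_proportion

    def test_small_pool_samples_with_replacement(self):
        res = self._run(0.4, n_perm=50)
        assert res.with_replacement
        assert res.n_sampled == 50

    def test_unusable_genes_skipped(self):
        meth, expr, sheet, annotations = self.inputs
        cfg = AnalysisConfig(n_permutations=5, seed=1)
        res = permutation_null(
            self._observed(0.4),
            list(self.pool_spec) + ["GHOST"],  # no probes, no expression row
            annotations, meth, expr, sheet, cfg,
        )
        assert res.n_skipped == 1
        assert sorted(res.null_proportions) == [0.0, 0.1, 0.2, 0.5, 0.6]

    def test_empty_pool_rejected(self):
        meth, expr, sheet, annotations = self.inputs
        with pytest.raises(ConfigError):
            permutation_null(
                self._observed(0.4), [], annotations, meth, expr, sheet, AnalysisConfig()
            )

    def test_plus_one_smoothing_option(self):
        meth, expr, sheet, annotations = self.inputs
        cfg = AnalysisConfig(n_permutations=5, seed=1, plus_one_smoothing=True)
        res = permutation_null(
            self._observed(0.4), list(self.pool_spec), annotations, meth, expr, sheet, cfg
        )
        assert res.empirical_p == pytest.approx(3 / 6)
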