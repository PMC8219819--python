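"""Group-discordant correlation statistic and its random-gene permutation null.

A CpG is *discordant* when its methylation–expression correlations in the two
clinical groups have opposite signs with magnitudes above a cutoff (default
|r| >= 0.4 in both groups) — the signature of methylation-dependent
regulation being remodelled in one group. The per-gene statistic is the
proportion of the gene's CpGs that are discordant; its significance is
assessed empirically by recomputing the proportion for randomly sampled
genes and counting how often the sampled proportion reaches the observed
one.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .core import (
    AnalysisConfig,
    ConfigError,
    CorrelationRecord,
    DiscordanceSummary,
    OmicsMatrix,
    PermutationResult,
    ProbeAnnotation,
    SampleSheet,
    STRATUM_POOLED,
    ValidationError,
)
from .correlation import group_strata, pearson_rows

__all__ = ["is_discordant", "gene_discordance", "permutation_null"]

log = logging.getLogger(__name__)


def is_discordant(
    r1: float | None,
    r2: float | None,
    cutoff: float = 0.4,
    rule: str = "both_exceed",
) -> bool:
    """Opposite correlation signs above the magnitude cutoff.

    ``both_exceed``: both |r| >= cutoff. ``either_exceeds``: max |r| >=
    cutoff. A correlation of exactly 0 (or a missing one) is never
    discordant.
    """
    if rule not in ("both_exceed", "either_exceeds"):
        raise ConfigError(f"unknown discordance rule {rule!r}")
    if cutoff < 0:
        raise ConfigError("cutoff must be >= 0")
    if r1 is None or r2 is None or not (np.isfinite(r1) and np.isfinite(r2)):
        return False
    if not (-1 <= r1 <= 1 and -1 <= r2 <= 1):
        raise ValidationError(f"|r| > 1: ({r1}, {r2})")
    if r1 * r2 >= 0:  # same sign, or either exactly 0
        return False
    if rule == "both_exceed":
        return abs(r1) >= cutoff and abs(r2) >= cutoff
    return max(abs(r1), abs(r2)) >= cutoff


def _group_r_pairs(
    records: Iterable[CorrelationRecord],
    group_labels: tuple[str, str] | None = None,
) -> tuple[dict[str, tuple[float | None, float | None]], tuple[str, str]]:
    """Per-probe (r_group1, r_group2) from a record list, auto-detecting the
    two non-POOLED stratum labels when not given."""
    records = list(records)
    if group_labels is None:
        labels = sorted({r.stratum for r in records} - {STRATUM_POOLED})
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly 2 group strata besides {STRATUM_POOLED}, found {labels}"
            )
        group_labels = (labels[0], labels[1])
    pairs: dict[str, list[float | None]] = {}
    for rec in records:
        if rec.stratum not in group_labels:
            continue
        slot = group_labels.index(rec.stratum)
        pairs.setdefault(rec.probe_id, [None, None])[slot] = rec.r
    return {k: (v[0], v[1]) for k, v in pairs.items()}, group_labels


def gene_discordance(
    records: Iterable[CorrelationRecord],
    config: AnalysisConfig | None = None,
    group_labels: tuple[str, str] | None = None,
) -> DiscordanceSummary:
    """Count discordant CpGs of one gene and return the proportion.

    Probes missing r in either group stratum count toward n_cpgs and
    n_missing but are never discordant.
    """
    config = config or AnalysisConfig()
    records = list(records)
    genes = {r.gene for r in records}
    if len(genes) != 1:
        raise ValidationError(f"records must share one gene, found {sorted(genes)}")
    pairs, _ = _group_r_pairs(records, group_labels)
    if not pairs:
        raise ValidationError("no probes with group-stratum records")
    discordant = []
    n_missing = 0
    for probe_id, (r1, r2) in pairs.items():
        if r1 is None or r2 is None or not (np.isfinite(r1) and np.isfinite(r2)):
            n_missing += 1
            continue
        if is_discordant(r1, r2, config.discordance_cutoff, config.discordance_rule):
            discordant.append(probe_id)
    n_cpgs = len(pairs)
    return DiscordanceSummary(
        gene=genes.pop(),
        n_cpgs=n_cpgs,
        n_discordant=len(discordant),
        proportion=len(discordant) / n_cpgs,
        discordant_probe_ids=discordant,
        n_missing=n_missing,
    )


def _fast_gene_summary(
    gene: str,
    probe_ids: Sequence[str],
    meth: OmicsMatrix,
    expr_row: np.ndarray,
    group_masks: tuple[np.ndarray, np.ndarray],
    sample_ids: Sequence[str],
    config: AnalysisConfig,
) -> DiscordanceSummary:
    """Vectorized group correlations feeding gene_discordance."""
    M = meth.data.loc[list(probe_ids), list(sample_ids)].to_numpy(dtype=float)
    records: list[CorrelationRecord] = []
    for label, mask in zip(("GROUP1", "GROUP2"), group_masks):
        r = pearson_rows(M[:, mask], expr_row[mask])
        for pid, ri in zip(probe_ids, r):
            records.append(
                CorrelationRecord(
                    pid, gene, label,
                    float(ri) if np.isfinite(ri) else None,
                    None, int(mask.sum()),
                )
            )
    return gene_discordance(records, config, group_labels=("GROUP1", "GROUP2"))


def permutation_null(
    target_summary: DiscordanceSummary,
    gene_pool: Sequence[str],
    annotations: Sequence[ProbeAnnotation],
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    sheet: SampleSheet,
    config: AnalysisConfig,
) -> PermutationResult:
    """Empirical null for a gene's discordance proportion.

    Samples ``config.n_permutations`` genes from ``gene_pool`` — uniformly
    without replacement when the usable pool is at least that large,
    otherwise with replacement (logged) — recomputes each sampled gene's
    two group correlation profiles and discordance proportion, and returns
    empirical_p = #{null proportion >= observed} / n_sampled (ties count).
    Reproducible for a given config.seed.
    """
    if not gene_pool:
        raise ConfigError("empty permutation gene pool")
    probes_by_gene: dict[str, list[str]] = {}
    meth_index = set(meth.data.index)
    for ann in annotations:
        if ann.probe_id in meth_index:
            probes_by_gene.setdefault(ann.gene, []).append(ann.probe_id)
    expr_index = set(expr.data.index)
    usable, n_skipped = [], 0
    for g in gene_pool:
        if g in expr_index and len(probes_by_gene.get(g, [])) >= config.min_cpgs:
            usable.append(g)
        else:
            n_skipped += 1
            log.info("permutation pool: gene %s skipped (no usable probes/expression)", g)
    if not usable:
        raise ConfigError("no usable genes in permutation pool")

    rng = np.random.default_rng(config.seed)
    with_replacement = len(usable) < config.n_permutations
    if with_replacement:
        log.info(
            "pool of %d usable genes < n_permutations=%d; sampling with replacement",
            len(usable), config.n_permutations,
        )
    sampled = rng.choice(np.asarray(usable, dtype=object), size=config.n_permutations,
                         replace=with_replacement)

    samples = [s for s in sheet.sample_ids if s in meth.data.columns and s in expr.data.columns]
    strata = group_strata(sheet, config)
    groups = sheet.groups.loc[samples]
    masks = (
        (groups == strata["GROUP1"]).to_numpy(),
        (groups == strata["GROUP2"]).to_numpy(),
    )
    null_values: list[float] = []
    for g in sampled:
        e = expr.data.loc[g, samples].to_numpy(dtype=float)
        summary = _fast_gene_summary(g, probes_by_gene[g], meth, e, masks, samples, config)
        null_values.append(float(summary.n_discordant if config.compare_counts else summary.proportion))

    observed = float(
        target_summary.n_discordant if config.compare_counts else target_summary.proportion
    )
    null_arr = np.asarray(null_values)
    k = int(np.sum(null_arr >= observed))
    n = len(null_values)
    empirical_p = (k + 1) / (n + 1) if config.plus_one_smoothing else k / n
    return PermutationResult(
        observed_proportion=observed,
        null_proportions=null_values,
        n_sampled=n,
        empirical_p=float(empirical_p),
        seed=config.seed,
        with_replacement=with_replacement,
        n_skipped=n_skipped,
    )
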