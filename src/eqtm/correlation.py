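"""Per-CpG Pearson correlation of adjusted methylation against cognate-gene
expression, pooled and per clinical group.

Each CpG of a gene yields three correlation records — POOLED (all matched
samples), GROUP1 and GROUP2 (the sample sheet's two group levels, in lexical
order unless overridden). Sample matching is pairwise-complete per
probe-gene pair and n is reported per record. Two-sided p-values come from
the exact t transform t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
freedom; |r| = 1 gives p = 0.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    CorrelationRecord,
    DegenerateInputError,
    InsufficientDataError,
    OmicsMatrix,
    PROMOTER_FEATURES,
    ProbeAnnotation,
    SampleSheet,
    STRATUM_POOLED,
    ValidationError,
    annotation_index,
)

__all__ = [
    "pearson",
    "pearson_rows",
    "correlate_gene",
    "significant_records",
    "feature_breakdown",
    "promoter_count",
    "scatter_data",
    "records_to_frame",
    "table1_style_report",
]


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson correlation with exact t-based two-sided p.

    Pairs with a missing value in either vector are dropped. Returns
    (r, p, n). Raises InsufficientDataError for n < 3 and
    DegenerateInputError for zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance in input vector")
    # dot of unit vectors: exactly +-1 for collinear input
    r = float(np.clip((xc / sx) @ (yc / sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0), n


def pearson_rows(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every row of ``M`` against the vector ``y`` (no p-values).

    Vectorized complete-data fast path used by the permutation null; rows (or
    a ``y``) containing NaN fall back to pairwise-complete per row, returning
    NaN where fewer than 3 pairs or zero variance remain.
    """
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isfinite(M).all() and np.isfinite(y).all():
        Mc = M - M.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sy = np.linalg.norm(yc)
        sm = np.linalg.norm(Mc, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Mc / sm) @ (yc / sy)
        return np.clip(r, -1.0, 1.0)
    out = np.full(M.shape[0], np.nan)
    for i in range(M.shape[0]):
        try:
            out[i] = pearson(M[i], y)[0]
        except (InsufficientDataError, DegenerateInputError):
            pass
    return out


def group_strata(sheet: SampleSheet, config: AnalysisConfig | None = None) -> dict[str, str]:
    """Map the sheet's two group levels to stratum labels GROUP1/GROUP2."""
    level1, level2 = sheet.require_two_groups()
    if config is not None and config.group_order is not None:
        level1, level2 = config.group_order
        observed = set(sheet.group_levels)
        if {level1, level2} != observed:
            raise ValidationError(
                f"group_order {config.group_order} does not match observed groups {sorted(observed)}"
            )
    return {"GROUP1": level1, "GROUP2": level2}


def _stratum_record(probe_id, gene, stratum, x, y) -> CorrelationRecord:
    try:
        r, p, n = pearson(x, y)
        return CorrelationRecord(probe_id, gene, stratum, r, p, n)
    except (InsufficientDataError, DegenerateInputError) as err:
        n = int(np.sum(np.isfinite(np.asarray(x, float)) & np.isfinite(np.asarray(y, float))))
        return CorrelationRecord(probe_id, gene, stratum, None, None, n, note=str(err))


def correlate_gene(
    gene: str,
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    annotations: Sequence[ProbeAnnotation],
    sheet: SampleSheet,
    config: AnalysisConfig | None = None,
) -> list[CorrelationRecord]:
    """Correlate every CpG annotated to ``gene`` with that gene's expression.

    Emits exactly three records per probe present in the methylation matrix
    (POOLED, GROUP1, GROUP2). Strata with fewer than 3 complete pairs or a
    degenerate vector yield records with missing r/p and a reason, not a
    crash.
    """
    if gene not in expr.data.index:
        raise LookupError(f"gene {gene!r} not in expression matrix")
    probes = [a.probe_id for a in annotations if a.gene == gene]
    probes = [p for p in probes if p in meth.data.index]
    if not probes:
        raise LookupError(f"no annotated probes of gene {gene!r} in methylation matrix")

    samples = [s for s in sheet.sample_ids if s in meth.data.columns and s in expr.data.columns]
    if len(samples) < 3:
        raise InsufficientDataError(f"only {len(samples)} samples shared across inputs")
    strata = group_strata(sheet, config)
    groups = sheet.groups.loc[samples]
    masks = {STRATUM_POOLED: np.ones(len(samples), dtype=bool)}
    for label, level in strata.items():
        masks[label] = (groups == level).to_numpy()

    e = expr.data.loc[gene, samples].to_numpy(dtype=float)
    records: list[CorrelationRecord] = []
    for probe in probes:
        m = meth.data.loc[probe, samples].to_numpy(dtype=float)
        for label in (STRATUM_POOLED, "GROUP1", "GROUP2"):
            sel = masks[label]
            records.append(_stratum_record(probe, gene, label, m[sel], e[sel]))
    return records


def significant_records(
    records: Iterable[CorrelationRecord],
    alpha: float = 0.05,
    stratum: str = STRATUM_POOLED,
    sign: str = "any",
) -> list[CorrelationRecord]:
    """Records of one stratum with p < alpha and matching correlation sign,
    stably ordered by ascending p."""
    if sign not in ("negative", "positive", "any"):
        raise ValidationError(f"unknown sign filter {sign!r}")
    out = []
    for rec in records:
        if rec.stratum != stratum or rec.r is None or rec.p is None:
            continue
        if rec.p >= alpha:
            continue
        if sign == "negative" and rec.r >= 0:
            continue
        if sign == "positive" and rec.r <= 0:
            continue
        out.append(rec)
    return sorted(out, key=lambda rec: rec.p)


def feature_breakdown(
    records: Iterable[CorrelationRecord],
    annotations: Sequence[ProbeAnnotation],
) -> dict[str, int]:
    """Count the distinct probes of ``records`` per gene-feature class."""
    index = annotation_index(annotations)
    seen: set[str] = set()
    counts: Counter[str] = Counter()
    for rec in records:
        if rec.probe_id in seen:
            continue
        seen.add(rec.probe_id)
        if rec.probe_id not in index:
            raise LookupError(f"probe {rec.probe_id!r} has no annotation")
        counts[index[rec.probe_id].feature] += 1
    return dict(counts)


def promoter_count(breakdown: dict[str, int]) -> int:
    """Probes in promoter features (TSS1500 + TSS200)."""
    return sum(breakdown.get(f, 0) for f in PROMOTER_FEATURES)


def scatter_data(
    probe_id: str,
    gene: str,
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Per-sample adjusted M vs adjusted expression with group labels, the
    plot-ready data behind a per-CpG scatter panel."""
    samples = [s for s in sheet.sample_ids if s in meth.data.columns and s in expr.data.columns]
    return pd.DataFrame(
        {
            "sample_id": samples,
            "group": sheet.groups.loc[samples].to_numpy(),
            "mvalue": meth.data.loc[probe_id, samples].to_numpy(dtype=float),
            "expression": expr.data.loc[gene, samples].to_numpy(dtype=float),
        }
    )


def records_to_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": rec.probe_id,
                "gene": rec.gene,
                "stratum": rec.stratum,
                "r": rec.r,
                "p": rec.p,
                "n": rec.n,
                "note": rec.note,
            }
            for rec in records
        ]
    )


def table1_style_report(
    records: Iterable[CorrelationRecord],
    annotations: Sequence[ProbeAnnotation],
) -> pd.DataFrame:
    """Wide per-probe table mirroring the published layout: probe context
    plus (r, p, n) for each stratum."""
    index = annotation_index(annotations)
    frame = records_to_frame(records)
    if frame.empty:
        return frame
    strata = [STRATUM_POOLED] + sorted(s for s in frame["stratum"].unique() if s != STRATUM_POOLED)
    rows = []
    for (gene, probe), sub in frame.groupby(["gene", "probe_id"], sort=False):
        ann = index.get(probe)
        row: dict = {
            "gene": gene,
            "probe_id": probe,
            "chromosome": ann.chromosome if ann else "",
            "position": ann.position if ann else "",
            "feature_cgi": ann.feature_cgi if ann else "",
        }
        for stratum in strata:
            hit = sub[sub["stratum"] == stratum]
            for col in ("r", "p", "n"):
                row[f"{col}_{stratum}"] = hit[col].iloc[0] if len(hit) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["gene", "position"], kind="stable").reset_index(drop=True)
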