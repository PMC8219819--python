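"""End-to-end orchestration: preprocess -> correlate -> report -> discordance.

A run is driven by one YAML/dict config naming the four input TSVs, the
covariate lists for each matrix, the genes to analyse and the analysis
parameters. All outputs are plain TSV/JSON written with fixed numeric
formatting; a given config + seed reproduces every output byte (the run log
records the config hash, seed and package version, never a timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .core import (
    AnalysisConfig,
    ConfigError,
    EqtmError,
    OmicsMatrix,
    read_annotation,
    read_omics_matrix,
    read_sample_sheet,
    write_omics_matrix,
)
from .correlation import (
    correlate_gene,
    feature_breakdown,
    promoter_count,
    records_to_frame,
    significant_records,
    table1_style_report,
)
from .discordance import gene_discordance, permutation_null
from .preprocess import beta_to_m, residualize
from .table1 import table1_fixture

__all__ = ["run_pipeline", "fixture_report", "load_run_config"]

log = logging.getLogger(__name__)


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a YAML mapping")
    return cfg


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _analysis_config(config: dict) -> AnalysisConfig:
    a = dict(config.get("analysis", {}))
    if "group_order" in a and a["group_order"] is not None:
        a["group_order"] = tuple(a["group_order"])
    return AnalysisConfig(**a)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute all stages and write a run directory.

    config may be a dict or a YAML path; see the package docs for the
    schema. Any stage error aborts with the stage name and the offending
    feature/sample id in the message.
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = _analysis_config(config)
    stage = "load"
    counts: dict[str, int | str] = {}
    try:
        inputs = config["inputs"]
        meth = read_omics_matrix(inputs["methylation"], inputs.get("methylation_kind", "beta"))
        expr = read_omics_matrix(inputs["expression"], "expression")
        sheet = read_sample_sheet(inputs["samples"])
        annotations = read_annotation(inputs["annotation"])
        sheet.require_two_groups()
        for s in set(meth.sample_ids) | set(expr.sample_ids):
            if s not in sheet.groups.index:
                raise EqtmError(f"sample {s!r} absent from sample sheet")
        counts["n_probes"] = meth.shape[0]
        counts["n_genes_expr"] = expr.shape[0]
        counts["n_samples"] = len(sheet.sample_ids)

        stage = "preprocess"
        if meth.kind == "beta":
            meth = OmicsMatrix("mvalue", meth.data.copy())
            meth.data.iloc[:, :] = beta_to_m(meth.data.to_numpy(dtype=float))
        covs = config.get("covariates", {})
        meth_adj, rep_m = residualize(meth, sheet, covs.get("methylation", []))
        expr_adj, rep_e = residualize(expr, sheet, covs.get("expression", []))
        write_omics_matrix(meth_adj, out / "adjusted_methylation.tsv")
        write_omics_matrix(expr_adj, out / "adjusted_expression.tsv")
        counts["covariates_methylation"] = ",".join(rep_m.covariate_names)
        counts["covariates_expression"] = ",".join(rep_e.covariate_names)

        stage = "correlate"
        genes = config.get("genes") or []
        report_rows = {}
        records_by_gene = {}
        for gene in genes:
            records = correlate_gene(gene, meth_adj, expr_adj, annotations, sheet, acfg)
            records_by_gene[gene] = records
            records_to_frame(records).to_csv(
                out / f"correlations_{gene}.tsv", sep="\t", index=False, float_format="%.12g"
            )
            table1_style_report(records, annotations).to_csv(
                out / f"report_{gene}.tsv", sep="\t", index=False, float_format="%.12g"
            )
            sig_neg = significant_records(records, acfg.alpha, sign="negative")
            sig_pos = significant_records(records, acfg.alpha, sign="positive")
            report_rows[gene] = {
                "n_cpgs": len(records) // 3,
                "significant_negative_pooled": len(sig_neg),
                "significant_positive_pooled": len(sig_pos),
                "negative_feature_breakdown": feature_breakdown(sig_neg, annotations),
                "negative_promoter": promoter_count(feature_breakdown(sig_neg, annotations)),
                "positive_feature_breakdown": feature_breakdown(sig_pos, annotations),
            }
        _write_json(report_rows, out / "significant_summary.json")

        stage = "discordance"
        perm_cfg = config.get("permutation", {})
        targets = perm_cfg.get("targets", [])
        all_genes = sorted({a.gene for a in annotations})
        for gene in targets:
            records = records_by_gene.get(gene) or correlate_gene(
                gene, meth_adj, expr_adj, annotations, sheet, acfg
            )
            summary = gene_discordance(records, acfg, group_labels=("GROUP1", "GROUP2"))
            pool = perm_cfg.get("pool", "all")
            if pool == "all":
                pool = [g for g in all_genes if g != gene and g in expr_adj.data.index]
            result = permutation_null(summary, pool, annotations, meth_adj, expr_adj, sheet, acfg)
            nulls = result.null_proportions
            qs = {
                q: float(sorted(nulls)[min(len(nulls) - 1, int(q * len(nulls)))])
                for q in (0.5, 0.9, 0.95, 0.99)
            }
            _write_json(
                {
                    "gene": gene,
                    "summary": asdict(summary),
                    "observed_proportion": result.observed_proportion,
                    "empirical_p": result.empirical_p,
                    "n_sampled": result.n_sampled,
                    "with_replacement": result.with_replacement,
                    "null_quantiles": {str(k): v for k, v in qs.items()},
                    "seed": result.seed,
                },
                out / f"discordance_{gene}.json",
            )
            with open(out / f"null_proportions_{gene}.tsv", "w") as fh:
                fh.write("proportion\n")
                for v in nulls:
                    fh.write(f"{v:.12g}\n")

        stage = "log"
        _write_json(
            {
                "config_hash": _config_hash(config),
                "seed": acfg.seed,
                "version": __version__,
                "counts": counts,
            },
            out / "run_log.json",
        )
    except EqtmError as err:
        raise type(err)(f"[stage {stage}] {err}") from err
    return out


def fixture_report(out_dir: str | Path | None = None) -> dict:
    """Report-only mode on the packaged reference table — needs no input
    files. Returns (and optionally writes) the significant-CpG counts,
    feature breakdowns and the printed-row discordance of the embedded
    records."""
    annotations, records = table1_fixture()
    out: dict = {}
    for gene, sign in (("MOBP", "negative"), ("HIP1", "positive")):
        recs = [r for r in records if r.gene == gene]
        sig = significant_records(recs, alpha=0.05, stratum="POOLED", sign=sign)
        bd = feature_breakdown(sig, annotations)
        out[gene] = {
            "n_printed_cpgs": len({r.probe_id for r in recs}),
            f"significant_{sign}_pooled": len(sig),
            "feature_breakdown": bd,
            "promoter": promoter_count(bd),
            "probe_ids": [r.probe_id for r in sig],
        }
    hip1 = [r for r in records if r.gene == "HIP1"]
    summary = gene_discordance(hip1, AnalysisConfig(), group_labels=("MSA", "CTRL"))
    out["HIP1"]["printed_discordance"] = {
        "n_cpgs": summary.n_cpgs,
        "n_discordant": summary.n_discordant,
        "proportion": summary.proportion,
        "discordant_probe_ids": summary.discordant_probe_ids,
    }
    if out_dir is not None:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        _write_json(out, path / "fixture_report.json")
    return out
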