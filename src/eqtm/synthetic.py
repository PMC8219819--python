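"""Synthetic two-group methylation/expression cohorts with known truth.

The generator emulates the statistical structure the analysis assumes: per
gene, an expression level drawn from a normal distribution; per CpG, an
M-value correlated with that gene's expression at a configurable,
group-specific correlation rho, then mapped to a beta value through the
inverse logit; optional linear covariate effects (age, sex, post-mortem
interval, batch) added to both matrices. Correlations are induced on the
M-value scale because the analysis runs on M-values; the logit map leaves
beta-scale correlations slightly attenuated, which is deliberate.

Group-specific rho with opposite signs implements "epigenetic remodelling":
a CpG whose methylation tracks expression positively in one group and
negatively in the other. One global seed governs all draws through a
spawned-stream scheme (one child stream for covariates, one per gene), so
subsets of the cohort are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, OmicsMatrix, ProbeAnnotation, SampleSheet
from .preprocess import beta_to_m, m_to_beta

__all__ = [
    "CpGSpec",
    "GeneSpec",
    "CovariateSpec",
    "SyntheticConfig",
    "generate_cohort",
    "remodelling_scenario",
    "null_scenario",
    "default_covariate_specs",
    "config_to_dict",
    "config_from_dict",
]

#: Generator group labels; lexical order makes them map onto the analysis
#: strata GROUP1/GROUP2 in the same order as rho_group1/rho_group2.
GROUP_LABELS = ("grp1", "grp2")


@dataclass(frozen=True)
class CpGSpec:
    probe_id: str
    feature: str = "Body"
    cgi_relation: str = "opensea"
    rho_group1: float = 0.0
    rho_group2: float = 0.0
    beta_mean: float = 0.5

    def __post_init__(self) -> None:
        for rho in (self.rho_group1, self.rho_group2):
            if not -1 <= rho <= 1:
                raise ConfigError(f"{self.probe_id}: |rho| > 1 ({rho})")
        if not 0 < self.beta_mean < 1:
            raise ConfigError(f"{self.probe_id}: beta_mean must be in (0,1)")


@dataclass(frozen=True)
class GeneSpec:
    gene: str
    cpgs: tuple[CpGSpec, ...]
    expr_mean: float = 8.0  # VST-like log2 abundance scale
    expr_sd: float = 1.0


@dataclass(frozen=True)
class CovariateSpec:
    """normal(mean, sd) or bernoulli(p); bernoulli covariates come out as
    0/1 indicators (sex, batch)."""

    name: str
    dist: str  # "normal" | "bernoulli"
    params: tuple[float, ...]

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, n)
        if self.dist == "bernoulli":
            (p,) = self.params
            return rng.binomial(1, p, n).astype(float)
        raise ConfigError(f"unknown covariate distribution {self.dist!r}")


def default_covariate_specs() -> list[CovariateSpec]:
    """Age (years), sex indicator, post-mortem interval (hours), batch
    indicator — the confounders a post-mortem brain cohort adjusts for."""
    return [
        CovariateSpec("age", "normal", (70.0, 8.0)),
        CovariateSpec("sex", "bernoulli", (0.5,)),
        CovariateSpec("pmi", "normal", (40.0, 15.0)),
        CovariateSpec("batch", "bernoulli", (0.5,)),
    ]


@dataclass
class SyntheticConfig:
    """Cohort shape and truth. Defaults mirror the study design: 14 vs 10
    samples; noise_sd is the M-value scale factor (array M-value spreads are
    typically ~0.3-0.7)."""

    genes: list[GeneSpec] = field(default_factory=list)
    n_group1: int = 14
    n_group2: int = 10
    covariate_specs: list[CovariateSpec] = field(default_factory=default_covariate_specs)
    # per-matrix linear coefficients: {"methylation": {cov: coef}, "expression": {...}}
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.5
    seed: int = 0
    group_labels: tuple[str, str] = GROUP_LABELS

    def __post_init__(self) -> None:
        if self.n_group1 < 3 or self.n_group2 < 3:
            raise ConfigError("each group needs at least 3 samples")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        for key in self.covariate_effects:
            if key not in ("methylation", "expression"):
                raise ConfigError(f"unknown covariate_effects key {key!r}")


def _standardize_within_groups(x: np.ndarray, group_masks: Sequence[np.ndarray]) -> np.ndarray:
    z = np.empty_like(x)
    for mask in group_masks:
        sub = x[mask]
        sd = sub.std()
        z[mask] = (sub - sub.mean()) / (sd if sd > 0 else 1.0)
    return z


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleSheet, list[ProbeAnnotation], pd.DataFrame]:
    """Draw one cohort: (beta matrix, expression matrix, sample sheet,
    annotations, truth table).

    Per sample, covariates are drawn; per gene, a standard-normal expression
    core e sets the gene's expression (expr_mean + expr_sd * e + covariate
    effects); per CpG, the M-value is
    logit2(beta_mean) + noise_sd * (rho_g * z + sqrt(1 - rho_g^2) * eps)
    with z the within-group standardized e and eps standard normal, plus
    covariate effects, finally mapped to beta by the inverse logit. The
    within-group correlation of (M, e) is therefore rho_g by construction,
    independent of noise_sd. The truth table records every rho.
    """
    if not config.genes:
        raise ConfigError("config lists no genes")
    n = config.n_group1 + config.n_group2
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    labels = [config.group_labels[0]] * config.n_group1 + [config.group_labels[1]] * config.n_group2
    masks = [np.array([g == lbl for g in labels]) for lbl in config.group_labels]

    ss = np.random.SeedSequence(config.seed)
    cov_stream, *gene_streams = [
        np.random.default_rng(s) for s in ss.spawn(1 + len(config.genes))
    ]

    cov = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for spec in config.covariate_specs:
        cov[spec.name] = spec.draw(cov_stream, n)
    eff_m = config.covariate_effects.get("methylation", {})
    eff_e = config.covariate_effects.get("expression", {})
    for eff in (eff_m, eff_e):
        unknown = set(eff) - set(cov.columns)
        if unknown:
            raise ConfigError(f"covariate effect on unknown covariate {sorted(unknown)[0]!r}")
    shift_m = sum(coef * cov[name].to_numpy() for name, coef in eff_m.items()) if eff_m else 0.0
    shift_e = sum(coef * cov[name].to_numpy() for name, coef in eff_e.items()) if eff_e else 0.0

    beta_rows, expr_rows = {}, {}
    annotations: list[ProbeAnnotation] = []
    truth_rows = []
    for gi, (gene, rng) in enumerate(zip(config.genes, gene_streams)):
        e_core = rng.normal(0.0, 1.0, n)
        expr_rows[gene.gene] = gene.expr_mean + gene.expr_sd * e_core + shift_e
        z = _standardize_within_groups(e_core, masks)
        rho_by_group = np.empty(n)
        for ci, cpg in enumerate(gene.cpgs):
            rho_by_group[masks[0]] = cpg.rho_group1
            rho_by_group[masks[1]] = cpg.rho_group2
            eps = rng.normal(0.0, 1.0, n)
            m = (
                beta_to_m(cpg.beta_mean)
                + config.noise_sd * (rho_by_group * z + np.sqrt(1.0 - rho_by_group**2) * eps)
                + shift_m
            )
            beta_rows[cpg.probe_id] = m_to_beta(m)
            annotations.append(
                ProbeAnnotation(
                    probe_id=cpg.probe_id,
                    chromosome=str(gi % 22 + 1),
                    position=(gi + 1) * 1_000_000 + (ci + 1) * 1_000,
                    gene=gene.gene,
                    feature=cpg.feature,
                    cgi_relation=cpg.cgi_relation,
                )
            )
            truth_rows.append(
                {
                    "gene": gene.gene,
                    "probe_id": cpg.probe_id,
                    "rho_group1": cpg.rho_group1,
                    "rho_group2": cpg.rho_group2,
                    "beta_mean": cpg.beta_mean,
                    "feature": cpg.feature,
                    "cgi_relation": cpg.cgi_relation,
                }
            )

    beta = OmicsMatrix("beta", pd.DataFrame(beta_rows, index=sample_ids).T)
    expr = OmicsMatrix("expression", pd.DataFrame(expr_rows, index=sample_ids).T)
    sheet = SampleSheet(groups=pd.Series(labels, index=sample_ids, name="group"), covariates=cov)
    truth = pd.DataFrame(truth_rows)
    return beta, expr, sheet, annotations, truth


def _null_gene(name: str, n_cpgs: int = 10) -> GeneSpec:
    return GeneSpec(
        gene=name,
        cpgs=tuple(
            CpGSpec(probe_id=f"{name}_cg{j + 1:02d}") for j in range(n_cpgs)
        ),
    )


def remodelling_scenario(
    n_null_genes: int = 199,
    seed: int = 0,
    covariate_effects: dict[str, dict[str, float]] | None = None,
) -> SyntheticConfig:
    """Packaged scenario with a remodelled target gene and a null pool.

    TARGET carries 10 CpGs: 7 with rho +0.6 in group1 and -0.6 in group2
    (sign-flip remodelling, true discordance proportion 0.7 at the 0.4
    cutoff in the large-sample limit) and 3 concordant at +0.6 in both.
    PROMNEG is a promoter-repression gene: 4 TSS1500-shore CpGs at rho -0.6
    in both groups (low beta_mean, as promoters tend to be unmethylated)
    plus 2 null Body CpGs. n_null_genes genes with rho 0 everywhere form the
    permutation pool.
    """
    target = GeneSpec(
        gene="TARGET",
        cpgs=tuple(
            [
                CpGSpec(f"TARGET_cg{j + 1:02d}", rho_group1=0.6, rho_group2=-0.6)
                for j in range(7)
            ]
            + [
                CpGSpec(f"TARGET_cg{j + 1:02d}", rho_group1=0.6, rho_group2=0.6)
                for j in range(7, 10)
            ]
        ),
    )
    promneg = GeneSpec(
        gene="PROMNEG",
        cpgs=tuple(
            [
                CpGSpec(
                    f"PROMNEG_cg{j + 1:02d}",
                    feature="TSS1500",
                    cgi_relation="shore",
                    rho_group1=-0.6,
                    rho_group2=-0.6,
                    beta_mean=0.2,
                )
                for j in range(4)
            ]
            + [
                CpGSpec(f"PROMNEG_cg{j + 1:02d}", beta_mean=0.7)
                for j in range(4, 6)
            ]
        ),
    )
    nulls = [_null_gene(f"NULL{j + 1:04d}") for j in range(n_null_genes)]
    return SyntheticConfig(
        genes=[target, promneg] + nulls,
        seed=seed,
        covariate_effects=covariate_effects or {},
    )


def null_scenario(n_genes: int = 200, n_cpgs: int = 10, seed: int = 0) -> SyntheticConfig:
    """All-null genome: every gene's methylation independent of expression in
    both groups. Gene 1 is named TARGET so calibration runs can treat it as
    the gene under test."""
    genes = [_null_gene("TARGET", n_cpgs)] + [
        _null_gene(f"NULL{j + 1:04d}", n_cpgs) for j in range(n_genes - 1)
    ]
    return SyntheticConfig(genes=genes, seed=seed)


def config_to_dict(config: SyntheticConfig) -> dict:
    """Plain-dict form of a config (YAML/JSON friendly)."""
    d = asdict(config)
    d["group_labels"] = list(config.group_labels)
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    genes = [
        GeneSpec(
            gene=g["gene"],
            cpgs=tuple(CpGSpec(**c) for c in g["cpgs"]),
            expr_mean=g.get("expr_mean", 8.0),
            expr_sd=g.get("expr_sd", 1.0),
        )
        for g in d.get("genes", [])
    ]
    covs = [
        CovariateSpec(c["name"], c["dist"], tuple(c["params"]))
        for c in d.get("covariate_specs", [])
    ] or default_covariate_specs()
    return SyntheticConfig(
        genes=genes,
        n_group1=d.get("n_group1", 14),
        n_group2=d.get("n_group2", 10),
        covariate_specs=covs,
        covariate_effects=d.get("covariate_effects", {}),
        noise_sd=d.get("noise_sd", 0.5),
        seed=d.get("seed", 0),
        group_labels=tuple(d.get("group_labels", GROUP_LABELS)),
    )
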