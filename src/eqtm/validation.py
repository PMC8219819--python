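"""Simulation studies of the pipeline's statistical properties.

These drivers regenerate synthetic cohorts and push them through the real
analysis path (beta -> M -> correlation -> discordance -> permutation null),
measuring estimator accuracy, null calibration and power. They exist so the
package can audit itself reproducibly: every study takes one seed and spawns
independent substreams per replicate.
"""

from __future__ import annotations

import numpy as np

from .core import AnalysisConfig, OmicsMatrix
from .correlation import correlate_gene, pearson
from .discordance import gene_discordance, permutation_null
from .preprocess import beta_to_m, residualize
from .synthetic import (
    CpGSpec,
    GeneSpec,
    SyntheticConfig,
    generate_cohort,
    null_scenario,
    remodelling_scenario,
)

__all__ = [
    "pearson_oracle_max_error",
    "rho_recovery_errors",
    "null_p_rejection_rate",
    "adjustment_recovery",
    "calibration_study",
    "power_study",
]


def _as_m(beta: OmicsMatrix) -> OmicsMatrix:
    m = OmicsMatrix("mvalue", beta.data.copy())
    m.data.iloc[:, :] = beta_to_m(beta.data.to_numpy(dtype=float))
    return m


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep spawned seeds below 2**31 so they stay CLI-representable
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def pearson_oracle_max_error(n_instances: int = 1000, seed: int = 0) -> float:
    """Max |r - r_oracle| over random vectors (n in [3, 50]), the oracle being
    the explicit covariance formula."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(3, 51))
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, _, _ = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        worst = max(worst, abs(r - oracle))
    return worst


def rho_recovery_errors(
    rhos=(-0.9, -0.4, 0.0, 0.4, 0.9), n: int = 2000, seed: int = 0
) -> dict[float, float]:
    """Generate one gene per rho at large n and return |estimate - rho|,
    estimated on the analysis scale (M-values vs expression, group 1)."""
    errors: dict[float, float] = {}
    for rho, s in zip(rhos, _child_seeds(seed, len(rhos))):
        cfg = SyntheticConfig(
            genes=[GeneSpec("G", (CpGSpec("cg0", rho_group1=rho, rho_group2=rho),))],
            n_group1=n,
            n_group2=10,
            covariate_effects={},
            seed=s,
        )
        beta, expr, sheet, *_ = generate_cohort(cfg)
        m = _as_m(beta)
        mask = (sheet.groups == "grp1").to_numpy()
        r, _, _ = pearson(
            m.data.loc["cg0"].to_numpy(float)[mask],
            expr.data.loc["G"].to_numpy(float)[mask],
        )
        errors[rho] = abs(r - rho)
    return errors


def null_p_rejection_rate(
    n_sims: int = 2000, n: int = 24, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of two-sided Pearson p-values below alpha under rho = 0."""
    rng = np.random.default_rng(seed)
    hits = sum(
        pearson(rng.normal(size=n), rng.normal(size=n))[1] < alpha for _ in range(n_sims)
    )
    return hits / n_sims


def adjustment_recovery(n: int = 2000, rho: float = 0.6, seed: int = 0) -> dict:
    """Inject linear covariate effects, remove them with residualize, and
    report the per-group correlation error plus the worst residual-covariate
    orthogonality (normalized dot product)."""
    effects = {
        "methylation": {"age": 0.05, "sex": 0.8, "pmi": -0.02, "batch": 0.5},
        "expression": {"age": -0.04, "sex": 1.0, "pmi": 0.03, "batch": -0.6},
    }
    cfg = SyntheticConfig(
        genes=[GeneSpec("G", (CpGSpec("cg0", rho_group1=rho, rho_group2=rho),))],
        n_group1=n // 2,
        n_group2=n - n // 2,
        covariate_effects=effects,
        seed=seed,
    )
    beta, expr, sheet, *_ = generate_cohort(cfg)
    covs = ["age", "sex", "pmi", "batch"]
    m_adj, _ = residualize(_as_m(beta), sheet, covs)
    e_adj, _ = residualize(expr, sheet, covs)
    errors = {}
    for g in ("grp1", "grp2"):
        mask = (sheet.groups == g).to_numpy()
        r, _, _ = pearson(
            m_adj.data.loc["cg0"].to_numpy(float)[mask],
            e_adj.data.loc["G"].to_numpy(float)[mask],
        )
        errors[g] = abs(r - rho)
    C = sheet.covariates[covs].to_numpy(float)
    Cc = C - C.mean(axis=0)
    worst = 0.0
    for row in np.vstack([m_adj.values, e_adj.values]):
        rc = row - row.mean()
        dots = np.abs(rc @ Cc) / (np.linalg.norm(rc) * np.linalg.norm(Cc, axis=0))
        worst = max(worst, float(dots.max()))
    return {"rho_errors": errors, "max_orthogonality": worst}


def _empirical_p_for_target(cfg: SyntheticConfig, analysis: AnalysisConfig) -> tuple[float, float]:
    """Run the full discordance analysis for gene TARGET on one generated
    cohort; return (observed proportion, empirical p)."""
    beta, expr, sheet, annotations, _ = generate_cohort(cfg)
    m = _as_m(beta)
    records = correlate_gene("TARGET", m, expr, annotations, sheet, analysis)
    summary = gene_discordance(records, analysis, group_labels=("GROUP1", "GROUP2"))
    pool = sorted({a.gene for a in annotations} - {"TARGET"})
    result = permutation_null(summary, pool, annotations, m, expr, sheet, analysis)
    return summary.proportion, result.empirical_p


def calibration_study(
    n_replicates: int = 200,
    n_genes: int = 200,
    n_cpgs: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Null calibration: all-null genome, TARGET is a null gene; the fraction
    of replicates with empirical_p <= alpha measures the test's actual size.
    The full usable pool is sampled once per replicate (without replacement)."""
    seeds = _child_seeds(seed, 2 * n_replicates)
    ps = []
    for i in range(n_replicates):
        cfg = null_scenario(n_genes=n_genes, n_cpgs=n_cpgs, seed=seeds[2 * i])
        analysis = AnalysisConfig(n_permutations=n_genes - 1, seed=seeds[2 * i + 1])
        _, p = _empirical_p_for_target(cfg, analysis)
        ps.append(p)
    ps_arr = np.asarray(ps)
    return {
        "empirical_ps": ps,
        "fraction_le_alpha": float(np.mean(ps_arr <= alpha)),
        "n_replicates": n_replicates,
    }


def power_study(
    n_replicates: int = 100,
    n_permutations: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Power of the permutation test for the remodelled target gene (7/10
    CpGs with a +-0.6 sign flip) against a 199-gene null pool at the study's
    sample sizes."""
    seeds = _child_seeds(seed, 2 * n_replicates)
    ps, proportions = [], []
    for i in range(n_replicates):
        cfg = remodelling_scenario(n_null_genes=199, seed=seeds[2 * i])
        analysis = AnalysisConfig(n_permutations=n_permutations, seed=seeds[2 * i + 1])
        prop, p = _empirical_p_for_target(cfg, analysis)
        proportions.append(prop)
        ps.append(p)
    ps_arr = np.asarray(ps)
    return {
        "empirical_ps": ps,
        "observed_proportions": proportions,
        "power": float(np.mean(ps_arr <= alpha)),
        "mean_observed_proportion": float(np.mean(proportions)),
        "n_replicates": n_replicates,
    }
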