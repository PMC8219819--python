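"""Beta/M-value transforms and linear covariate adjustment.

Methylation statistics are computed on M-values, the base-2 logit of the
beta value: M = log2(beta / (1 - beta)). Betas are clamped away from {0, 1}
by a small epsilon before the logit so boundary probes stay finite.

Confounder adjustment replaces each feature row by its ordinary-least-squares
residuals on [intercept | covariates], with the row mean added back so
adjusted matrices keep their original center (correlations are unaffected by
the re-centering). Collinear covariates are dropped deterministically,
left-to-right, and reported. A feature × sample missing entry excludes that
sample from that feature's regression only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ConfigError, DegenerateInputError, OmicsMatrix, SampleSheet, ValidationError

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "log2_counts",
    "residualize",
    "ResidualizationReport",
]

_DEFAULT_EPS = 1e-6


def beta_to_m(beta, epsilon: float = _DEFAULT_EPS):
    """Base-2 logit transform of methylation beta values.

    Accepts scalars or arrays; betas must lie in [0, 1] (NaN passes through
    as missing). Values are clamped to [epsilon, 1 - epsilon] first.
    """
    b = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (b < 0) | (b > 1)
    if np.any(bad):
        raise DegenerateInputError(
            f"beta value {b[bad].flat[0]!r} outside [0,1]"
            if b.ndim
            else f"beta value {float(b)!r} outside [0,1]"
        )
    b = np.clip(b, epsilon, 1 - epsilon)
    out = np.log2(b / (1 - b))
    return float(out) if np.isscalar(beta) or out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (without the clamp): 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return float(out) if out.ndim == 0 else out


def log2_counts(counts):
    """Convenience log2(x + 1) transform for raw expression counts.

    A simple variance-flattening stand-in for count normalization; inputs
    that are already normalized should skip it.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise DegenerateInputError("negative count")
    return np.log2(c + 1.0)


@dataclass
class ResidualizationReport:
    """What the adjustment actually fit: covariates retained, covariates
    dropped as collinear (left-to-right scan), and the design rank."""

    covariate_names: list[str]
    dropped_covariates: list[str] = field(default_factory=list)
    rank: int = 1
    n_rows_skipped: int = 0


def _select_independent(X: np.ndarray, names: Sequence[str], tol: float = 1e-10):
    """Greedy left-to-right scan keeping covariate columns that add rank
    beyond the intercept and previously kept columns."""
    n = X.shape[0]
    basis = np.ones((n, 1))
    keep: list[int] = []
    dropped: list[str] = []
    for j, name in enumerate(names):
        col = X[:, j : j + 1]
        # residual of the candidate against the current basis
        q, _ = np.linalg.qr(basis)
        resid = col - q @ (q.T @ col)
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(col)):
            basis = np.hstack([basis, col])
            keep.append(j)
        else:
            dropped.append(name)
    return keep, dropped


def residualize(
    matrix: OmicsMatrix,
    sheet: SampleSheet,
    covariate_names: Sequence[str],
) -> tuple[OmicsMatrix, ResidualizationReport]:
    """Adjust every feature row for the named covariates by OLS residuals.

    Returns an adjusted matrix of the same kind plus a report. Residuals are
    orthogonal to every retained covariate; the per-row mean is added back.
    Beta matrices are refused — transform to M-values first, since residuals
    of proportions leave [0, 1].
    """
    if matrix.kind == "beta":
        raise ConfigError("residualize expects M-values (or expression); convert beta first")
    missing_cov = [c for c in covariate_names if c not in sheet.covariates.columns]
    if missing_cov:
        raise ValidationError(f"covariate {missing_cov[0]!r} not in sample sheet")
    missing_samp = [s for s in matrix.sample_ids if s not in sheet.groups.index]
    if missing_samp:
        raise ValidationError(f"sample {missing_samp[0]!r} not in sample sheet")

    samples = matrix.sample_ids
    X = sheet.covariates.loc[samples, list(covariate_names)].to_numpy(dtype=float)
    n = len(samples)
    keep, dropped = _select_independent(X, covariate_names)
    retained = [covariate_names[j] for j in keep]
    k = len(retained)
    if n < k + 2:
        raise ConfigError(
            f"{k} retained covariates need at least {k + 2} samples, have {n}"
        )

    design = np.hstack([np.ones((n, 1)), X[:, keep]])
    Y = matrix.values  # features x samples
    adjusted = np.array(Y, dtype=float)
    complete = np.isfinite(Y)
    n_skipped = 0

    q_full, _ = np.linalg.qr(design)
    full_rows = complete.all(axis=1)
    if full_rows.any():
        Yf = Y[full_rows]
        fitted = (Yf @ q_full) @ q_full.T
        adjusted[full_rows] = Yf - fitted + Yf.mean(axis=1, keepdims=True)

    for i in np.nonzero(~full_rows)[0]:
        mask = complete[i]
        if mask.sum() < k + 2:
            n_skipped += 1
            warnings.warn(
                f"feature {matrix.feature_ids[i]!r}: only {int(mask.sum())} complete "
                "samples; adjusted values set to missing",
                stacklevel=2,
            )
            adjusted[i] = np.nan
            continue
        d = design[mask]
        y = Y[i, mask]
        coef, *_ = np.linalg.lstsq(d, y, rcond=None)
        adjusted[i, mask] = y - d @ coef + y.mean()
        adjusted[i, ~mask] = np.nan

    out = OmicsMatrix(
        kind=matrix.kind,
        data=matrix.data.copy(),
    )
    out.data.iloc[:, :] = adjusted
    report = ResidualizationReport(
        covariate_names=retained,
        dropped_covariates=dropped,
        rank=k + 1,
        n_rows_skipped=n_skipped,
    )
    return out, report
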