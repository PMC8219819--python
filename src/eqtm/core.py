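"""Domain types and TSV input/output for the methylation–expression pipeline.

The analysis operates on three tabular inputs — a methylation matrix (CpG
probes × samples, beta values or M-values), a normalized expression matrix
(genes × samples) and a sample sheet (group label plus numeric covariates per
sample) — together with a probe annotation table giving each CpG's genomic
position, gene, gene-feature class (TSS1500, Body, ...) and CpG-island
relation (island/shore/shelf/opensea). All files are plain tab-separated
text; empty cells in a matrix denote missing values and are distinct from 0.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EqtmError",
    "ValidationError",
    "ParseError",
    "ConfigError",
    "InsufficientDataError",
    "DegenerateInputError",
    "FEATURES",
    "CGI_RELATIONS",
    "PROMOTER_FEATURES",
    "STRATUM_POOLED",
    "ProbeAnnotation",
    "OmicsMatrix",
    "SampleSheet",
    "CorrelationRecord",
    "AnalysisConfig",
    "DiscordanceSummary",
    "PermutationResult",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_annotation",
    "write_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
]


class EqtmError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(EqtmError):
    """A loaded object violates a structural invariant (range, uniqueness...)."""


class ParseError(EqtmError):
    """A file cell or token could not be interpreted."""


class ConfigError(EqtmError):
    """An analysis configuration is inconsistent or infeasible."""


class InsufficientDataError(EqtmError):
    """Fewer complete observations than the statistic requires."""


class DegenerateInputError(EqtmError):
    """Zero-variance or otherwise degenerate numeric input."""


# Gene-feature classes of the Illumina manifest (UCSC_RefGene_Group), plus an
# explicit label for probes not assigned to any gene feature.
FEATURES = frozenset(
    {"TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"}
)
#: TSS1500 + TSS200 together are reported as "promoter".
PROMOTER_FEATURES = frozenset({"TSS1500", "TSS200"})
CGI_RELATIONS = frozenset({"island", "shore", "shelf", "opensea"})

STRATUM_POOLED = "POOLED"

# Unicode hyphen lookalikes normalized to ASCII "-" before any splitting.
_HYPHENS = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


def _normalize_hyphens(s: str) -> str:
    return s.translate(_HYPHENS)


def _normalize_cgi(token: str) -> str:
    """Map manifest-style CGI tokens (N_Shore, S_Shelf, OpenSea...) to the
    canonical lowercase set."""
    t = token.strip().lower().replace(" ", "").replace("_", "")
    t = re.sub(r"^[ns](?=shore|shelf)", "", t)
    if t in {"island", "cpgisland"}:
        return "island"
    if t in CGI_RELATIONS:
        return t
    raise ParseError(f"unknown CGI relation {token!r}")


def _normalize_feature(token: str) -> str:
    t = token.strip()
    for f in FEATURES:
        if t.lower() == f.lower():
            return f
    raise ParseError(f"unknown gene feature {token!r}")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic and gene context of one CpG probe.

    position follows the manifest "Mapinfo" convention: a 1-based single
    coordinate, strand-collapsed (no interval, no strand).
    """

    probe_id: str
    chromosome: str
    position: int
    gene: str
    feature: str
    cgi_relation: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"probe {self.probe_id}: position must be >= 1, got {self.position}"
            )
        if self.feature not in FEATURES:
            raise ParseError(f"probe {self.probe_id}: unknown feature {self.feature!r}")
        if self.cgi_relation not in CGI_RELATIONS:
            raise ParseError(
                f"probe {self.probe_id}: unknown CGI relation {self.cgi_relation!r}"
            )

    @property
    def feature_cgi(self) -> str:
        """Composite label as printed in array manifests, e.g. ``Body-shore``."""
        return f"{self.feature}-{self.cgi_relation}"


@dataclass
class OmicsMatrix:
    """Named real matrix (features × samples) with a value-kind tag.

    kind is one of ``beta`` (methylation proportions in [0,1]), ``mvalue``
    (logit2-transformed betas) or ``expression``. Missing entries are NaN.
    """

    kind: str
    data: pd.DataFrame

    KINDS = ("beta", "mvalue", "expression")

    def __post_init__(self) -> None:
        self.validate()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.kind == "beta":
            vals = self.data.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"beta value {vals[i, j]!r} outside [0,1] at probe "
                    f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
                )

    def row(self, feature_id: str) -> pd.Series:
        try:
            return self.data.loc[feature_id]
        except KeyError:
            raise LookupError(f"feature {feature_id!r} not in {self.kind} matrix")


def read_omics_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a features × samples TSV (header row = sample ids, first column =
    feature ids). Empty cells become NaN; any other non-numeric cell is a
    ParseError naming the offending row and column."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ValidationError(f"{path.name}: duplicate sample id {dup!r} in header")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate feature id {dup!r}")
    numeric = raw.replace("", np.nan).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (raw != "")
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise ParseError(
            f"{path.name}: non-numeric value {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return OmicsMatrix(kind=kind, data=numeric)


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix TSV; values keep 12 significant digits, missing → empty."""
    matrix.data.to_csv(path, sep="\t", float_format="%.12g", na_rep="")


_ANNOT_COLUMNS = ["probe_id", "chromosome", "position", "gene", "feature", "cgi_relation"]


def _parse_feature_cgi(token: str) -> tuple[str, str]:
    token = _normalize_hyphens(token).strip()
    if "-" not in token:
        raise ParseError(f"malformed Feature-CGI string {token!r} (no hyphen)")
    feat, _, cgi = token.partition("-")
    return _normalize_feature(feat), _normalize_cgi(cgi)


def read_annotation(path: str | Path) -> list[ProbeAnnotation]:
    """Read a probe annotation TSV.

    Accepts either split ``feature`` and ``cgi_relation`` columns or a single
    composite ``feature_cgi`` column holding manifest-style strings like
    ``TSS1500-shore`` (unicode hyphens tolerated). A probe annotated to
    several genes (semicolon-separated) keeps the first listed gene, with a
    warning.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    required = ["probe_id", "chromosome", "position", "gene"]
    for name in required:
        if name not in cols:
            raise ParseError(f"annotation is missing column {name!r}")
    composite = "feature_cgi" in cols
    if not composite and not ("feature" in cols and "cgi_relation" in cols):
        raise ParseError(
            "annotation needs either a feature_cgi column or feature + cgi_relation"
        )
    out: list[ProbeAnnotation] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = row[cols["probe_id"]].strip()
        if pid in seen:
            raise ValidationError(f"duplicate probe id {pid!r} in annotation")
        seen.add(pid)
        gene = row[cols["gene"]].strip()
        if ";" in gene:
            first = gene.split(";")[0].strip()
            warnings.warn(
                f"probe {pid}: multi-gene annotation {gene!r}; keeping {first!r}",
                stacklevel=2,
            )
            gene = first
        if composite:
            feat, cgi = _parse_feature_cgi(row[cols["feature_cgi"]])
        else:
            feat = _normalize_feature(row[cols["feature"]])
            cgi = _normalize_cgi(row[cols["cgi_relation"]])
        try:
            pos = int(row[cols["position"]])
        except ValueError:
            raise ParseError(f"probe {pid}: non-integer position {row[cols['position']]!r}")
        out.append(
            ProbeAnnotation(
                probe_id=pid,
                chromosome=row[cols["chromosome"]].strip(),
                position=pos,
                gene=gene,
                feature=feat,
                cgi_relation=cgi,
            )
        )
    return out


def write_annotation(annotations: Iterable[ProbeAnnotation], path: str | Path) -> None:
    rows = [
        (a.probe_id, a.chromosome, a.position, a.gene, a.feature, a.cgi_relation)
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, sep="\t", index=False)


def annotation_index(annotations: Iterable[ProbeAnnotation]) -> dict[str, ProbeAnnotation]:
    return {a.probe_id: a for a in annotations}


@dataclass
class SampleSheet:
    """Sample ids, a two-level group label and a numeric covariate table.

    Categorical covariates must be pre-encoded as indicator columns. The
    covariate table may be empty (no columns) but never contains missing
    values.
    """

    groups: pd.Series  # index = sample_id, values = group label
    covariates: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        self.groups = self.groups.astype(str)
        self.groups.index = self.groups.index.astype(str)
        if self.groups.index.duplicated().any():
            dup = self.groups.index[self.groups.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
        self.covariates = self.covariates.reindex(self.groups.index)
        if self.covariates.isna().to_numpy().any():
            bad = self.covariates.isna()
            sid = bad.index[bad.any(axis=1)][0]
            col = bad.columns[bad.loc[sid]][0]
            raise ValidationError(f"missing covariate {col!r} for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_levels(self) -> list[str]:
        """Observed group labels, in lexical order."""
        return sorted(self.groups.unique())

    def require_two_groups(self) -> tuple[str, str]:
        levels = self.group_levels
        if len(levels) != 2:
            raise ValidationError(
                f"analysis requires exactly 2 group levels, found {levels}"
            )
        return levels[0], levels[1]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        missing = [s for s in sample_ids if s not in self.groups.index]
        if missing:
            raise ValidationError(f"sample {missing[0]!r} not in sample sheet")
        return SampleSheet(
            groups=self.groups.loc[list(sample_ids)],
            covariates=self.covariates.loc[list(sample_ids)],
        )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV with columns sample_id, group, then covariates."""
    df = pd.read_csv(Path(path), sep="\t", dtype={0: str})
    cols = {c.strip().lower(): c for c in df.columns}
    for name in ("sample_id", "group"):
        if name not in cols:
            raise ParseError(f"sample sheet is missing column {name!r}")
    df = df.set_index(cols["sample_id"])
    df.index = df.index.astype(str)
    cov_cols = [c for c in df.columns if c != cols["group"]]
    cov = df[cov_cols].apply(pd.to_numeric, errors="raise")
    return SampleSheet(groups=df[cols["group"]], covariates=cov)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = pd.DataFrame({"sample_id": sheet.sample_ids, "group": sheet.groups.values})
    for c in sheet.covariates.columns:
        out[c] = sheet.covariates[c].values
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class CorrelationRecord:
    """One CpG × gene correlation for one sample stratum.

    stratum is ``POOLED`` or a group-stratum label (``GROUP1``/``GROUP2`` in
    pipeline output, mapped from the sample sheet's two group levels in
    lexical order). r and p are None when the stratum had too few complete
    pairs or degenerate input; ``note`` then says why.
    """

    probe_id: str
    gene: str
    stratum: str
    r: float | None
    p: float | None
    n: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.r is not None and not -1 <= self.r <= 1:
            raise ValidationError(f"{self.probe_id}/{self.stratum}: |r| > 1 ({self.r})")
        if self.p is not None and not 0 <= self.p <= 1:
            raise ValidationError(f"{self.probe_id}/{self.stratum}: p outside [0,1] ({self.p})")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    alpha
        per-test significance level for Table-style reporting (default 0.05).
    discordance_cutoff
        minimum |r| for a group correlation to count toward discordance
        (default 0.4).
    discordance_rule
        ``both_exceed`` (default; both group |r| >= cutoff with opposite
        signs) or ``either_exceeds`` (opposite signs, max |r| >= cutoff).
    n_permutations
        number of genes sampled for the permutation null (default 1000).
    min_cpgs
        minimum usable CpGs for a sampled gene to enter the null (default 1).
    plus_one_smoothing
        if True, empirical p = (k+1)/(n+1) instead of k/n.
    compare_counts
        if True, the permutation null compares raw discordant-CpG counts
        instead of proportions.
    group_order
        optional explicit (GROUP1, GROUP2) group-level pair, overriding
        lexical order.
    """

    alpha: float = 0.05
    discordance_cutoff: float = 0.4
    n_permutations: int = 1000
    seed: int = 0
    discordance_rule: str = "both_exceed"
    min_cpgs: int = 1
    plus_one_smoothing: bool = False
    compare_counts: bool = False
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.discordance_cutoff < 0:
            raise ConfigError("discordance_cutoff must be >= 0")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.discordance_rule not in ("both_exceed", "either_exceeds"):
            raise ConfigError(f"unknown discordance rule {self.discordance_rule!r}")
        if self.min_cpgs < 1:
            raise ConfigError("min_cpgs must be >= 1")


@dataclass
class DiscordanceSummary:
    """Per-gene opposite-correlation-sign summary."""

    gene: str
    n_cpgs: int
    n_discordant: int
    proportion: float
    discordant_probe_ids: list[str] = field(default_factory=list)
    n_missing: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_discordant <= self.n_cpgs:
            raise ValidationError("n_discordant outside [0, n_cpgs]")


@dataclass
class PermutationResult:
    """Random-gene null for a gene's discordance proportion."""

    observed_proportion: float
    null_proportions: list[float]
    n_sampled: int
    empirical_p: float
    seed: int
    with_replacement: bool = False
    n_skipped: int = 0
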