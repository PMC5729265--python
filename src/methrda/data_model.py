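"""Core containers for array methylation data and model design.

Conventions
-----------
* Methylation matrices are stored CpGs (rows) x samples (columns), the
  orientation in which 450K-style beta matrices are distributed.
* Beta values are methylation proportions in ``(0, 1)``; M-values are
  ``log2(beta / (1 - beta))`` and are the scale on which the linear
  (Gaussian) modelling is done.
* Genomic regions are 1-based, fully inclusive (``chr17:37,700,000-38,000,000``
  covers both endpoints).  BED input is 0-based half-open and is converted
  on read (see :mod:`methrda.io`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import (
    EmptyRegionError,
    FormatError,
    RankError,
    RegionTooSmallError,
)

logger = logging.getLogger(__name__)

#: default clipping bound applied to beta values before the logit2 transform
DEFAULT_EPSILON = 1e-6

#: minimum number of CpGs a region must contain to be analyzable
MIN_CPGS = 3

_LN2 = np.log(2.0)


def _as_numeric_frame(values, what: str) -> pd.DataFrame:
    df = pd.DataFrame(values)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{what} contains non-numeric entries: {exc}") from exc
    return df


@dataclass
class BetaMatrix:
    """Beta-value matrix, CpGs x samples.

    Rows with missing values are dropped at construction (no imputation);
    the number of dropped CpGs is logged.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = _as_numeric_frame(self.values, "beta matrix")
        n_missing = int(df.isna().any(axis=1).sum())
        if n_missing:
            logger.info("dropping %d CpG rows with missing beta values", n_missing)
            df = df.dropna(axis=0)
        if df.empty:
            raise FormatError("beta matrix has no complete CpG rows")
        arr = df.to_numpy()
        if (arr < 0).any() or (arr > 1).any():
            raise FormatError("beta values must lie in [0, 1]")
        if not df.index.is_unique:
            raise FormatError("duplicate probe IDs in beta matrix")
        self.values = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class MValueMatrix:
    """M-value matrix (log2 scale), same indexing as :class:`BetaMatrix`."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = _as_numeric_frame(self.values, "M-value matrix")
        if not np.isfinite(df.to_numpy()).all():
            raise FormatError("M-values must be finite")
        self.values = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def beta_to_m(betas: BetaMatrix, epsilon: float = DEFAULT_EPSILON) -> MValueMatrix:
    """Logit2-transform beta values to M-values.

    Betas are clipped to ``[epsilon, 1 - epsilon]`` first so that boundary
    values map to large finite M-values rather than +/-inf.
    """
    if not 0.0 < epsilon < 0.5:
        raise FormatError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.clip(betas.values.to_numpy(), epsilon, 1.0 - epsilon)
    m = logit(b) / _LN2
    return MValueMatrix(
        pd.DataFrame(m, index=betas.values.index, columns=betas.values.columns)
    )


def m_to_beta(mvals: MValueMatrix) -> BetaMatrix:
    """Inverse-logit2 M-values back to beta values (numerically stable)."""
    beta = expit(mvals.values.to_numpy() * _LN2)
    # expit is strictly inside (0,1) for finite input; no clipping needed
    return BetaMatrix(
        pd.DataFrame(beta, index=mvals.values.index, columns=mvals.values.columns)
    )


_REGION_RE = re.compile(r"^\s*([\w.]+)\s*:\s*([\d,]+)\s*-\s*([\d,]+)\s*$")


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, fully inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"invalid region {self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse ``chr17:37,700,000-38,000,000`` (thousands commas allowed)."""
        match = _REGION_RE.match(text)
        if match is None:
            raise FormatError(f"cannot parse region string {text!r}")
        chrom, start, end = match.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class CpGAnnotation:
    """Probe annotation: probe_id (index), chromosome, 1-based position.

    Stored sorted by (chromosome, position); probe IDs must be unique and
    positions strictly increasing within each chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = {"chromosome", "position"} - set(df.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if not df.index.is_unique:
            raise FormatError("duplicate probe IDs in annotation")
        df = df.copy()
        df["position"] = df["position"].astype(int)
        if (df["position"] < 1).any():
            raise FormatError("annotation positions must be >= 1 (1-based)")
        df = df.sort_values(["chromosome", "position"], kind="mergesort")
        dup = df.duplicated(subset=["chromosome", "position"])
        if dup.any():
            raise FormatError("duplicate (chromosome, position) pairs in annotation")
        self.table = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def probes_in_region(self, region: GenomicRegion) -> pd.Index:
        """Probe IDs inside ``region``, in genomic order."""
        tbl = self.table
        mask = (
            (tbl["chromosome"] == region.chromosome)
            & (tbl["position"] >= region.start)
            & (tbl["position"] <= region.end)
        )
        return tbl.index[mask]

    def restrict(self, probe_ids: Iterable[str]) -> "CpGAnnotation":
        """Annotation restricted to ``probe_ids`` (genomic order preserved)."""
        keep = self.table.index.isin(pd.Index(probe_ids))
        return CpGAnnotation(self.table.loc[keep])


def select_region(
    m: MValueMatrix,
    ann: CpGAnnotation,
    region: GenomicRegion,
    min_cpgs: int = MIN_CPGS,
) -> tuple[pd.DataFrame, list[str]]:
    """Resolve a region to its CpG submatrix (k x n), in genomic order.

    Returns ``(submatrix, probe_ids)``.  Raises :class:`EmptyRegionError`
    when no annotated CpG falls in the region (including unknown
    chromosomes) and :class:`RegionTooSmallError` when fewer than
    ``min_cpgs`` do.
    """
    probes = ann.probes_in_region(region)
    probes = probes[probes.isin(m.values.index)]
    k = len(probes)
    if k == 0:
        raise EmptyRegionError(f"no CpGs found in region {region}")
    if k < min_cpgs:
        raise RegionTooSmallError(
            f"region {region} has {k} CpG(s); at least {min_cpgs} required"
        )
    return m.values.loc[probes], list(probes)


@dataclass
class DesignMatrix:
    """Centered predictor matrix (samples x m) with optional conditioning block.

    ``values`` holds the outcome predictors (dummy-coded factors and/or
    numeric variables, mean-centered, full column rank).  ``conditioning``
    holds covariates to be partialled out before the constrained fit.
    """

    values: np.ndarray
    column_names: list[str]
    sample_ids: list[str] = field(default_factory=list)
    conditioning: np.ndarray | None = None
    conditioning_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("design values must be 2-dimensional")
        if self.conditioning is not None:
            self.conditioning = np.asarray(self.conditioning, dtype=float)
            if self.conditioning.shape[0] != self.values.shape[0]:
                raise FormatError("conditioning rows must match design rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def q(self) -> int:
        return 0 if self.conditioning is None else self.conditioning.shape[1]


def _encode_columns(
    phenotypes: pd.DataFrame, columns: Sequence[str], what: str
) -> tuple[np.ndarray, list[str]]:
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in columns:
        if col not in phenotypes.columns:
            raise FormatError(f"unknown {what} column {col!r}")
        series = phenotypes[col]
        if series.isna().any():
            raise FormatError(f"{what} column {col!r} has missing values")
        if pd.api.types.is_numeric_dtype(series) and not isinstance(
            series.dtype, pd.CategoricalDtype
        ):
            blocks.append(series.to_numpy(dtype=float)[:, None])
            names.append(col)
        else:
            levels = sorted(map(str, series.unique()))
            if len(levels) < 2:
                raise FormatError(
                    f"{what} column {col!r} has fewer than 2 observed levels"
                )
            as_str = series.astype(str)
            # first lexicographic level is the reference
            for level in levels[1:]:
                blocks.append((as_str == level).to_numpy(dtype=float)[:, None])
                names.append(f"{col}[{level}]")
    if not blocks:
        return np.empty((len(phenotypes), 0)), []
    return np.hstack(blocks), names


def encode_design(
    phenotypes: pd.DataFrame,
    outcomes: Sequence[str],
    covariates: Sequence[str] = (),
) -> DesignMatrix:
    """Build a centered design matrix from a phenotype table.

    Categorical variables are dummy-coded with the first lexicographic
    level as reference (only the span of the contrasts matters for R2);
    all columns are mean-centered.  ``covariates`` go into the
    conditioning block that is partialled out before the constrained fit.
    """
    x, x_names = _encode_columns(phenotypes, outcomes, "outcome")
    x = x - x.mean(axis=0, keepdims=True)
    if x.shape[1]:
        scale = np.abs(x).max(axis=0)
        if (scale < 1e-12).any():
            bad = [n for n, s in zip(x_names, scale) if s < 1e-12]
            raise RankError(f"constant column(s) after centering: {bad}")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise RankError("design matrix is rank deficient after encoding")
    z: np.ndarray | None = None
    z_names: list[str] = []
    if covariates:
        z, z_names = _encode_columns(phenotypes, covariates, "covariate")
        z = z - z.mean(axis=0, keepdims=True)
        if np.linalg.matrix_rank(z) < z.shape[1]:
            raise RankError("conditioning block is rank deficient after encoding")
    return DesignMatrix(
        values=x,
        column_names=x_names,
        sample_ids=list(map(str, phenotypes.index)),
        conditioning=z,
        conditioning_names=z_names,
    )
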