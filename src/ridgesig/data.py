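"""Genotype and phenotype containers and the standard preprocessing step.

Genotypes are held as an n x m matrix of minor-allele counts (samples in
rows, SNPs in columns).  Raw matrices hold values in {0, 1, 2} with NaN for
missing calls; the :func:`preprocess` step imputes missing calls with the
column mean, drops SNPs that are invariant in the sample, and standardises
every surviving column to mean zero and unit standard deviation, which is
the form the ridge models expect.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_STD_TOL = 1e-10


@dataclass
class GenotypeMatrix:
    """n x m matrix of minor-allele counts with SNP metadata.

    Parameters
    ----------
    values : ndarray, shape (n, m)
        Minor-allele counts in {0, 1, 2} (NaN = missing) for raw data, or
        real-valued columns after standardisation.
    snp_ids : sequence of str
        Unique identifier per SNP column.
    standardized : bool
        Whether columns have been centred and scaled.
    """

    values: np.ndarray
    snp_ids: np.ndarray
    standardized: bool = False
    #: indices into the original matrix for each surviving column
    source_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if self.snp_ids.shape[0] != self.values.shape[1]:
            raise ValidationError(
                f"{self.snp_ids.shape[0]} SNP ids for {self.values.shape[1]} columns"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("snp_ids must be unique")
        if not self.standardized:
            vals = self.values[~np.isnan(self.values)]
            if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
                raise ValidationError("raw genotype values must lie in {0, 1, 2} or be missing")
        if self.source_index is None:
            self.source_index = np.arange(self.values.shape[1])

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per SNP (folded to <= 0.5).

        Computed from raw allele counts; missing calls are ignored.
        """
        if self.standardized:
            raise ValidationError("MAF is defined on raw allele counts, not standardised values")
        freq = np.nanmean(self.values, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class Phenotype:
    """Response vector, either continuous or binary 0/1."""

    y: np.ndarray
    kind: str  # "continuous" | "binary"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.kind not in ("continuous", "binary"):
            raise ValidationError(f"unknown phenotype kind {self.kind!r}")
        if not np.isfinite(self.y).all():
            raise ValidationError("phenotype contains non-finite values")
        if self.kind == "binary" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValidationError("binary phenotype must contain only 0/1")

    def __len__(self) -> int:
        return self.y.size


@dataclass
class PenaltySpec:
    """Shrinkage parameter plus a per-column penalisation mask.

    ``penalize_mask[j] = False`` leaves column j unpenalised (used for
    covariates such as age or smoking status that enter the model as
    unconstrained parameters).
    """

    lam: float
    penalize_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lam = float(self.lam)
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValidationError("shrinkage parameter lambda must be finite and >= 0")
        if self.penalize_mask is not None:
            self.penalize_mask = np.asarray(self.penalize_mask, dtype=bool).ravel()

    def mask_for(self, width: int) -> np.ndarray:
        if self.penalize_mask is None:
            return np.ones(width, dtype=bool)
        if self.penalize_mask.size != width:
            raise ValidationError(
                f"penalize_mask length {self.penalize_mask.size} != design width {width}"
            )
        return self.penalize_mask


def preprocess(G: GenotypeMatrix, impute_missing: bool = True) -> GenotypeMatrix:
    """Impute missing calls, drop invariant SNPs and standardise columns.

    Missing genotypes are replaced by the column mean (mean imputation).
    SNPs invariant in the sample carry no association information and their
    standardisation would divide by zero, so they are removed; the surviving
    columns are centred and scaled to unit standard deviation (computed with
    the n denominator).

    Returns a new standardised :class:`GenotypeMatrix`; ``source_index``
    maps surviving columns back to the input matrix.
    """
    X = np.array(G.values, dtype=float)
    if impute_missing and np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        # columns that are entirely missing stay NaN and get dropped below
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_mean, idx[1])
    if np.isnan(X).any():
        bad = np.unique(np.where(np.isnan(X))[1])
        raise ValidationError(
            f"missing genotypes remain in columns {bad.tolist()}; enable impute_missing"
        )
    sd = X.std(axis=0)
    keep = sd > _STD_TOL
    if not keep.any():
        raise ValidationError("all SNP columns are invariant in this sample")
    dropped = [str(s) for s in G.snp_ids[~keep]]
    if dropped:
        logger.info("dropping %d invariant SNPs: %s", len(dropped), ", ".join(dropped[:10]))
        warnings.warn(f"dropped {len(dropped)} invariant SNP(s)", UserWarning, stacklevel=2)
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return GenotypeMatrix(
        values=X,
        snp_ids=G.snp_ids[keep],
        standardized=True,
        source_index=G.source_index[keep],
    )


def as_design(X) -> np.ndarray:
    """Coerce a GenotypeMatrix, DataFrame or array to a 2-D float design matrix."""
    if isinstance(X, GenotypeMatrix):
        arr = X.values
    elif hasattr(X, "to_numpy"):
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.isfinite(arr).all():
        raise ValidationError("design matrix contains non-finite entries")
    return arr
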