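r"""Shrinkage-parameter selection and ridge / p-value traces.

``lambda_hkb`` implements the Hoerl-Kennard-Baldwin estimate
:math:`\lambda_{HKB} = m\hat\sigma^2/(\hat\beta'\hat\beta)` computed from
ordinary least squares quantities (so it requires m < n and a full-rank
design).

The ridge trace plots the coefficient paths :math:`\hat\beta_\lambda` as
lambda increases from zero; the p-value trace plots the p-values of the
coefficients (conventionally on a -log10 scale) over the same grid.  Both
are emitted as data for user inspection — the "stabilisation" point is a
judgement call, not auto-detected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PenaltySpec, as_design
from .exceptions import RidgeSigError, SingularityError, ValidationError
from .linear import LinearRidge
from .logistic import LogisticRidge
from .significance import approximate_test, permutation_test

#: default grid: 25 log-spaced points covering the working range of
#: genetic applications (lambda ~ 0.1-100, plus margin either side)
DEFAULT_LAM_GRID = np.logspace(-2, 4, 25)

#: base of the logarithm used when presenting p-value traces
PVALUE_TRACE_LOG_BASE = 10


@dataclass
class TraceResult:
    """Coefficients and p-values over an increasing lambda grid."""

    lam_grid: np.ndarray
    coefficients: np.ndarray  # grid x m
    p_values: np.ndarray | None = None  # grid x m, raw (untransformed) p
    test_variant: str | None = None  # "approximate" | "permutation"
    snp_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        """Tidy long-format table: lambda, snp_id, coefficient, p_value."""
        import pandas as pd

        grid, m = self.coefficients.shape
        ids = (self.snp_ids if self.snp_ids is not None
               else np.array([f"x{j}" for j in range(m)], dtype=object))
        rows = {
            "lambda": np.repeat(self.lam_grid, m),
            "snp_id": np.tile(ids, grid),
            "coefficient": self.coefficients.ravel(),
            "p_value": (self.p_values.ravel() if self.p_values is not None
                        else np.full(grid * m, np.nan)),
        }
        return pd.DataFrame(rows)

    def plot(self, ax=None, kind: str = "coefficients"):
        """Line plot per SNP against lambda (log axis).

        ``kind="p_values"`` plots -log10 p instead of coefficients.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if kind == "coefficients":
            Y, ylabel = self.coefficients, "coefficient"
        elif kind == "p_values":
            if self.p_values is None:
                raise ValidationError("trace carries no p-values")
            Y = -np.log10(np.clip(self.p_values, 1e-300, None))
            ylabel = f"-log{PVALUE_TRACE_LOG_BASE}(p)"
        else:
            raise ValidationError(f"unknown plot kind {kind!r}")
        for j in range(Y.shape[1]):
            label = None if self.snp_ids is None else str(self.snp_ids[j])
            ax.plot(self.lam_grid, Y[:, j], lw=0.8, label=label)
        ax.set_xscale("log")
        ax.set_xlabel(r"$\lambda$")
        ax.set_ylabel(ylabel)
        return ax


def _check_grid(lam_grid) -> np.ndarray:
    grid = np.asarray(lam_grid, dtype=float).ravel()
    if grid.size == 0 or (grid < 0).any() or (np.diff(grid) <= 0).any():
        raise ValidationError("lam_grid must be strictly increasing and >= 0")
    return grid


def lambda_hkb(X, y) -> float:
    """Hoerl-Kennard-Baldwin shrinkage estimate m*sigma2_OLS / (b'b).

    Uses the OLS residual mean square RSS/(n - m) and OLS coefficients, so
    the design must have more rows than columns and full column rank.  The
    design is column-centred and the response centred first, consistent
    with the ridge-fit convention of standardised predictors.
    """
    Xd = as_design(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, m = Xd.shape
    if m >= n:
        raise SingularityError(
            "lambda_HKB requires OLS estimates (sigma2 and beta from the "
            "unpenalised fit), which need m < n and a full-rank design"
        )
    Xd = Xd - Xd.mean(axis=0)
    yc = yv - yv.mean()
    beta, res, rank, _ = np.linalg.lstsq(Xd, yc, rcond=None)
    if rank < m:
        raise SingularityError("design is rank deficient; OLS estimates undefined")
    rss = float(((yc - Xd @ beta) ** 2).sum())
    sigma2 = rss / (n - m)
    denom = float(beta @ beta)
    if denom == 0:
        raise ValidationError("OLS coefficients are all zero; lambda_HKB undefined")
    return m * sigma2 / denom


def _fit_at(X, y, lam: float, model: str, penalty_mask=None):
    pen = PenaltySpec(lam=lam, penalize_mask=penalty_mask)
    if model == "linear":
        return LinearRidge(y, X, penalty=pen).fit(lam)
    if model == "logistic":
        return LogisticRidge(y, X, penalty=pen).fit(lam)
    raise ValidationError(f"unknown model {model!r}")


def ridge_trace(X, y, lam_grid=DEFAULT_LAM_GRID, model: str = "linear",
                snp_ids=None, penalty_mask=None) -> TraceResult:
    """Coefficient paths over an increasing lambda grid (no p-values)."""
    grid = _check_grid(lam_grid)
    coefs = []
    for lam in grid:
        try:
            coefs.append(_fit_at(X, y, lam, model, penalty_mask).params)
        except RidgeSigError as exc:
            raise type(exc)(f"fit failed at lambda = {lam:g}: {exc}") from exc
    return TraceResult(
        lam_grid=grid, coefficients=np.stack(coefs), snp_ids=snp_ids,
        metadata={"model": model},
    )


def pvalue_trace(X, y, lam_grid=DEFAULT_LAM_GRID, model: str = "linear",
                 test_variant: str = "approximate", B: int = 1000,
                 seed: int | None = None, snp_ids=None,
                 penalty_mask=None) -> TraceResult:
    """Coefficients and raw p-values over a lambda grid.

    Raw p-values are stored; the -log10 transform is applied only when
    plotting (base recorded in metadata).
    """
    grid = _check_grid(lam_grid)
    if test_variant not in ("approximate", "permutation"):
        raise ValidationError(f"unknown test variant {test_variant!r}")
    coefs, pvals = [], []
    seedseq = np.random.SeedSequence(seed) if seed is not None else None
    for i, lam in enumerate(grid):
        try:
            fit = _fit_at(X, y, lam, model, penalty_mask)
            coefs.append(fit.params)
            if test_variant == "approximate":
                pvals.append(approximate_test(fit).p_values)
            else:
                sub = (int(seedseq.spawn(1)[0].generate_state(1)[0] % (2**31))
                       if seedseq is not None else None)
                pen = PenaltySpec(lam=lam, penalize_mask=penalty_mask)
                pvals.append(permutation_test(X, y, pen, model=model, B=B,
                                              seed=sub).p_values)
        except RidgeSigError as exc:
            raise type(exc)(f"trace failed at lambda = {lam:g}: {exc}") from exc
    return TraceResult(
        lam_grid=grid, coefficients=np.stack(coefs), p_values=np.stack(pvals),
        test_variant=test_variant, snp_ids=snp_ids,
        metadata={"model": model, "log_base": PVALUE_TRACE_LOG_BASE, "B": B,
                  "seed": seed},
    )
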