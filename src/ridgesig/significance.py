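r"""Significance tests for ridge regression coefficients.

The approximate (Wald-type) test uses

.. math:: T_\lambda = \hat\beta_{j\lambda} / se(\hat\beta_{j\lambda}),

with the standard error taken from the sandwich covariance of the fitted
ridge model.  Under the null the statistic is referred to the standard
normal distribution or, for the linear model, optionally to a Student t
distribution with :math:`n - \mathrm{tr}(H)` degrees of freedom; the two
agree for the large samples typical of genetic data.

The permutation benchmark refits the ridge model on B random permutations
of the response and computes, per coefficient, the proportion of permuted
coefficients at least as large in absolute value as the observed one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import PenaltySpec, Phenotype, as_design
from .exceptions import ConvergenceError, ValidationError
from .linear import LinearRidge, LinearRidgeResults
from .logistic import LogisticRidge, LogisticRidgeResults


@dataclass
class SignificanceResult:
    """Per-coefficient Wald-type statistics and p-values."""

    statistics: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    null_dist: str  # "normal" | "student_t"
    lam: float
    df: float | None = None  # n - tr(H), student_t only

    def __post_init__(self):
        assert ((self.p_values >= 0) & (self.p_values <= 1)).all()


@dataclass
class PermutationResult:
    """Permutation-test p-values for ridge coefficients.

    ``p_values`` lie on the grid {0, 1/B, ..., 1}; an exact zero means no
    permuted coefficient reached the observed magnitude and is reported as
    "< 1/B" in formatted output.
    """

    p_values: np.ndarray
    B: int
    seed: int | None
    null_coefficients: np.ndarray | None = None
    n_failed: int = 0

    def formatted(self) -> list[str]:
        return [f"<{1.0 / self.B:.6g}" if p == 0.0 else f"{p:.6g}" for p in self.p_values]


def approximate_test(fit: LinearRidgeResults | LogisticRidgeResults,
                     null_dist: str = "normal") -> SignificanceResult:
    """Approximate test of significance for the coefficients of a ridge fit.

    Parameters
    ----------
    fit : LinearRidgeResults or LogisticRidgeResults
        A fitted ridge model carrying its covariance.
    null_dist : {"normal", "student_t"}
        Null reference distribution.  ``"student_t"`` (df = n - tr(H)) is
        defined only for the linear model.
    """
    if null_dist not in ("normal", "student_t"):
        raise ValidationError(f"unknown null distribution {null_dist!r}")
    se = fit.bse
    params = fit.params
    const = se <= 0
    if const.any():
        raise ValidationError(
            f"zero standard error for coefficient(s) {np.where(const)[0].tolist()}; "
            "constant or degenerate column in the design"
        )
    T = params / se
    df = None
    if null_dist == "student_t":
        if not isinstance(fit, LinearRidgeResults):
            raise ValidationError(
                "the t-distributed variant (df = n - tr(H)) applies to the linear "
                "model only; use null_dist='normal' for logistic ridge"
            )
        df = fit.nobs - fit.edf_model
        if df <= 0:
            raise ValidationError(f"n - tr(H) = {df:.3g} <= 0; increase lambda")
        p = 2.0 * stats.t.sf(np.abs(T), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(T))
    return SignificanceResult(
        statistics=T, standard_errors=se, p_values=np.minimum(p, 1.0),
        null_dist=null_dist, lam=fit.lam, df=df,
    )


def permutation_test(X, y, penalty: PenaltySpec, model: str = "linear",
                     B: int = 1000, seed: int | None = None,
                     keep_null: bool = False,
                     max_iter: int = 50, tol: float = 1e-8) -> PermutationResult:
    """Permutation test for ridge regression coefficients.

    The response is permuted B times (default 1000); the ridge model is
    refitted at the same lambda on each permuted response, and the p-value
    of coefficient j is the proportion of permuted coefficients whose
    absolute value is >= the observed |beta_j| (denominator B).

    Logistic refits that fail to converge are excluded with a warning; more
    than 10% failures is an error.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if model not in ("linear", "logistic"):
        raise ValidationError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    yvec = y.y if isinstance(y, Phenotype) else np.asarray(y, dtype=float).ravel()
    Xd = as_design(X)
    lam = penalty.lam

    if model == "linear":
        mdl = LinearRidge(yvec, Xd, penalty=penalty)
        mdl.fit(lam)  # validates the preconditions at this lambda
        # the ridge solution is linear in y: beta* = M @ y_perm, so all B
        # refits collapse into one matrix product
        if mdl._uniform:
            d = mdl._d
            shrink = d / (d**2 + lam) if lam > 0 else np.where(d > 0, 1.0 / d, 0.0)
            M = (mdl._Vt.T * shrink) @ mdl._U.T
        else:
            A = Xd.T @ Xd + lam * np.diag(mdl.penalize_mask.astype(float))
            M = np.linalg.solve(A, Xd.T)
        yc = yvec - yvec.mean()
        # observed through the same map so exact ties (e.g. the identity
        # permutation) are counted consistently
        observed = np.abs(M @ yc)
        perms = np.stack([rng.permutation(yc) for _ in range(B)])  # B x n
        null = perms @ M.T  # B x m
        n_failed = 0
    else:
        mdl = LogisticRidge(yvec, Xd, penalty=penalty)
        observed = np.abs(mdl.fit(lam, max_iter=max_iter, tol=tol).params)
        rows, n_failed = [], 0
        for _ in range(B):
            yp = rng.permutation(yvec)
            try:
                res = LogisticRidge(yp, Xd, penalty=penalty).fit(
                    lam, max_iter=max_iter, tol=tol)
                if not res.converged:
                    raise ConvergenceError("not converged")
                rows.append(res.params)
            except ConvergenceError:
                n_failed += 1
        if n_failed > 0.10 * B:
            raise ConvergenceError(
                f"{n_failed}/{B} permutation refits failed to converge"
            )
        if n_failed:
            warnings.warn(
                f"excluded {n_failed} non-converged permutation refit(s)",
                UserWarning, stacklevel=2,
            )
        null = np.stack(rows)

    n_used = null.shape[0]
    p = (np.abs(null) >= observed[None, :]).sum(axis=0) / n_used
    return PermutationResult(
        p_values=p, B=B, seed=seed,
        null_coefficients=null if keep_null else None, n_failed=n_failed,
    )


def univariate_test(X, y, model: str = "linear", covariates=None,
                    snp_ids=None) -> np.ndarray:
    """Single-SNP Wald p-values from per-SNP (plus covariates) models.

    Each SNP is tested in its own ordinary linear or logistic regression
    model with an intercept and the optional unpenalised covariates; the
    reported p-value is the Wald p-value of the SNP coefficient.  Invariant
    SNPs yield NaN with a warning.
    """
    import statsmodels.api as sm

    Xd = as_design(X)
    yvec = y.y if isinstance(y, Phenotype) else np.asarray(y, dtype=float).ravel()
    C = as_design(covariates) if covariates is not None else None
    p_values = np.full(Xd.shape[1], np.nan)
    for j in range(Xd.shape[1]):
        col = Xd[:, j]
        if col.std() == 0:
            warnings.warn(f"SNP column {j} is invariant; p = NaN", UserWarning, stacklevel=2)
            continue
        parts = [col[:, None]] if C is None else [col[:, None], C]
        design = sm.add_constant(np.column_stack(parts))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(
                f"SNP column {j} is collinear with the covariates/intercept"
            )
        if model == "linear":
            res = sm.OLS(yvec, design).fit()
        elif model == "logistic":
            res = sm.Logit(yvec, design).fit(disp=0)
        else:
            raise ValidationError(f"unknown model {model!r}")
        p_values[j] = res.pvalues[1]  # column after the constant
    return p_values
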