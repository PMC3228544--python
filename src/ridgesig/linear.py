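r"""Linear ridge regression with effective degrees of freedom and coefficient covariance.

The ridge estimator is

.. math:: \hat\beta_\lambda = (X'X + \lambda I)^{-1} X'Y,

well defined for any :math:`\lambda > 0` even when the number of predictors
m exceeds the sample size n.  The fitted values are :math:`\hat Y = HY` with
hat matrix :math:`H = X(X'X+\lambda I)^{-1}X'`; the model degrees of freedom
are :math:`\mathrm{tr}(H)` and the residual effective degrees of freedom

.. math:: \nu = n - \mathrm{tr}(2H - HH'),

which reduces to :math:`n - m` at :math:`\lambda = 0` with a full-rank
design.  The residual variance estimate is :math:`\hat\sigma^2 =
\mathrm{RSS}/\nu` and the coefficient covariance is the sandwich

.. math:: \mathrm{Var}(\hat\beta_\lambda)
          = \hat\sigma^2 (X'X+\lambda I)^{-1} X'X (X'X+\lambda I)^{-1}.

Everything is computed from a thin SVD of X, so no m x m matrix is ever
inverted when m > n.  Unpenalised columns (covariates) are supported through
a diagonal penalty mask P, in which case the generalised quantities use
:math:`(X'X + \lambda P)^{-1}` formed by a dense solve.
"""
from __future__ import annotations

import numpy as np
from scipy import linalg

from .data import PenaltySpec, Phenotype, as_design
from .exceptions import SingularityError, ValidationError

_RANK_TOL = 1e-12


def _check_lam(lam: float) -> float:
    lam = float(lam)
    if not np.isfinite(lam) or lam < 0:
        raise ValidationError("lambda must be finite and >= 0")
    return lam


class LinearRidge:
    """Linear ridge regression model.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Continuous response.  Centred internally when ``center=True``
        (default); the intercept is then recovered as ``mean(endog)``,
        which is exact for a standardised (column-centred) design.
    exog : GenotypeMatrix, DataFrame or ndarray, shape (n, m)
        Design matrix.  Genotype matrices are expected to be preprocessed
        (standardised) first.
    penalty : PenaltySpec, optional
        Only the ``penalize_mask`` is consulted at model construction; the
        shrinkage parameter itself is passed to :meth:`fit`.
    center : bool
        Centre the response and recover the intercept as its mean.

    Examples
    --------
    >>> model = LinearRidge(y, X)
    >>> res = model.fit(lam=1.0)
    >>> res.params, res.bse, res.edf_model
    """

    def __init__(self, endog, exog, penalty: PenaltySpec | None = None, center: bool = True):
        if isinstance(endog, Phenotype):
            if endog.kind != "continuous":
                raise ValidationError("LinearRidge requires a continuous phenotype")
            endog = endog.y
        self.exog = as_design(exog)
        self.endog = np.asarray(endog, dtype=float).ravel()
        if not np.isfinite(self.endog).all():
            raise ValidationError("response contains non-finite values")
        if self.endog.size != self.exog.shape[0]:
            raise ValidationError("endog and exog have incompatible lengths")
        self.nobs, self.k_exog = self.exog.shape
        mask = (penalty.mask_for(self.k_exog) if penalty is not None
                else np.ones(self.k_exog, dtype=bool))
        self.penalize_mask = mask
        self.center = bool(center)
        self._ymean = self.endog.mean() if center else 0.0
        self._yc = self.endog - self._ymean
        self._uniform = mask.all()
        if self._uniform:
            # thin SVD reused for every lambda: X = U diag(d) Vt
            self._U, self._d, self._Vt = linalg.svd(self.exog, full_matrices=False)
        else:
            self._U = self._d = self._Vt = None

    # ------------------------------------------------------------------
    @property
    def rank(self) -> int:
        if self._uniform:
            return int((self._d > _RANK_TOL * max(self._d.max(), 1.0)).sum())
        return int(np.linalg.matrix_rank(self.exog))

    def _require_invertible(self, lam: float) -> None:
        if lam == 0.0 and self.rank < self.k_exog:
            raise SingularityError(
                "lambda = 0 requires a full-column-rank design; "
                f"rank {self.rank} < m = {self.k_exog} "
                "(m > n or collinear predictors) — use lambda > 0"
            )

    def fit(self, lam: float, sigma2_method: str = "ridge") -> "LinearRidgeResults":
        """Fit the ridge model at shrinkage parameter ``lam``.

        ``sigma2_method`` selects the residuals used for the residual mean
        square: ``"ridge"`` (default) uses the ridge fit itself with
        nu = n - tr(2H - HH'); ``"ols"`` uses the ordinary least squares
        residual mean square RSS/(n - m), available only when m < n.
        """
        lam = _check_lam(lam)
        self._require_invertible(lam)
        if self._uniform:
            d = self._d
            shrink = d / (d**2 + lam) if lam > 0 else np.where(d > 0, 1.0 / d, 0.0)
            uty = self._U.T @ self._yc
            params = self._Vt.T @ (shrink * uty)
        else:
            params = self._solve_masked(lam)
        fitted = self.exog @ params + self._ymean
        resid = self.endog - fitted
        edf_model, edf_resid = self.edf(lam)
        if sigma2_method == "ridge":
            nu = edf_resid
            rss = float(resid @ resid)
        elif sigma2_method == "ols":
            if self.k_exog >= self.nobs:
                raise SingularityError("sigma2_method='ols' requires m < n")
            ols = np.linalg.lstsq(self.exog, self._yc, rcond=None)[0]
            r = self._yc - self.exog @ ols
            rss, nu = float(r @ r), self.nobs - self.k_exog
        else:
            raise ValidationError(f"unknown sigma2_method {sigma2_method!r}")
        if nu <= 0:
            raise ValidationError(
                f"residual effective degrees of freedom nu = {nu:.3g} <= 0; "
                "increase lambda or reduce the number of predictors"
            )
        sigma2 = rss / nu
        return LinearRidgeResults(
            model=self, lam=lam, params=params, intercept=self._ymean,
            fittedvalues=fitted, resid=resid, sigma2=sigma2,
            edf_model=edf_model, edf_resid=edf_resid,
        )

    def _solve_masked(self, lam: float) -> np.ndarray:
        """Masked-penalty solve via augmented least squares (no m x m inverse)."""
        mask = self.penalize_mask
        if lam > 0:
            extra = np.sqrt(lam) * np.eye(self.k_exog)[mask.nonzero()[0]]
            A = np.vstack([self.exog, extra])
            b = np.concatenate([self._yc, np.zeros(extra.shape[0])])
        else:
            A, b = self.exog, self._yc
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < self.k_exog:
            raise SingularityError(
                "design with unpenalised columns is rank deficient at this lambda"
            )
        return sol

    def edf(self, lam: float) -> tuple[float, float]:
        """Model and residual effective degrees of freedom at ``lam``.

        Spectral form: with singular values d_i of X,
        tr(H) = sum d_i^2/(d_i^2+lam) and
        nu = n - sum [2 d_i^2/(d_i^2+lam) - d_i^4/(d_i^2+lam)^2].
        """
        lam = _check_lam(lam)
        if self._uniform:
            d2 = self._d**2
            with np.errstate(invalid="ignore", divide="ignore"):
                h = np.where(d2 + lam > 0, d2 / (d2 + lam), 0.0)
        else:
            A = self.exog.T @ self.exog + lam * np.diag(self.penalize_mask.astype(float))
            H = self.exog @ linalg.solve(A, self.exog.T, assume_a="sym")
            h = np.linalg.eigvalsh(H)
        edf_model = float(h.sum())
        edf_resid = float(self.nobs - (2 * h - h**2).sum())
        return edf_model, edf_resid

    def cov_params(self, lam: float, sigma2: float) -> np.ndarray:
        """Sandwich covariance sigma2 * Ainv X'X Ainv with A = X'X + lam*P."""
        if self._uniform:
            d2 = self._d**2
            w = d2 / (d2 + lam) ** 2 if lam > 0 else np.where(d2 > 0, 1.0 / d2, 0.0)
            return sigma2 * (self._Vt.T * w) @ self._Vt
        A = self.exog.T @ self.exog + lam * np.diag(self.penalize_mask.astype(float))
        Ainv = linalg.inv(A)
        XtX = self.exog.T @ self.exog
        return sigma2 * Ainv @ XtX @ Ainv


class LinearRidgeResults:
    """Results of a linear ridge fit at a single shrinkage parameter.

    Attributes
    ----------
    params : ndarray, shape (m,)
        Ridge coefficient estimates.
    intercept : float
        Recovered intercept (mean of the response when centring is on).
    sigma2 : float
        Residual mean square RSS / nu.
    edf_model, edf_resid : float
        tr(H) and nu = n - tr(2H - HH').
    """

    def __init__(self, model, lam, params, intercept, fittedvalues, resid,
                 sigma2, edf_model, edf_resid):
        self.model = model
        self.lam = lam
        self.params = params
        self.intercept = intercept
        self.fittedvalues = fittedvalues
        self.resid = resid
        self.sigma2 = sigma2
        self.edf_model = edf_model
        self.edf_resid = edf_resid
        self._cov = None

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def cov_params(self) -> np.ndarray:
        if self._cov is None:
            self._cov = self.model.cov_params(self.lam, self.sigma2)
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        """Standard errors: square roots of the covariance diagonal."""
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0.0, None))

    def test_significance(self, null_dist: str = "normal"):
        from .significance import approximate_test

        return approximate_test(self, null_dist=null_dist)

    def summary(self, snp_ids=None) -> str:
        from .significance import approximate_test

        sig = approximate_test(self)
        ids = snp_ids if snp_ids is not None else [f"x{j}" for j in range(self.params.size)]
        lines = [
            "Linear ridge regression results",
            "=" * 64,
            f"n obs: {self.nobs:>8d}    m predictors: {self.params.size:>6d}",
            f"lambda: {self.lam:<10.6g} sigma2: {self.sigma2:<10.6g}",
            f"edf (model): {self.edf_model:<10.4f} edf (residual): {self.edf_resid:<10.4f}",
            "-" * 64,
            f"{'term':<16}{'coef':>12}{'se':>12}{'T':>10}{'P>|T|':>12}",
        ]
        for i, name in enumerate(ids):
            lines.append(
                f"{str(name):<16}{self.params[i]:>12.5f}{sig.standard_errors[i]:>12.5f}"
                f"{sig.statistics[i]:>10.3f}{sig.p_values[i]:>12.4g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


def fit_linear_ridge(X, y, penalty: PenaltySpec) -> LinearRidgeResults:
    """Functional wrapper: fit a linear ridge model under a PenaltySpec."""
    return LinearRidge(y, X, penalty=penalty).fit(penalty.lam)


def effective_degrees_of_freedom(X, lam: float) -> tuple[float, float]:
    """(tr(H), nu) for design X at shrinkage lam, via singular values."""
    X = as_design(X)
    d = linalg.svdvals(X)
    lam = _check_lam(lam)
    d2 = d**2
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(d2 + lam > 0, d2 / (d2 + lam), 0.0)
    return float(h.sum()), float(X.shape[0] - (2 * h - h**2).sum())
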