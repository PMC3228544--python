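r"""Penalised (ridge) logistic regression fitted by Newton-Raphson.

The penalised log-likelihood is

.. math:: \ell_\lambda(\beta) = \sum_i \big[y_i x_i\beta - \log(1+e^{x_i\beta})\big]
          - \lambda \beta' P \beta,

with P a diagonal 0/1 penalty mask (the intercept is always unpenalised).
Each Newton step solves

.. math:: (X'WX + 2\lambda P)\,\beta_{\mathrm{new}} = X'Wz,

where :math:`W = \mathrm{diag}\,\hat p_i(1-\hat p_i)` and z is the working
response :math:`z_i = \mathrm{logit}\,\hat p_i + (y_i-\hat p_i)/(\hat
p_i(1-\hat p_i))`.  The coefficient covariance is estimated from the final
iteration as the sandwich

.. math:: (X'WX+2\lambda P)^{-1}\, X'WX\, (X'WX+2\lambda P)^{-1}.

Plain Newton-Raphson can overshoot on near-separable data, so a step is
halved (up to 20 times) whenever it would decrease the penalised
log-likelihood; the penalty guarantees a finite maximiser for any
:math:`\lambda > 0`.
"""
from __future__ import annotations

import numpy as np
from scipy import linalg

from .data import PenaltySpec, Phenotype, as_design
from .exceptions import ConvergenceError, SingularityError, ValidationError

_W_FLOOR = 1e-10


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))


class LogisticRidge:
    """Ridge-penalised logistic regression model.

    Parameters
    ----------
    endog : array-like of 0/1, shape (n,)
        Binary response; both classes must be present.
    exog : GenotypeMatrix, DataFrame or ndarray, shape (n, m)
        Predictors (standardised genotypes, optionally covariates).
    penalty : PenaltySpec, optional
        Mask over exog columns; columns with ``False`` are unpenalised.
    add_intercept : bool
        Prepend an unpenalised intercept column (default; a case-control
        intercept absorbs prevalence and must not be shrunk).
    """

    def __init__(self, endog, exog, penalty: PenaltySpec | None = None,
                 add_intercept: bool = True):
        if isinstance(endog, Phenotype):
            if endog.kind != "binary":
                raise ValidationError("LogisticRidge requires a binary phenotype")
            endog = endog.y
        self.exog = as_design(exog)
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.endog.size != self.exog.shape[0]:
            raise ValidationError("endog and exog have incompatible lengths")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValidationError("logistic response must be coded 0/1")
        if self.endog.min() == self.endog.max():
            raise ValidationError("response contains a single class; both 0 and 1 required")
        self.nobs, self.k_exog = self.exog.shape
        mask = (penalty.mask_for(self.k_exog) if penalty is not None
                else np.ones(self.k_exog, dtype=bool))
        self.add_intercept = bool(add_intercept)
        if add_intercept:
            self._design = np.column_stack([np.ones(self.nobs), self.exog])
            self._mask = np.concatenate([[False], mask])
        else:
            self._design = self.exog
            self._mask = mask

    # ------------------------------------------------------------------
    def _penalized_llf(self, beta: np.ndarray, lam: float) -> float:
        eta = self._design @ beta
        ll = float(self.endog @ eta - _log1pexp(eta).sum())
        return ll - lam * float(beta[self._mask] @ beta[self._mask])

    def fit(self, lam: float, max_iter: int = 50, tol: float = 1e-8,
            max_halvings: int = 20) -> "LogisticRidgeResults":
        """Maximise the penalised log-likelihood by Newton-Raphson.

        Convergence is declared when the largest absolute coefficient change
        in a step drops below ``tol``.
        """
        lam = float(lam)
        if lam < 0 or not np.isfinite(lam):
            raise ValidationError("lambda must be finite and >= 0")
        Xf = self._design
        n, k = Xf.shape
        if lam == 0.0 and np.linalg.matrix_rank(Xf) < k:
            raise SingularityError(
                "lambda = 0 with a rank-deficient design (m >= n or collinear "
                "predictors); the maximum likelihood estimate is not unique"
            )
        maskdiag = 2.0 * lam * self._mask.astype(float)
        beta = np.zeros(k)
        if self.add_intercept:
            ybar = self.endog.mean()
            beta[0] = np.log(ybar / (1.0 - ybar))
        llf = self._penalized_llf(beta, lam)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = Xf @ beta
            p = _sigmoid(eta)
            w = np.clip(p * (1.0 - p), _W_FLOOR, None)
            # Newton direction: solve (X'WX + 2 lam P) step = grad
            grad = Xf.T @ (self.endog - p) - maskdiag * beta
            A = (Xf * w[:, None]).T @ Xf
            A[np.diag_indices_from(A)] += maskdiag
            try:
                step = linalg.solve(A, grad, assume_a="pos")
            except linalg.LinAlgError as exc:  # pragma: no cover - guarded by lam>0
                raise ConvergenceError(f"singular Newton system at iteration {n_iter}") from exc
            if not np.isfinite(step).all():
                raise ConvergenceError(f"non-finite Newton update at iteration {n_iter}")
            scale = 1.0
            for _ in range(max_halvings + 1):
                cand = beta + scale * step
                cand_llf = self._penalized_llf(cand, lam)
                if cand_llf >= llf - 1e-12 * (1.0 + abs(llf)):
                    break
                scale *= 0.5
            beta, llf = cand, cand_llf
            if np.max(np.abs(scale * step)) < tol:
                converged = True
                break
        eta = Xf @ beta
        p = _sigmoid(eta)
        w = np.clip(p * (1.0 - p), _W_FLOOR, None)
        z = eta + (self.endog - p) / w
        return LogisticRidgeResults(
            model=self, lam=lam, beta_full=beta, probs=p, weights=w,
            working_response=z, n_iter=n_iter, converged=converged,
            penalized_llf=llf, tol=tol,
        )


class LogisticRidgeResults:
    """Results of a penalised logistic fit at a single shrinkage parameter."""

    def __init__(self, model, lam, beta_full, probs, weights, working_response,
                 n_iter, converged, penalized_llf, tol):
        self.model = model
        self.lam = lam
        self._beta_full = beta_full
        self.probs = probs
        self.weights = weights
        self.working_response = working_response
        self.n_iter = n_iter
        self.converged = converged
        self.penalized_llf = penalized_llf
        self.tol = tol
        self._cov_full = None

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def intercept(self) -> float:
        return float(self._beta_full[0]) if self.model.add_intercept else 0.0

    @property
    def params(self) -> np.ndarray:
        """Coefficients for the exog columns (intercept excluded)."""
        return self._beta_full[1:] if self.model.add_intercept else self._beta_full

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.probs

    def _full_cov(self) -> np.ndarray:
        if not self.converged:
            raise ConvergenceError(
                "covariance is estimated from the final Newton-Raphson iteration "
                "and is undefined for a non-converged fit"
            )
        if self._cov_full is None:
            Xf = self.model._design
            w = self.weights
            B = (Xf * w[:, None]).T @ Xf
            A = B.copy()
            A[np.diag_indices_from(A)] += 2.0 * self.lam * self.model._mask.astype(float)
            Ainv_B = linalg.solve(A, B, assume_a="pos")
            cov = linalg.solve(A, Ainv_B.T, assume_a="pos").T
            self._cov_full = (cov + cov.T) / 2.0
        return self._cov_full

    def cov_params(self) -> np.ndarray:
        """Sandwich covariance of the exog coefficients (intercept marginalised out)."""
        cov = self._full_cov()
        return cov[1:, 1:] if self.model.add_intercept else cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0.0, None))

    def test_significance(self, null_dist: str = "normal"):
        from .significance import approximate_test

        return approximate_test(self, null_dist=null_dist)

    def summary(self, snp_ids=None) -> str:
        from .significance import approximate_test

        sig = approximate_test(self)
        ids = snp_ids if snp_ids is not None else [f"x{j}" for j in range(self.params.size)]
        lines = [
            "Logistic ridge regression results",
            "=" * 64,
            f"n obs: {self.nobs:>8d}    m predictors: {self.params.size:>6d}",
            f"lambda: {self.lam:<10.6g} iterations: {self.n_iter} "
            f"converged: {self.converged}",
            f"penalised log-likelihood: {self.penalized_llf:.6f}",
            f"intercept (unpenalised): {self.intercept:.5f}",
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


def fit_logistic_ridge(X, y, penalty: PenaltySpec, max_iter: int = 50,
                       tol: float = 1e-8) -> LogisticRidgeResults:
    """Functional wrapper around :class:`LogisticRidge`."""
    return LogisticRidge(y, X, penalty=penalty).fit(penalty.lam, max_iter=max_iter, tol=tol)
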