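"""Ridge-regression BLUP with REML variance components.

The model is the standard genomic-selection mixed model

    y = 1 mu + Z u + e,   u ~ N(0, I sigma2_u),   e ~ N(0, I sigma2_e),

with y the n-vector of phenotypes, Z the n x m marker matrix (fed exactly as
encoded, never standardized), mu the grand mean and u the m-vector of marker
effects.  With lam = sigma2_e / sigma2_u, the BLUP of u at known lam is the
ridge solution of the mixed-model equations

    [[1'1, 1'Z], [Z'1, Z'Z + lam I]] [mu; u] = [1'y; Z'y].

lam is estimated by REML: the restricted likelihood of y under
y ~ N(1 mu, sigma2_u (Z Z' + lam I)) is profiled over mu and sigma2_u via a
one-time eigendecomposition of the intercept-projected kernel Z Z', leaving
a smooth 1-D criterion in log(lam) that is maximized numerically.

Usage follows the Model/Results convention::

    model = RidgeBLUP(y, Z)
    res = model.fit()
    gebv = res.predict(Z_new)
    print(res.summary())
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .encoding import MarkerMatrix

__all__ = ["RidgeBLUP", "RidgeBLUPResults", "solve_given_lambda", "reml_loglik"]

LAMBDA_BOUNDS = (1e-9, 1e9)


def _as_matrix(Z) -> tuple[np.ndarray, Optional[list[str]]]:
    if isinstance(Z, MarkerMatrix):
        return Z.values, Z.marker_ids
    return np.asarray(Z, dtype=float), None


def _validate(Z: np.ndarray, y: np.ndarray) -> None:
    if Z.ndim != 2:
        raise ValueError("Z must be 2-D")
    if y.ndim != 1 or y.shape[0] != Z.shape[0]:
        raise ValueError("y must be a vector with one entry per row of Z")
    if np.isnan(Z).any() or np.isnan(y).any():
        raise ValueError("Z and y must not contain missing values")
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 observations")


def solve_given_lambda(
    Z,
    y: np.ndarray,
    lam: float,
    fit_intercept: bool = True,
    method: str = "auto",
) -> tuple[float, np.ndarray]:
    """Solve the mixed-model equations for (mu, u) at a fixed ridge parameter.

    Parameters
    ----------
    Z, y
        Marker matrix (array or :class:`MarkerMatrix`) and phenotype vector.
    lam
        Ridge parameter lam = sigma2_e / sigma2_u; must be > 0.
    fit_intercept
        If False, mu is constrained to 0 and u = (Z'Z + lam I)^-1 Z'y.
    method
        "primal" solves the (m x m) system, "kernel" the (n x n) dual via
        u = Z' V^-1 (y - 1 mu) with V = Z Z' + lam I; "auto" picks the
        smaller one.  Both agree to numerical precision.
    """
    Zv, _ = _as_matrix(Z)
    y = np.asarray(y, dtype=float)
    _validate(Zv, y)
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    n, m = Zv.shape
    if method == "auto":
        method = "kernel" if m > n else "primal"
    if method not in ("primal", "kernel"):
        raise ValueError(f"unknown method {method!r}")

    if method == "primal":
        A = Zv.T @ Zv + lam * np.eye(m)
        if fit_intercept:
            ones = np.ones(n)
            top = np.concatenate(([n], ones @ Zv))
            rest = np.column_stack([Zv.T @ ones, A])
            full = np.vstack([top, rest])
            rhs = np.concatenate(([ones @ y], Zv.T @ y))
            sol = np.linalg.solve(full, rhs)
            return float(sol[0]), sol[1:]
        u = np.linalg.solve(A, Zv.T @ y)
        return 0.0, u

    V = Zv @ Zv.T + lam * np.eye(n)
    cho = scipy.linalg.cho_factor(V, lower=True)
    if fit_intercept:
        ones = np.ones(n)
        vi_y = scipy.linalg.cho_solve(cho, y)
        vi_1 = scipy.linalg.cho_solve(cho, ones)
        mu = float(ones @ vi_y) / float(ones @ vi_1)
        u = Zv.T @ scipy.linalg.cho_solve(cho, y - mu * ones)
        return mu, u
    u = Zv.T @ scipy.linalg.cho_solve(cho, y)
    return 0.0, u


def _reml_spectrum(Zv: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues theta and transformed data eta for the profiled REML.

    The intercept is projected out with an orthonormal basis Q2 of the
    complement of the ones vector (n x (n-1)); theta are the eigenvalues of
    Q2' Z Z' Q2 and eta the rotated projected phenotypes.
    """
    n = Zv.shape[0]
    q_full, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
    q2 = q_full[:, 1:]
    zt = q2.T @ Zv
    k_tilde = zt @ zt.T
    theta, vec = np.linalg.eigh(k_tilde)
    theta = np.clip(theta, 0.0, None)  # guard tiny negative round-off
    eta = vec.T @ (q2.T @ y)
    return theta, eta


def _profiled_loglik(theta: np.ndarray, eta: np.ndarray, lam: float) -> float:
    d = theta + lam
    q = eta * eta / d
    s2 = q.sum() / len(eta)
    if s2 <= 0.0:
        return np.inf  # degenerate (constant y); handled by fit()
    return float(
        -0.5 * (len(eta) * (np.log(2.0 * np.pi * s2) + 1.0) + np.log(d).sum())
    )


def reml_loglik(Z, y: np.ndarray, lam: float) -> float:
    """Profiled restricted log-likelihood of y as a function of lam.

    mu is projected out (REML) and the overall scale sigma2_u is profiled
    analytically, so the value depends on y only through intercept-free
    contrasts: it is invariant to adding a constant to y and to permuting
    accessions (rows of Z and y together).
    """
    Zv, _ = _as_matrix(Z)
    y = np.asarray(y, dtype=float)
    _validate(Zv, y)
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    theta, eta = _reml_spectrum(Zv, y)
    return _profiled_loglik(theta, eta, lam)


class RidgeBLUP:
    """Ridge-regression BLUP model for a phenotype on a marker matrix.

    Parameters
    ----------
    endog
        Phenotype vector (length n, no missing values).
    exog_markers
        n x m marker matrix; a :class:`MarkerMatrix` or plain array.  Values
        enter the model exactly as encoded.
    marker_ids
        Optional marker names; taken from the MarkerMatrix when given there.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog_markers,
        marker_ids: Optional[Sequence[str]] = None,
    ) -> None:
        self.Z, ids = _as_matrix(exog_markers)
        self.y = np.asarray(endog, dtype=float)
        _validate(self.Z, self.y)
        if self.Z.shape[1] < 1:
            raise ValueError("need at least one marker column")
        if marker_ids is not None:
            ids = list(marker_ids)
        if ids is not None and len(ids) != self.Z.shape[1]:
            raise ValueError("marker_ids length does not match Z columns")
        self.marker_ids = ids

    @classmethod
    def from_marker_matrix(
        cls, matrix: MarkerMatrix, phenotypes, trait: str
    ) -> "RidgeBLUP":
        """Build from a MarkerMatrix and a phenotype table (trait column).

        Accessions are taken in the matrix's order; a missing phenotype for
        any accession in the matrix is an error (drop accessions first).
        """
        y = phenotypes.loc[matrix.accession_ids, trait].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"trait {trait!r} has missing values for matrix accessions")
        return cls(y, matrix)

    def loglike(self, lam: float) -> float:
        return reml_loglik(self.Z, self.y, lam)

    def fit(self, lam: Optional[float] = None) -> "RidgeBLUPResults":
        """Estimate lam by REML (or use a fixed one) and solve for (mu, u).

        A constant phenotype yields the documented boundary fit sigma2_u = 0,
        u = 0, mu = the constant, rather than an exception.
        """
        if self.Z.shape[0] < 3 and lam is None:
            raise ValueError("REML needs at least 3 observations")
        if np.ptp(self.y) == 0.0:  # y constant: no intercept-free variation at all
            m = self.Z.shape[1]
            return RidgeBLUPResults(
                self, mu=float(self.y.mean()), u=np.zeros(m),
                sigma2_u=0.0, sigma2_e=0.0, lam=np.inf,
                loglik=np.nan, converged=True,
            )
        theta, eta = _reml_spectrum(self.Z, self.y)
        if lam is None:
            lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
            opt = minimize_scalar(
                lambda t: -_profiled_loglik(theta, eta, np.exp(t)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-6},
            )
            lam_hat = float(np.exp(opt.x))
            converged = bool(opt.success)
        else:
            if not lam > 0:
                raise ValueError(f"lam must be > 0, got {lam}")
            lam_hat = float(lam)
            converged = True
        sigma2_u = float((eta * eta / (theta + lam_hat)).sum() / len(eta))
        sigma2_e = lam_hat * sigma2_u
        mu, u = solve_given_lambda(self.Z, self.y, lam_hat)
        return RidgeBLUPResults(
            self, mu=mu, u=u, sigma2_u=sigma2_u, sigma2_e=sigma2_e,
            lam=lam_hat, loglik=_profiled_loglik(theta, eta, lam_hat),
            converged=converged,
        )


class RidgeBLUPResults:
    """Fitted rrBLUP model: grand mean, marker effects, variance components."""

    def __init__(
        self,
        model: RidgeBLUP,
        mu: float,
        u: np.ndarray,
        sigma2_u: float,
        sigma2_e: float,
        lam: float,
        loglik: float,
        converged: bool,
    ) -> None:
        self.model = model
        self.mu = mu
        self.u = np.asarray(u, dtype=float)
        self.sigma2_u = sigma2_u
        self.sigma2_e = sigma2_e
        self.lam = lam
        self.loglik = loglik
        self.converged = converged
        self.marker_ids = model.marker_ids

    @property
    def marker_variance_share(self) -> float:
        """sigma2_u / (sigma2_u + sigma2_e): the per-marker prior-variance
        share, a shrinkage diagnostic — not a trait heritability."""
        tot = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / tot if tot > 0 else 0.0

    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.Z)

    def predict(self, Z_new) -> np.ndarray:
        """Genomic estimated breeding values mu + Z_new u for new accessions.

        When ``Z_new`` is a :class:`MarkerMatrix`, its marker columns must
        match the training marker ids in order.
        """
        Zv, ids = _as_matrix(Z_new)
        if ids is not None and self.marker_ids is not None and ids != self.marker_ids:
            raise ValueError("marker columns of Z_new do not match the fitted model")
        if Zv.ndim != 2 or Zv.shape[1] != self.u.shape[0]:
            raise ValueError(
                f"Z_new has {Zv.shape[1] if Zv.ndim == 2 else '?'} columns, "
                f"model has {self.u.shape[0]} markers"
            )
        return self.mu + Zv @ self.u

    def summary(self) -> str:
        n, m = self.model.Z.shape
        lam = "inf" if np.isinf(self.lam) else f"{self.lam:.6g}"
        lines = [
            "Ridge-regression BLUP (REML)",
            "=" * 44,
            f"{'No. accessions:':<28}{n}",
            f"{'No. markers:':<28}{m}",
            f"{'Grand mean (mu):':<28}{self.mu:.6g}",
            f"{'Marker variance (s2_u):':<28}{self.sigma2_u:.6g}",
            f"{'Residual variance (s2_e):':<28}{self.sigma2_e:.6g}",
            f"{'Ridge parameter (lambda):':<28}{lam}",
            f"{'Restricted log-lik:':<28}{self.loglik:.6g}",
            f"{'Converged:':<28}{self.converged}",
            "=" * 44,
        ]
        return "\n".join(lines)
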