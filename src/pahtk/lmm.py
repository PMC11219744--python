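"""Linear mixed model for log-scale exponential decay with AR(1) residuals.

Model for the outcome y = ln(C - C0) of post-peak decay records:

    y_i = alpha_{b(i)} + lambda_{b(i)} * t_i + u0_{p(i)} + u1_{p(i)} * t_i
          + w_{p(i), s(i)} + eps_i

with fixed per-biomarker intercepts alpha_b (= ln B_b) and slopes lambda_b,
a correlated participant-level random intercept/slope pair (u0, u1) with
unstructured 2x2 covariance G, a session-within-participant random intercept
w with variance tau^2, and residuals eps with variance sigma^2 that are AR(1)
correlated within each time-ordered (participant, session, biomarker) series:
corr(eps_i, eps_j) = phi^|rank_i - rank_j| (discrete-order convention) or
phi^|t_i - t_j| (continuous-time convention for uneven spacing).

Estimation maximizes the restricted (default) or full marginal Gaussian
likelihood over the variance parameters on an unconstrained scale
(log standard deviations, atanh/logit for phi), profiling the fixed effects
out by generalized least squares. The marginal covariance is assembled and
factorized per participant, the natural independence block. Wald standard
errors come from (X' V^-1 X)^-1 at the optimum. All starting values are
fixed functions of the data, so fits are deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = ["MixedModelSpec", "LMMResult", "DecayLMM"]

_LOG_2PI = math.log(2.0 * math.pi)
_LOGSD_LO, _LOGSD_HI = -8.0, 5.0


@dataclass(frozen=True)
class MixedModelSpec:
    """Structure and estimation options for :class:`DecayLMM`.

    ar1: ``"order"`` (phi^|i-j| within a series, the classical discrete
    convention), ``"continuous"`` (phi^|t_i-t_j|, phi constrained to (0,1)),
    or ``"none"``.
    """

    reml: bool = True
    ar1: str = "order"
    random_slope: bool = True
    session_intercept: bool = True
    maxiter: int = 500
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.ar1 not in ("order", "continuous", "none"):
            raise ValueError("ar1 must be 'order', 'continuous' or 'none'")


@dataclass
class LMMResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    fixed_names: list[str]
    varcomps: dict[str, float]
    theta: np.ndarray
    loglik: float
    converged: bool
    message: str
    n_obs: int
    n_fixed: int
    boundary: list[str] = field(default_factory=list)


class DecayLMM:
    """Marginal-likelihood machinery for the decay mixed model."""

    def __init__(self, t, y, biomarker, participant, session,
                 spec: MixedModelSpec | None = None):
        self.spec = spec or MixedModelSpec()
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        biomarker = np.asarray(biomarker).astype(str)
        participant = np.asarray(participant).astype(str)
        session = np.asarray(session).astype(str)
        if not (len(t) == len(y) == len(biomarker) == len(participant) == len(session)):
            raise ValueError("all input arrays must share one length")
        order = np.lexsort((t, biomarker, session, participant))
        self.t, self.y = t[order], y[order]
        self.biomarker = biomarker[order]
        self.participant = participant[order]
        self.session = session[order]
        self.levels: list[str] = sorted(set(self.biomarker))
        K = len(self.levels)
        n = len(self.y)
        self.n, self.K = n, K
        X = np.zeros((n, 2 * K))
        for k, lev in enumerate(self.levels):
            m = self.biomarker == lev
            X[m, k] = 1.0
            X[m, K + k] = self.t[m]
        self.X = X
        self.fixed_names = ([f"intercept[{l}]" for l in self.levels]
                            + [f"slope[{l}]" for l in self.levels])
        self._blocks = []
        for p in sorted(set(self.participant)):
            idx = np.where(self.participant == p)[0]
            tp = self.t[idx]
            Z = np.column_stack([np.ones(len(idx)), tp])
            sess = self.session[idx]
            S = (sess[:, None] == np.array(sorted(set(sess)))[None, :]).astype(float)
            SS = S @ S.T
            series = np.char.add(np.char.add(sess, "||"), self.biomarker[idx])
            same = series[:, None] == series[None, :]
            if self.spec.ar1 == "continuous":
                D = np.abs(tp[:, None] - tp[None, :])
            else:
                rank = np.empty(len(idx))
                for s in set(series):
                    m = series == s
                    rank[m] = np.arange(m.sum())  # rows already time-ordered
                D = np.abs(rank[:, None] - rank[None, :])
            parity = np.where(np.mod(D, 2.0) < 0.5, 1.0, -1.0)
            self._blocks.append((idx, Z, SS, same, D, parity,
                                 self.X[idx], self.y[idx]))

    # -- parameter packing -------------------------------------------------
    @property
    def n_theta(self) -> int:
        k = 1  # log sd resid
        k += 3 if self.spec.random_slope else 1
        if self.spec.session_intercept:
            k += 1
        if self.spec.ar1 != "none":
            k += 1
        return k

    def _unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        i = 0
        if self.spec.random_slope:
            l11, l21, l22 = math.exp(theta[0]), theta[1], math.exp(theta[2])
            L = np.array([[l11, 0.0], [l21, l22]])
            G = L @ L.T
            i = 3
        else:
            G = np.array([[math.exp(2.0 * theta[0])]])
            i = 1
        if self.spec.session_intercept:
            tau2 = math.exp(2.0 * theta[i]); i += 1
        else:
            tau2 = 0.0
        sigma2 = math.exp(2.0 * theta[i]); i += 1
        if self.spec.ar1 == "order":
            phi = math.tanh(theta[i]); i += 1
        elif self.spec.ar1 == "continuous":
            phi = 1.0 / (1.0 + math.exp(-theta[i])); i += 1
        else:
            phi = 0.0
        return G, tau2, sigma2, phi

    def _block_cov(self, block, G, tau2, sigma2, phi):
        idx, Z, SS, same, D, parity, Xp, yp = block
        Zr = Z[:, : G.shape[0]]
        V = Zr @ G @ Zr.T + tau2 * SS
        if phi == 0.0:
            V[np.diag_indices_from(V)] += sigma2
        else:
            mag = np.abs(phi) ** D
            corr = mag * parity if phi < 0 else mag
            V += sigma2 * np.where(same, corr, 0.0)
        return V

    # -- likelihood --------------------------------------------------------
    def _profile(self, theta):
        """Return (logdet sum, A = X'V^-1 X, b = X'V^-1 y, q = y'V^-1 y)."""
        G, tau2, sigma2, phi = self._unpack(theta)
        p = self.X.shape[1]
        A = np.zeros((p, p))
        b = np.zeros(p)
        q = 0.0
        logdet = 0.0
        for block in self._blocks:
            V = self._block_cov(block, G, tau2, sigma2, phi)
            Xp, yp = block[6], block[7]
            c, low = cho_factor(V, lower=True, check_finite=False)
            logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
            Vx = cho_solve((c, low), Xp, check_finite=False)
            Vy = cho_solve((c, low), yp, check_finite=False)
            A += Xp.T @ Vx
            b += Xp.T @ Vy
            q += float(yp @ Vy)
        return logdet, A, b, q

    def neg2loglik(self, theta) -> float:
        """-2 x (restricted) profile log-likelihood, constants included."""
        try:
            logdet, A, b, q = self._profile(theta)
            sign, ldA = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e12
            beta = np.linalg.solve(A, b)
        except (LinAlgError, np.linalg.LinAlgError, ValueError):
            return 1e12
        quad = q - float(b @ beta)
        if not np.isfinite(quad):
            return 1e12
        if self.spec.reml:
            return logdet + ldA + quad + (self.n - self.X.shape[1]) * _LOG_2PI
        return logdet + quad + self.n * _LOG_2PI

    def loglik_at(self, theta, beta) -> float:
        """Exact Gaussian log-likelihood at explicit (theta, beta)."""
        G, tau2, sigma2, phi = self._unpack(theta)
        beta = np.asarray(beta, dtype=float)
        logdet = 0.0
        quad = 0.0
        for block in self._blocks:
            V = self._block_cov(block, G, tau2, sigma2, phi)
            Xp, yp = block[6], block[7]
            r = yp - Xp @ beta
            c, low = cho_factor(V, lower=True, check_finite=False)
            logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
            quad += float(r @ cho_solve((c, low), r, check_finite=False))
        return -0.5 * (logdet + quad + self.n * _LOG_2PI)

    def profile_beta(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed effects and their covariance at fixed theta."""
        _, A, b, _ = self._profile(theta)
        beta = np.linalg.solve(A, b)
        return beta, np.linalg.inv(A)

    # -- estimation --------------------------------------------------------
    def _start(self) -> np.ndarray:
        resid = np.empty(0)
        for lev in self.levels:
            m = self.biomarker == lev
            if m.sum() >= 3 and np.ptp(self.t[m]) > 0:
                c = np.polyfit(self.t[m], self.y[m], 1)
                resid = np.concatenate([resid, self.y[m] - np.polyval(c, self.t[m])])
        v = max(float(np.var(resid)) if len(resid) else 0.0, 1e-8)
        x0 = []
        if self.spec.random_slope:
            x0 += [0.5 * math.log(0.3 * v), 0.0, math.log(0.02)]
        else:
            x0 += [0.5 * math.log(0.3 * v)]
        if self.spec.session_intercept:
            x0 += [0.5 * math.log(0.2 * v)]
        x0 += [0.5 * math.log(0.5 * v)]
        if self.spec.ar1 != "none":
            x0 += [0.0]
        return np.clip(np.array(x0), _LOGSD_LO + 0.5, _LOGSD_HI - 0.5)

    def _bounds(self):
        bounds = []
        if self.spec.random_slope:
            bounds += [(_LOGSD_LO, _LOGSD_HI), (-10.0, 10.0), (_LOGSD_LO, _LOGSD_HI)]
        else:
            bounds += [(_LOGSD_LO, _LOGSD_HI)]
        if self.spec.session_intercept:
            bounds += [(_LOGSD_LO, _LOGSD_HI)]
        bounds += [(_LOGSD_LO, _LOGSD_HI)]
        if self.spec.ar1 != "none":
            bounds += [(-3.8, 3.8)]
        return bounds

    def fit(self) -> LMMResult:
        x0 = self._start()
        bounds = self._bounds()
        res = optimize.minimize(
            self.neg2loglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": self.spec.maxiter, "ftol": self.spec.tol,
                     "gtol": 1e-6},
        )
        best = res
        if not res.success or not np.isfinite(res.fun):
            res2 = optimize.minimize(
                self.neg2loglik, res.x, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-7, "fatol": self.spec.tol},
            )
            if res2.fun <= res.fun:
                best = res2
        theta = np.asarray(best.x, dtype=float)
        beta, cov_beta = self.profile_beta(theta)
        G, tau2, sigma2, phi = self._unpack(theta)
        varcomps = {
            "participant_intercept_sd": math.sqrt(G[0, 0]),
            "session_intercept_sd": math.sqrt(tau2),
            "residual_sd": math.sqrt(sigma2),
            "ar1_phi": phi,
        }
        if self.spec.random_slope:
            varcomps["participant_slope_sd"] = math.sqrt(G[1, 1])
            denom = math.sqrt(G[0, 0] * G[1, 1])
            varcomps["intercept_slope_corr"] = (G[0, 1] / denom) if denom > 0 else 0.0
        boundary = []
        for name, val in (("participant_intercept_sd", G[0, 0]),
                          ("participant_slope_sd",
                           G[1, 1] if self.spec.random_slope else None),
                          ("session_intercept_sd", tau2),
                          ("residual_sd", sigma2)):
            if val is not None and val < math.exp(2 * (_LOGSD_LO + 0.6)):
                boundary.append(name)  # variance pinned at (effectively) zero
        return LMMResult(
            beta=beta, cov_beta=cov_beta, fixed_names=list(self.fixed_names),
            varcomps=varcomps, theta=theta, loglik=-0.5 * float(best.fun),
            converged=bool(best.success and np.isfinite(best.fun)),
            message=str(best.message), n_obs=self.n, n_fixed=self.X.shape[1],
            boundary=boundary,
        )
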