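"""Zero-inflated two-component mixture model for forest IMD values.

Forest IMD has an atom at exactly 0 (variables never entering any tree) plus
a continuous part on (0, 1] that is well described by two components: a
low-mean "noise" component and a higher-mean "signal" component.  The model
is

    x = 0                 with probability p0
    x ~ p f1 + (1 - p) f2 with probability 1 - p0,

where f1, f2 are Gaussian densities (optionally the first one truncated at 0
and renormalized by 1 - Phi(0)).  p0 is estimated as the exact empirical
zero fraction; (p, mu1, sigma1, mu2, sigma2) are fitted to the nonzero
values by EM, maximizing

    n0 log p0 + sum_{x != 0} log(p1 f1(x) + p2 f2(x)),

with p1 = p (1 - p0) and p2 = (1 - p)(1 - p0).  Components are relabelled
after fitting so that component 1 always has the smaller mean (the noise
component); posterior probabilities put all mass on the zero component at
x = 0.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["ZeroInflatedGaussianMixture"]

_SIGMA_FLOOR = 1e-6
_W_FLOOR = 1e-10


class ZeroInflatedGaussianMixture(BaseEstimator):
    """EM fit of the zero-inflated two-component (truncated-)Gaussian mixture.

    Parameters
    ----------
    truncated : if True, the first (noise) component density is a normal
        truncated at 0, ``phi(x) / (1 - Phi(0))``; the second component stays
        an untruncated normal.
    tol : EM convergence tolerance on the log-likelihood change.
    max_iter : EM iteration cap.

    Attributes
    ----------
    p0_ : exact empirical fraction of zeros.
    weight_ : first-component proportion p among nonzero values.
    means_, sigmas_ : component parameters, ordered so means_[0] <= means_[1].
    loglik_ : final modified log-likelihood.
    loglik_trace_ : per-iteration log-likelihood (non-decreasing).
    n_iter_, converged_
    """

    def __init__(self, truncated: bool = False, tol: float = 1e-6, max_iter: int = 1000):
        self.truncated = truncated
        self.tol = tol
        self.max_iter = max_iter

    # --- densities -------------------------------------------------------
    def _f1(self, x, mu, sigma):
        d = stats.norm.pdf(x, mu, sigma)
        if self.truncated:
            d = d / stats.norm.sf(0.0, mu, sigma)
        return d

    @staticmethod
    def _f2(x, mu, sigma):
        return stats.norm.pdf(x, mu, sigma)

    def _loglik(self, x, p, mu1, s1, mu2, s2, n0, p0):
        mix = p * self._f1(x, mu1, s1) + (1 - p) * self._f2(x, mu2, s2)
        ll = np.log(np.maximum(mix, 1e-300)).sum()
        if n0 > 0:
            ll += n0 * np.log(max(p0, _W_FLOOR)) + len(x) * np.log(max(1 - p0, _W_FLOOR))
        return float(ll)

    def fit(self, values):
        x_all = np.asarray(values, dtype=float).ravel()
        if np.any((x_all < 0) | (x_all > 1)):
            raise ValueError("IMD values must lie in [0, 1]")
        n0 = int(np.sum(x_all == 0.0))
        x = x_all[x_all != 0.0]
        if len(x) < 10:
            raise ValueError(
                f"only {len(x)} nonzero values; at least 10 are needed to fit the mixture"
            )
        self.p0_ = n0 / len(x_all)

        # deterministic initialization: split the nonzeros at their 75th percentile
        cut = np.quantile(x, 0.75)
        lo, hi = x[x <= cut], x[x > cut]
        if len(hi) < 2:  # degenerate quantile (heavy ties); fall back to a median split
            cut = np.median(x)
            lo, hi = x[x <= cut], x[x > cut]
        if len(hi) < 2:
            lo, hi = x[: len(x) // 2], x[len(x) // 2 :]
        p = len(lo) / len(x)
        mu1, s1 = float(lo.mean()), max(float(lo.std(ddof=0)), _SIGMA_FLOOR)
        mu2, s2 = float(hi.mean()), max(float(hi.std(ddof=0)), _SIGMA_FLOOR)

        trace = [self._loglik(x, p, mu1, s1, mu2, s2, n0, self.p0_)]
        converged = False
        for it in range(self.max_iter):
            # E-step
            d1 = p * self._f1(x, mu1, s1)
            d2 = (1 - p) * self._f2(x, mu2, s2)
            tot = np.maximum(d1 + d2, 1e-300)
            r1 = d1 / tot
            # M-step
            w1 = r1.sum()
            p = float(np.clip(w1 / len(x), _W_FLOOR, 1 - _W_FLOOR))
            if self.truncated:
                mu1, s1 = self._mstep_truncated(x, r1, mu1, s1)
            else:
                mu1 = float((r1 * x).sum() / max(w1, _W_FLOOR))
                s1 = float(np.sqrt((r1 * (x - mu1) ** 2).sum() / max(w1, _W_FLOOR)))
                s1 = max(s1, _SIGMA_FLOOR)
            w2 = len(x) - w1
            mu2 = float(((1 - r1) * x).sum() / max(w2, _W_FLOOR))
            s2 = float(np.sqrt(((1 - r1) * (x - mu2) ** 2).sum() / max(w2, _W_FLOOR)))
            s2 = max(s2, _SIGMA_FLOOR)
            trace.append(self._loglik(x, p, mu1, s1, mu2, s2, n0, self.p0_))
            if abs(trace[-1] - trace[-2]) < self.tol:
                converged = True
                break

        # enforce component 1 = smaller mean (noise)
        if mu1 > mu2:
            mu1, mu2, s1, s2, p = mu2, mu1, s2, s1, 1 - p
        self.weight_ = p
        self.means_ = np.array([mu1, mu2])
        self.sigmas_ = np.array([s1, s2])
        self.loglik_trace_ = np.asarray(trace)
        self.loglik_ = float(trace[-1])
        self.n_iter_ = len(trace) - 1
        self.converged_ = converged
        return self

    def _mstep_truncated(self, x, r1, mu0, s0):
        """Weighted truncated-normal MLE step (generalized EM: never decreases Q)."""
        w = r1
        wsum = max(w.sum(), _W_FLOOR)

        def negq(theta):
            mu, log_s = theta
            s = np.exp(log_s)
            z = (x - mu) / s
            logf = -0.5 * z**2 - log_s - 0.5 * np.log(2 * np.pi)
            logf -= stats.norm.logsf(0.0, mu, s)
            return -(w * logf).sum() / wsum

        x0 = np.array([mu0, np.log(max(s0, _SIGMA_FLOOR))])
        res = optimize.minimize(negq, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        if res.fun <= negq(x0):
            mu, s = float(res.x[0]), float(np.exp(res.x[1]))
        else:  # keep current parameters rather than degrade Q
            mu, s = mu0, s0
        return mu, max(s, _SIGMA_FLOOR)

    def predict_proba(self, values) -> np.ndarray:
        """Posterior probabilities over components (0 = zero atom, 1 = noise, 2 = signal).

        The zero atom carries all posterior mass at x = 0 (the continuous
        densities are measure-zero there); nonzero points split between the
        two continuous components.
        """
        check_is_fitted(self, "means_")
        x = np.asarray(values, dtype=float).ravel()
        out = np.zeros((len(x), 3))
        zero = x == 0.0
        out[zero, 0] = 1.0
        nz = ~zero
        if nz.any():
            d1 = self.weight_ * self._f1(x[nz], self.means_[0], self.sigmas_[0])
            d2 = (1 - self.weight_) * self._f2(x[nz], self.means_[1], self.sigmas_[1])
            tot = np.maximum(d1 + d2, 1e-300)
            out[nz, 1] = d1 / tot
            out[nz, 2] = d2 / tot
        return out
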