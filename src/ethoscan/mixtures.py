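"""Mixture models for per-line noninitiator proportions.

In most lines every male initiates courtship, but in a minority of lines a
modest fraction of males never engages the female at all. The per-line
proportion of such noninitiator males is therefore expected to be bimodal:
a spike at (near) zero plus a second mode at a small positive proportion.
Two candidate distributions are fitted by maximum likelihood and compared
by AIC = 2k - 2 logL:

* an exponential distribution (k = 1; a unimodal decay from zero), and
* a two-component Normal mixture (k = 5; fitted by EM with the components
  ordered so mu1 <= mu2).

The near-degenerate zero component makes the unrestricted Gaussian
likelihood unbounded, so component variances are floored (default 1e-6).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MixtureResults",
    "ExponentialModel",
    "TwoNormalMixture",
    "compare_fits",
]


def _data_hash(data: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(
        np.asarray(data, dtype=float)).tobytes()).hexdigest()


@dataclass
class MixtureResults:
    """Fitted distribution: parameters, likelihood, AIC, convergence."""

    model_name: str
    params: dict
    loglik: float
    k: int
    converged: bool
    n_iter: int
    n_obs: int
    data_hash: str
    trace: list = field(default_factory=list, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    def summary(self) -> str:
        pars = ", ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        return (
            f"{self.model_name}: logL={self.loglik:.3f}  AIC={self.aic:.3f}"
            f"  k={self.k}  n={self.n_obs}  converged={self.converged}"
            f"  ({pars})"
        )


class ExponentialModel:
    """Exponential fit to nonnegative proportion data (closed-form MLE)."""

    def __init__(self, data):
        data = np.asarray(data, dtype=float)
        if data.size < 2:
            raise ValueError("need at least 2 observations")
        if (data < 0).any():
            raise ValueError("exponential model requires nonnegative data")
        self.data = data

    def fit(self) -> MixtureResults:
        mean = self.data.mean()
        if mean <= 0:
            raise ValueError(
                "all observations are zero: exponential rate undefined "
                "(consider a zero-inflation floor)"
            )
        rate = 1.0 / mean
        loglik = float(np.sum(stats.expon.logpdf(self.data, scale=mean)))
        return MixtureResults(
            model_name="exponential",
            params={"rate": float(rate)},
            loglik=loglik,
            k=1,
            converged=True,
            n_iter=0,
            n_obs=self.data.size,
            data_hash=_data_hash(self.data),
        )


class TwoNormalMixture:
    """Two-component Gaussian mixture fitted by EM.

    Initialization splits the data at its median (lower/upper halves seed
    the two components); ``seed`` only matters for the optional k-means
    initialization and for jittering degenerate splits, so fits are
    deterministic given (data, seed). Components are relabeled after
    fitting so that mu1 <= mu2.

    Parameters
    ----------
    var_floor : lower bound on component variances. The zero spike in
        noninitiator data drives one variance toward 0 and the likelihood
        toward infinity without it.
    """

    def __init__(self, data, var_floor: float = 1e-6):
        data = np.asarray(data, dtype=float)
        if data.size < 4:
            raise ValueError("need at least 4 observations")
        self.data = data
        self.var_floor = float(var_floor)

    def _init_params(self, rng: np.random.Generator, init: str):
        x = self.data
        if init == "kmeans":
            c = np.sort(rng.choice(x, 2, replace=False))
            for _ in range(20):
                lab = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
                for j in (0, 1):
                    if (lab == j).any():
                        c[j] = x[lab == j].mean()
            lower, upper = x[lab == 0], x[lab == 1]
        else:  # quantile split
            med = np.median(x)
            lower, upper = x[x <= med], x[x > med]
        if upper.size == 0 or lower.size == 0:  # all-identical data
            lower = x + rng.normal(0, 1e-9, x.size)
            upper = lower
        mu = np.array([lower.mean(), upper.mean()])
        var = np.maximum(
            np.array([lower.var(), upper.var()]), self.var_floor
        )
        pi = np.array([lower.size, max(upper.size, 1)], dtype=float)
        pi /= pi.sum()
        return mu, var, pi

    def fit(
        self,
        seed: int = 0,
        tol: float = 1e-9,
        max_iter: int = 2000,
        init: str = "quantile",
    ) -> MixtureResults:
        x = self.data
        rng = np.random.default_rng(seed)
        mu, var, pi = self._init_params(rng, init)
        prev = -np.inf
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E step
            logp = np.stack([
                np.log(pi[j]) + stats.norm.logpdf(x, mu[j], np.sqrt(var[j]))
                for j in (0, 1)
            ])
            logtot = np.logaddexp(logp[0], logp[1])
            resp = np.exp(logp - logtot)  # (2, n), columns sum to 1
            loglik = float(logtot.sum())
            if loglik < prev - 1e-8:
                raise RuntimeError("EM log-likelihood decreased")
            trace.append(loglik)
            if loglik - prev < tol:
                converged = True
                break
            prev = loglik
            # M step
            nj = resp.sum(axis=1)
            nj = np.maximum(nj, 1e-300)
            mu = resp @ x / nj
            var = np.maximum(
                (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nj,
                self.var_floor,
            )
            pi = nj / x.size
            pi = np.clip(pi, 1e-12, 1 - 1e-12)
        order = np.argsort(mu)
        mu, var, pi = mu[order], var[order], pi[order]
        return MixtureResults(
            model_name="normal2",
            params={
                "mu1": float(mu[0]), "sigma1": float(np.sqrt(var[0])),
                "mu2": float(mu[1]), "sigma2": float(np.sqrt(var[1])),
                "pi2": float(pi[1]),
            },
            loglik=trace[-1],
            k=5,
            converged=converged,
            n_iter=it,
            n_obs=x.size,
            data_hash=_data_hash(x),
            trace=trace,
        )

    def responsibilities(self, result: MixtureResults) -> np.ndarray:
        """Posterior component membership (n, 2) under a fitted result."""
        p = result.params
        mus = np.array([p["mu1"], p["mu2"]])
        sds = np.array([p["sigma1"], p["sigma2"]])
        pis = np.array([1 - p["pi2"], p["pi2"]])
        logp = np.stack([
            np.log(pis[j]) + stats.norm.logpdf(self.data, mus[j], sds[j])
            for j in (0, 1)
        ])
        return np.exp(logp - np.logaddexp(logp[0], logp[1])).T


def compare_fits(fits: list[MixtureResults]) -> list[dict]:
    """Rank fits on the same data by ascending AIC.

    Refuses to compare fits whose underlying data differ. Ties keep input
    order. Each entry reports the model name, AIC, and delta AIC to the
    winner.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ValueError("fits were computed on different data")
    ranked = sorted(fits, key=lambda f: f.aic)
    best = ranked[0].aic
    return [
        {"model": f.model_name, "AIC": f.aic, "logL": f.loglik,
         "delta_AIC": f.aic - best}
        for f in ranked
    ]
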