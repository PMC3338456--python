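"""MCMC convergence and model-comparison diagnostics.

Gelman-Rubin potential scale reduction in the Brooks-Gelman corrected
(BUGS-era) form, a simple autocorrelation-based effective sample size,
and the Deviance Information Criterion from a caller-supplied deviance
function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    ess: dict[str, float]
    threshold: float
    passed: dict[str, bool]

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


@dataclass
class DICReport:
    """Deviance summary: DIC = Dbar + pD, pD = Dbar - D(at posterior mean)."""

    dbar: float
    d_at_mean: float

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


def gelman_rubin(chains: np.ndarray) -> float:
    """Brooks-Gelman corrected potential scale reduction factor.

    ``chains`` has shape (m, n): m >= 2 chains of n >= 10 draws each.
    With B the between-chain and W the within-chain variance,

        Vhat  = (n-1)/n * W + B/n
        Rhat^2 = (m+1)/m * Vhat/W - (n-1)/(m*n)

    which tends to 1 from above for well-mixed chains (up to the
    (n-1)/n small-sample factor for degenerate, identical chains).
    Zero within-chain variance with distinct chains returns +inf.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains as a 2-D (m, n) array")
    m, n = chains.shape
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    means = chains.mean(axis=1)
    W = float(chains.var(axis=1, ddof=1).mean())
    B = n * float(np.var(means, ddof=1))
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    vhat = (n - 1) / n * W + B / n
    r2 = (m + 1) / m * vhat / W - (n - 1) / (m * n)
    return float(np.sqrt(max(r2, 0.0)))


def effective_sample_size(chains: np.ndarray, max_lag: int | None = None) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator.

    Chain-mean-centered autocorrelations are averaged across chains and
    summed until the first non-positive value.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    m, n = chains.shape
    centered = chains - chains.mean(axis=1, keepdims=True)
    denom = float(np.sum(centered**2))
    if denom == 0:
        return float(m * n)
    max_lag = max_lag or min(n - 1, 1000)
    tau = 1.0
    for lag in range(1, max_lag):
        rho = float(np.sum(centered[:, :-lag] * centered[:, lag:])) / denom
        if rho <= 0:
            break
        tau += 2.0 * rho
    return float(m * n / tau)


def convergence_report(
    samples: Mapping[str, np.ndarray], threshold: float = 1.1
) -> ConvergenceReport:
    """Per-parameter R-hat and ESS for a mapping name -> (m, n) draws."""
    rhat, ess, passed = {}, {}, {}
    for name, arr in samples.items():
        rhat[name] = gelman_rubin(arr)
        ess[name] = effective_sample_size(arr)
        passed[name] = rhat[name] < threshold
    return ConvergenceReport(rhat=rhat, ess=ess, threshold=threshold, passed=passed)


def dic(
    draws: list | np.ndarray,
    deviance_fn: Callable,
    mean_state=None,
) -> DICReport:
    """Deviance Information Criterion from posterior draws.

    Parameters
    ----------
    draws : sequence
        Posterior parameter states (any objects ``deviance_fn`` accepts).
    deviance_fn : callable
        Maps one parameter state to its deviance (-2 log likelihood).
    mean_state : optional
        Posterior-mean parameter state for the plug-in deviance. When
        omitted, ``draws`` must be numeric and their mean is used; pass
        an explicit state for structured parameters (SDs should be
        averaged on an unconstrained scale by the caller).
    """
    devs = np.array([float(deviance_fn(d)) for d in draws])
    if not np.all(np.isfinite(devs)):
        bad = np.flatnonzero(~np.isfinite(devs))
        raise ValueError(f"non-finite deviance at draws {bad[:10].tolist()}")
    dbar = float(devs.mean())
    if mean_state is None:
        arr = np.asarray(draws, dtype=float)
        mean_state = arr.mean(axis=0)
    d_at_mean = float(deviance_fn(mean_state))
    return DICReport(dbar=dbar, d_at_mean=d_at_mean)
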