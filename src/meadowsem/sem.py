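"""Hierarchical Bayesian structural equation model.

One seasonal model relates standardized meadow-year observations:

* measurement: CP = Q + e, TP = lam_tp*Q + e, ADF = lam_adf*Q + e,
  with the CP loading fixed to 1 to set the latent forage-quality scale
  (ADF is expected to load negatively: more fiber = lower quality);
* structural: (Q, P) | W bivariate normal with means gamma_wq*W,
  gamma_wp*W and disturbance correlation rho_qp;
  U = beta_qu*Q + beta_pu*P + meadow/allotment/year intercepts + e;
* occupancy: O ~ Bernoulli(expit(alpha + beta_wo*W + beta_uo*U)).

Random intercepts (meadow nested additively within allotment, year
crossed) enter the utilization equation. Inference is by
Metropolis-within-Gibbs: conjugate Gaussian blocks for the latent
quality values, loadings, structural coefficients and intercepts;
random-walk Metropolis on log-SDs, the disturbance correlation and the
occupancy coefficients (steps adapted during burn-in only, then frozen).

Priors are weakly informative on the standardized scale: Normal(0, 10^2)
on coefficients and free loadings, half-Normal(0, 1) on SDs and
Uniform(-1, 1) on the disturbance correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOG2PI = float(np.log(2.0 * np.pi))

STRUCTURAL_NODES = ("W", "Q", "P", "U", "O")
STRUCTURAL_EDGES = (
    ("W", "Q"), ("W", "P"), ("Q", "U"), ("P", "U"), ("W", "O"), ("U", "O"),
)
INDICATORS = ("cp", "tp", "adf")

#: scalar parameters tracked by the sampler, in update order
SCALAR_PARAMS = (
    "lam_tp", "lam_adf",
    "sigma_cp", "sigma_tp", "sigma_adf",
    "gamma_wq", "gamma_wp", "sigma_q", "sigma_p", "rho_qp",
    "beta_qu", "beta_pu", "sigma_u",
    "sigma_meadow", "sigma_allotment", "sigma_year",
    "alpha", "beta_wo", "beta_uo",
)
STRUCTURAL_COEFFS = (
    "gamma_wq", "gamma_wp", "beta_qu", "beta_pu", "beta_wo", "beta_uo", "alpha",
)
SD_PARAMS = tuple(p for p in SCALAR_PARAMS if p.startswith("sigma_"))

COEF_PRIOR_SD = 10.0  # Normal(0, 10^2) on coefficients/loadings
SD_PRIOR_SD = 1.0  # half-Normal(0, 1) on SDs


class SEMStructureError(ValueError):
    """Model specification or data/spec dimension mismatch."""


@dataclass(frozen=True)
class SEMSpec:
    """Graph-level description of one seasonal model."""

    season: str = "mid"
    nodes: tuple[str, ...] = STRUCTURAL_NODES
    edges: tuple[tuple[str, str], ...] = STRUCTURAL_EDGES
    indicators: tuple[str, ...] = INDICATORS
    fixed_loading: str = "cp"
    grouping: tuple[str, ...] = ("meadow", "allotment", "year")

    def __post_init__(self) -> None:
        if self.fixed_loading not in self.indicators:
            raise SEMStructureError("fixed loading must name an indicator")
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise SEMStructureError(f"edge ({a},{b}) uses unknown node")
        if self._has_cycle():
            raise SEMStructureError("structural graph must be acyclic")

    def _has_cycle(self) -> bool:
        out = {n: [] for n in self.nodes}
        for a, b in self.edges:
            out[a].append(b)
        seen, stack = set(), set()

        def visit(n):
            if n in stack:
                return True
            if n in seen:
                return False
            seen.add(n)
            stack.add(n)
            if any(visit(m) for m in out[n]):
                return True
            stack.discard(n)
            return False

        return any(visit(n) for n in self.nodes)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SEMSpec":
        kwargs = dict(d)
        if "edges" in kwargs:
            kwargs["edges"] = tuple(tuple(e) for e in kwargs["edges"])
        for key in ("nodes", "indicators", "grouping"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SEMSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ScalingRecord:
    """Column means/SDs captured by :func:`standardize`; supports exact inverse."""

    means: dict[str, float]
    sds: dict[str, float]


def standardize(
    df: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center and scale columns to mean 0, SD 1 (ddof=1).

    Raises on zero-variance columns, naming the offender.
    """
    out = df.copy()
    if columns is None:
        columns = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    means, sds = {}, {}
    for col in columns:
        x = df[col].to_numpy(dtype=float)
        sd = float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance column: {col!r}")
        mu = float(x.mean())
        out[col] = (x - mu) / sd
        means[col], sds[col] = mu, sd
    return out, ScalingRecord(means=means, sds=sds)


def destandardize(df: pd.DataFrame, record: ScalingRecord) -> pd.DataFrame:
    """Exact inverse of :func:`standardize`."""
    out = df.copy()
    for col, mu in record.means.items():
        out[col] = df[col].to_numpy(dtype=float) * record.sds[col] + mu
    return out


@dataclass
class SEMData:
    """Prepared (standardized) meadow-year data for one seasonal fit."""

    W: np.ndarray
    CP: np.ndarray
    TP: np.ndarray
    ADF: np.ndarray
    P: np.ndarray
    U: np.ndarray
    O: np.ndarray
    meadow_idx: np.ndarray
    allot_idx: np.ndarray
    year_idx: np.ndarray
    n_meadow: int
    n_allot: int
    n_year: int
    scaling: ScalingRecord | None = None

    @property
    def n(self) -> int:
        return len(self.W)

    def drop_unit(self, i: int) -> "SEMData":
        """Return a copy without row i (group level sets preserved)."""
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return SEMData(
            W=self.W[keep], CP=self.CP[keep], TP=self.TP[keep],
            ADF=self.ADF[keep], P=self.P[keep], U=self.U[keep], O=self.O[keep],
            meadow_idx=self.meadow_idx[keep], allot_idx=self.allot_idx[keep],
            year_idx=self.year_idx[keep], n_meadow=self.n_meadow,
            n_allot=self.n_allot, n_year=self.n_year, scaling=self.scaling,
        )


def prepare_sem_data(
    meadow_years: pd.DataFrame,
    season: str,
    years: Sequence[int] | None = None,
) -> SEMData:
    """Extract and standardize one season's meadow-year table.

    Continuous variables (wetness score, CP, TP, ADF, biomass,
    utilization) are standardized; occupancy stays binary. Rows with
    missing indicator values are dropped.
    """
    df = meadow_years.copy()
    if years is not None:
        df = df[df["year"].isin(list(years))]
    cols = {
        "W": "mean_score",
        "CP": f"cp_{season}",
        "TP": f"tp_{season}",
        "ADF": f"adf_{season}",
        "P": f"biomass_{season}",
        "U": f"utilization_{season}",
    }
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SEMStructureError(f"meadow-year table missing columns: {missing}")
    sub = df[["meadow", "allotment", "year", "occupancy"] + list(cols.values())]
    n_before = len(sub)
    sub = sub.dropna()
    if len(sub) < n_before:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d rows with missing values", n_before - len(sub)
        )
    work = pd.DataFrame({k: sub[v].to_numpy(dtype=float) for k, v in cols.items()})
    std, scaling = standardize(work)

    meadow_codes = pd.Categorical(sub["meadow"]).codes
    allot_codes = pd.Categorical(sub["allotment"]).codes
    year_codes = pd.Categorical(sub["year"]).codes
    return SEMData(
        W=std["W"].to_numpy(),
        CP=std["CP"].to_numpy(),
        TP=std["TP"].to_numpy(),
        ADF=std["ADF"].to_numpy(),
        P=std["P"].to_numpy(),
        U=std["U"].to_numpy(),
        O=sub["occupancy"].to_numpy(dtype=int),
        meadow_idx=np.asarray(meadow_codes, dtype=int),
        allot_idx=np.asarray(allot_codes, dtype=int),
        year_idx=np.asarray(year_codes, dtype=int),
        n_meadow=int(meadow_codes.max()) + 1,
        n_allot=int(allot_codes.max()) + 1,
        n_year=int(year_codes.max()) + 1,
        scaling=scaling,
    )


@dataclass
class SEMParams:
    """One full parameter state, including latents and random intercepts."""

    lam_cp: float = 1.0  # fixed by the sampler; free only for symmetry tests
    lam_tp: float = 0.9
    lam_adf: float = -0.8
    sigma_cp: float = 0.5
    sigma_tp: float = 0.5
    sigma_adf: float = 0.5
    gamma_wq: float = 0.0
    gamma_wp: float = 0.0
    sigma_q: float = 0.5
    sigma_p: float = 0.5
    rho_qp: float = 0.0
    beta_qu: float = 0.0
    beta_pu: float = 0.0
    sigma_u: float = 0.5
    sigma_meadow: float = 0.3
    sigma_allotment: float = 0.3
    sigma_year: float = 0.3
    alpha: float = 0.0
    beta_wo: float = 0.0
    beta_uo: float = 0.0
    Q: np.ndarray = field(default_factory=lambda: np.zeros(0))
    u_meadow: np.ndarray = field(default_factory=lambda: np.zeros(0))
    u_allotment: np.ndarray = field(default_factory=lambda: np.zeros(0))
    u_year: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def validate(self) -> None:
        for name in SD_PARAMS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not abs(self.rho_qp) < 1:
            raise ValueError("|rho_qp| must be < 1")


def _check_dims(params: SEMParams, data: SEMData) -> None:
    if len(params.Q) != data.n:
        raise SEMStructureError("Q length must match data rows")
    if len(params.u_meadow) != data.n_meadow:
        raise SEMStructureError("u_meadow length must match meadow count")
    if len(params.u_allotment) != data.n_allot:
        raise SEMStructureError("u_allotment length must match allotment count")
    if len(params.u_year) != data.n_year:
        raise SEMStructureError("u_year length must match year count")


def log_likelihood(params: SEMParams, data: SEMData) -> float:
    """Observed-data log likelihood conditional on latents and intercepts.

    Built from scipy.stats densities; serves as the independent check on
    the sampler's internally cached log density.
    """
    params.validate()
    _check_dims(params, data)
    p = params
    ll = 0.0
    ll += stats.norm.logpdf(data.CP, p.lam_cp * p.Q, p.sigma_cp).sum()
    ll += stats.norm.logpdf(data.TP, p.lam_tp * p.Q, p.sigma_tp).sum()
    ll += stats.norm.logpdf(data.ADF, p.lam_adf * p.Q, p.sigma_adf).sum()
    cov = np.array(
        [
            [p.sigma_q**2, p.rho_qp * p.sigma_q * p.sigma_p],
            [p.rho_qp * p.sigma_q * p.sigma_p, p.sigma_p**2],
        ]
    )
    resid = np.column_stack(
        [p.Q - p.gamma_wq * data.W, data.P - p.gamma_wp * data.W]
    )
    ll += stats.multivariate_normal.logpdf(resid, mean=[0.0, 0.0], cov=cov).sum()
    re = (
        p.u_meadow[data.meadow_idx]
        + p.u_allotment[data.allot_idx]
        + p.u_year[data.year_idx]
    )
    mu_u = p.beta_qu * p.Q + p.beta_pu * data.P + re
    ll += stats.norm.logpdf(data.U, mu_u, p.sigma_u).sum()
    eta = p.alpha + p.beta_wo * data.W + p.beta_uo * data.U
    ll += float(np.sum(data.O * eta - np.logaddexp(0.0, eta)))
    return float(ll)


def log_posterior(spec: SEMSpec, params: SEMParams, data: SEMData) -> float:
    """Log prior + log likelihood (finite for any valid state)."""
    p = params
    lp = log_likelihood(params, data)
    lp += stats.norm.logpdf(p.u_meadow, 0.0, p.sigma_meadow).sum()
    lp += stats.norm.logpdf(p.u_allotment, 0.0, p.sigma_allotment).sum()
    lp += stats.norm.logpdf(p.u_year, 0.0, p.sigma_year).sum()
    coefs = [p.lam_tp, p.lam_adf, p.gamma_wq, p.gamma_wp,
             p.beta_qu, p.beta_pu, p.alpha, p.beta_wo, p.beta_uo]
    lp += stats.norm.logpdf(np.array(coefs), 0.0, COEF_PRIOR_SD).sum()
    sds = np.array([getattr(p, name) for name in SD_PARAMS])
    lp += stats.halfnorm.logpdf(sds, scale=SD_PRIOR_SD).sum()
    lp += stats.uniform.logpdf(p.rho_qp, loc=-1.0, scale=2.0)
    return float(lp)


def conditional_deviance(params: SEMParams, data: SEMData) -> float:
    """-2 x log likelihood of the observed nodes given the parameter state.

    The productivity term enters through its conditional given the
    latent quality value, so the latent is treated as a parameter (the
    plug-in convention used for DIC).
    """
    p = params
    ll = 0.0
    for obs, lam, sd in (
        (data.CP, p.lam_cp, p.sigma_cp),
        (data.TP, p.lam_tp, p.sigma_tp),
        (data.ADF, p.lam_adf, p.sigma_adf),
    ):
        r = obs - lam * p.Q
        ll += -0.5 * np.sum(r**2) / sd**2 - data.n * (np.log(sd) + 0.5 * LOG2PI)
    # P | Q: conditional of the bivariate disturbance
    mu_p = p.gamma_wp * data.W + p.rho_qp * (p.sigma_p / p.sigma_q) * (
        p.Q - p.gamma_wq * data.W
    )
    sd_p = p.sigma_p * np.sqrt(1.0 - p.rho_qp**2)
    r = data.P - mu_p
    ll += -0.5 * np.sum(r**2) / sd_p**2 - data.n * (np.log(sd_p) + 0.5 * LOG2PI)
    re = (
        p.u_meadow[data.meadow_idx]
        + p.u_allotment[data.allot_idx]
        + p.u_year[data.year_idx]
    )
    r = data.U - (p.beta_qu * p.Q + p.beta_pu * data.P + re)
    ll += -0.5 * np.sum(r**2) / p.sigma_u**2 - data.n * (
        np.log(p.sigma_u) + 0.5 * LOG2PI
    )
    eta = p.alpha + p.beta_wo * data.W + p.beta_uo * data.U
    ll += float(np.sum(data.O * eta - np.logaddexp(0.0, eta)))
    return float(-2.0 * ll)


@dataclass
class PosteriorSamples:
    """Per-chain MCMC draws with iteration metadata."""

    params: dict[str, np.ndarray]  # name -> (n_chains, n_iter)
    latents: dict[str, np.ndarray]  # name -> (n_chains, n_iter, dim)
    lp: np.ndarray  # (n_chains, n_iter) cached log posterior
    burn_in: int
    thin: int
    seed: int
    accept_rates: dict[str, float]
    rhat_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_iter(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def post_burn(self, name: str) -> np.ndarray:
        """Post-burn-in draws for one parameter, shape (n_chains, kept)."""
        if name in self.params:
            return self.params[name][:, self.burn_in:]
        raise KeyError(name)

    def flat(self, name: str) -> np.ndarray:
        return self.post_burn(name).reshape(-1)

    def posterior_mean_state(self, data: SEMData) -> SEMParams:
        """Posterior-mean SEMParams (SDs averaged on the log scale)."""
        kw = {}
        for name in SCALAR_PARAMS:
            draws = self.flat(name)
            if name in SD_PARAMS:
                kw[name] = float(np.exp(np.mean(np.log(draws))))
            else:
                kw[name] = float(np.mean(draws))
        state = SEMParams(**kw)
        state.Q = self.latents["Q"][:, self.burn_in:, :].mean(axis=(0, 1))
        state.u_meadow = self.latents["u_meadow"][:, self.burn_in:, :].mean(axis=(0, 1))
        state.u_allotment = self.latents["u_allotment"][:, self.burn_in:, :].mean(
            axis=(0, 1)
        )
        state.u_year = self.latents["u_year"][:, self.burn_in:, :].mean(axis=(0, 1))
        return state

    def to_frame(self) -> pd.DataFrame:
        """One row per chain-iteration, scalar parameters as columns."""
        n_c, n_i = self.n_chains, self.n_iter
        out = {
            "chain": np.repeat(np.arange(n_c), n_i),
            "iteration": np.tile(np.arange(n_i), n_c),
        }
        for name, arr in self.params.items():
            out[name] = arr.reshape(-1)
        out["lp"] = self.lp.reshape(-1)
        return pd.DataFrame(out)


def _internal_log_posterior(st: dict, data: SEMData, suff: dict) -> float:
    """Hand-coded full log posterior used for the per-iteration cache."""
    n = data.n
    lp = 0.0
    for key, sd_name in (("cp", "sigma_cp"), ("tp", "sigma_tp"), ("adf", "sigma_adf")):
        sd = st[sd_name]
        lp += -0.5 * suff[f"ssr_{key}"] / sd**2 - n * (np.log(sd) + 0.5 * LOG2PI)
    sq, sp, rho = st["sigma_q"], st["sigma_p"], st["rho_qp"]
    omr = 1.0 - rho**2
    quad = (
        suff["sqq"] / sq**2
        - 2.0 * rho * suff["sqp"] / (sq * sp)
        + suff["spp"] / sp**2
    )
    lp += (
        -n * (np.log(sq) + np.log(sp))
        - 0.5 * n * np.log(omr)
        - 0.5 * quad / omr
        - n * LOG2PI
    )
    su = st["sigma_u"]
    lp += -0.5 * suff["ssr_u"] / su**2 - n * (np.log(su) + 0.5 * LOG2PI)
    eta = st["alpha"] + st["beta_wo"] * data.W + st["beta_uo"] * data.U
    lp += float(np.sum(data.O * eta - np.logaddexp(0.0, eta)))
    for vec, sd in (
        (st["u_meadow"], st["sigma_meadow"]),
        (st["u_allotment"], st["sigma_allotment"]),
        (st["u_year"], st["sigma_year"]),
    ):
        lp += -0.5 * float(np.sum(vec**2)) / sd**2 - len(vec) * (
            np.log(sd) + 0.5 * LOG2PI
        )
    coefs = np.array(
        [st[k] for k in ("lam_tp", "lam_adf", "gamma_wq", "gamma_wp",
                          "beta_qu", "beta_pu", "alpha", "beta_wo", "beta_uo")]
    )
    lp += float(
        np.sum(-0.5 * coefs**2 / COEF_PRIOR_SD**2)
        - 9 * (np.log(COEF_PRIOR_SD) + 0.5 * LOG2PI)
    )
    sds = np.array([st[k] for k in SD_PARAMS])
    lp += float(
        np.sum(-0.5 * sds**2 / SD_PRIOR_SD**2)
        + len(sds) * (0.5 * np.log(2.0 / np.pi) - np.log(SD_PRIOR_SD))
    )
    lp += -np.log(2.0)  # uniform(-1,1) on rho
    return float(lp)


def _init_state(data: SEMData, rng: np.random.Generator, scale: float) -> dict:
    """Overdispersed chain start; scale grows with the chain index."""
    st = {}
    for name in SCALAR_PARAMS:
        if name in SD_PARAMS:
            st[name] = 0.3 + abs(rng.normal(0.0, 0.4)) * scale
        elif name == "rho_qp":
            st[name] = float(np.clip(rng.normal(0.0, 0.3) * scale, -0.9, 0.9))
        else:
            st[name] = float(rng.normal(0.0, 0.7) * scale)
    st["u_meadow"] = rng.normal(0.0, 0.1, data.n_meadow)
    st["u_allotment"] = rng.normal(0.0, 0.1, data.n_allot)
    st["u_year"] = rng.normal(0.0, 0.1, data.n_year)
    st["Q"] = data.CP + rng.normal(0.0, 0.2 * scale, data.n)
    return st


def _run_chain(
    data: SEMData,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    init_scale: float,
    out: dict[str, np.ndarray],
    latents_out: dict[str, np.ndarray],
    lp_out: np.ndarray,
    use_uo: bool = True,
) -> dict[str, float]:
    """One MCMC chain; writes draws into preallocated row views."""
    st = _init_state(data, rng, init_scale)
    if not use_uo:
        st["beta_uo"] = 0.0
    n = data.n
    W, CP, TP, ADF, P, U, O = (
        data.W, data.CP, data.TP, data.ADF, data.P, data.U, data.O,
    )
    m_idx, a_idx, t_idx = data.meadow_idx, data.allot_idx, data.year_idx
    sumW2 = float(np.sum(W**2))
    n_meadow, n_allot, n_year = data.n_meadow, data.n_allot, data.n_year
    cnt_m = np.bincount(m_idx, minlength=n_meadow).astype(float)
    cnt_a = np.bincount(a_idx, minlength=n_allot).astype(float)
    cnt_t = np.bincount(t_idx, minlength=n_year).astype(float)
    prior_prec = 1.0 / COEF_PRIOR_SD**2

    mh_names = list(SD_PARAMS) + ["rho_qp", "occupancy", "qscale"]
    steps = {name: 0.25 for name in mh_names}
    steps["occupancy"] = 0.4
    steps["qscale"] = 0.5
    acc = {name: 0 for name in mh_names}
    acc_window = {name: 0 for name in mh_names}
    tries = {name: 0 for name in mh_names}

    def sd_logtarget(sd: float, ssr: float, count: float) -> float:
        # likelihood + half-normal prior + log-Jacobian for log-scale walk
        return (
            -count * np.log(sd)
            - 0.5 * ssr / sd**2
            - 0.5 * sd**2 / SD_PRIOR_SD**2
            + np.log(sd)
        )

    def mh_sd(name: str, ssr: float, count: float) -> None:
        sd = st[name]
        prop = sd * np.exp(steps[name] * rng.standard_normal())
        if np.log(rng.random()) < sd_logtarget(prop, ssr, count) - sd_logtarget(
            sd, ssr, count
        ):
            st[name] = prop
            acc[name] += 1
            acc_window[name] += 1
        tries[name] += 1

    for it in range(n_iter):
        re_u = st["u_meadow"][m_idx] + st["u_allotment"][a_idx] + st["u_year"][t_idx]

        # --- latent quality: conjugate Gaussian, vectorized over units
        omr = 1.0 - st["rho_qp"] ** 2
        var_qcond = st["sigma_q"] ** 2 * omr
        mu_qcond = st["gamma_wq"] * W + st["rho_qp"] * (
            st["sigma_q"] / st["sigma_p"]
        ) * (P - st["gamma_wp"] * W)
        prec = (
            1.0 / st["sigma_cp"] ** 2
            + st["lam_tp"] ** 2 / st["sigma_tp"] ** 2
            + st["lam_adf"] ** 2 / st["sigma_adf"] ** 2
            + 1.0 / var_qcond
            + st["beta_qu"] ** 2 / st["sigma_u"] ** 2
        )
        mp = (
            CP / st["sigma_cp"] ** 2
            + st["lam_tp"] * TP / st["sigma_tp"] ** 2
            + st["lam_adf"] * ADF / st["sigma_adf"] ** 2
            + mu_qcond / var_qcond
            + st["beta_qu"] * (U - st["beta_pu"] * P - re_u) / st["sigma_u"] ** 2
        )
        st["Q"] = mp / prec + rng.standard_normal(n) / np.sqrt(prec)

        # --- latent-scale group move: Q -> c*Q with loadings, quality
        # paths and disturbance SD rescaled to match. The fixed CP
        # loading makes the move non-neutral, so it can carry a chain
        # out of the collapsed-scale (or sign-flipped) local mode that
        # plain componentwise updates cannot escape.
        Q = st["Q"]
        c = float(np.exp(steps["qscale"] * rng.standard_normal()))
        if rng.random() < 0.1:
            c = -c
        sumQ2 = float(np.sum(Q**2))
        qcp = float(Q @ CP)

        def qscale_logtarget(cc):
            # CP-likelihood, sigma_q normalization, and priors that move;
            # a negative cc also flips rho so the bivariate cross term
            # stays invariant (uniform prior is symmetric)
            ll = -(0.5 / st["sigma_cp"] ** 2) * (
                cc**2 * sumQ2 - 2.0 * cc * qcp
            )
            ll += -n * np.log(abs(cc) * st["sigma_q"])
            ll += -0.5 * (
                (st["lam_tp"] / cc) ** 2 + (st["lam_adf"] / cc) ** 2
                + (cc * st["gamma_wq"]) ** 2 + (st["beta_qu"] / cc) ** 2
            ) / COEF_PRIOR_SD**2
            ll += -0.5 * (cc * st["sigma_q"]) ** 2 / SD_PRIOR_SD**2
            return ll

        delta = (
            qscale_logtarget(c)
            - qscale_logtarget(1.0)
            + (n - 1) * np.log(abs(c))
        )
        tries["qscale"] += 1
        if np.log(rng.random()) < delta:
            st["Q"] = Q = c * Q
            st["lam_tp"] /= c
            st["lam_adf"] /= c
            st["sigma_q"] *= abs(c)
            st["gamma_wq"] *= c
            st["beta_qu"] /= c
            if c < 0:
                st["rho_qp"] = -st["rho_qp"]
            acc["qscale"] += 1
            acc_window["qscale"] += 1
        sumQ2 = float(np.sum(Q**2))

        # --- free loadings: conjugate
        for name, obs, sd_name in (
            ("lam_tp", TP, "sigma_tp"),
            ("lam_adf", ADF, "sigma_adf"),
        ):
            s2 = st[sd_name] ** 2
            pr = sumQ2 / s2 + prior_prec
            mu = float(Q @ obs) / s2 / pr
            st[name] = mu + rng.standard_normal() / np.sqrt(pr)

        # --- indicator SDs: random-walk on log sigma
        ssr_cp = float(np.sum((CP - Q) ** 2))
        ssr_tp = float(np.sum((TP - st["lam_tp"] * Q) ** 2))
        ssr_adf = float(np.sum((ADF - st["lam_adf"] * Q) ** 2))
        mh_sd("sigma_cp", ssr_cp, n)
        mh_sd("sigma_tp", ssr_tp, n)
        mh_sd("sigma_adf", ssr_adf, n)

        # --- wetness paths: conjugate under the bivariate disturbance
        sq, sp, rho = st["sigma_q"], st["sigma_p"], st["rho_qp"]
        omr = 1.0 - rho**2
        i11 = 1.0 / (sq**2 * omr)
        i22 = 1.0 / (sp**2 * omr)
        i12 = -rho / (sq * sp * omr)
        r_p = P - st["gamma_wp"] * W
        pr = i11 * sumW2 + prior_prec
        mu = float(np.sum(W * (i11 * Q + i12 * r_p))) / pr
        st["gamma_wq"] = mu + rng.standard_normal() / np.sqrt(pr)
        r_q = Q - st["gamma_wq"] * W
        pr = i22 * sumW2 + prior_prec
        mu = float(np.sum(W * (i22 * P + i12 * r_q))) / pr
        st["gamma_wp"] = mu + rng.standard_normal() / np.sqrt(pr)

        # --- disturbance scale/correlation: MH on the bivariate block
        r_q = Q - st["gamma_wq"] * W
        r_p = P - st["gamma_wp"] * W
        sqq = float(np.sum(r_q**2))
        spp = float(np.sum(r_p**2))
        sqp = float(np.sum(r_q * r_p))

        def biv_logtarget(sq_, sp_, rho_):
            omr_ = 1.0 - rho_**2
            quad = sqq / sq_**2 - 2 * rho_ * sqp / (sq_ * sp_) + spp / sp_**2
            return (
                -n * (np.log(sq_) + np.log(sp_))
                - 0.5 * n * np.log(omr_)
                - 0.5 * quad / omr_
                - 0.5 * (sq_**2 + sp_**2) / SD_PRIOR_SD**2
            )

        for name in ("sigma_q", "sigma_p"):
            cur = st[name]
            prop = cur * np.exp(steps[name] * rng.standard_normal())
            args_cur = (st["sigma_q"], st["sigma_p"], st["rho_qp"])
            st[name] = prop
            args_prop = (st["sigma_q"], st["sigma_p"], st["rho_qp"])
            st[name] = cur
            delta = (
                biv_logtarget(*args_prop)
                + np.log(prop)
                - biv_logtarget(*args_cur)
                - np.log(cur)
            )
            if np.log(rng.random()) < delta:
                st[name] = prop
                acc[name] += 1
                acc_window[name] += 1
            tries[name] += 1
        cur = st["rho_qp"]
        prop = cur + steps["rho_qp"] * rng.standard_normal()
        tries["rho_qp"] += 1
        if abs(prop) < 1.0:
            delta = biv_logtarget(st["sigma_q"], st["sigma_p"], prop) - biv_logtarget(
                st["sigma_q"], st["sigma_p"], cur
            )
            if np.log(rng.random()) < delta:
                st["rho_qp"] = prop
                acc["rho_qp"] += 1
                acc_window["rho_qp"] += 1

        # --- utilization coefficients: joint 2D conjugate
        su2 = st["sigma_u"] ** 2
        target = U - re_u
        xtx = np.array(
            [
                [sumQ2, float(Q @ P)],
                [float(Q @ P), float(np.sum(P**2))],
            ]
        ) / su2
        xtx[0, 0] += prior_prec
        xtx[1, 1] += prior_prec
        xty = np.array([float(Q @ target), float(P @ target)]) / su2
        L = np.linalg.cholesky(xtx)
        mean = np.linalg.solve(xtx, xty)
        z = rng.standard_normal(2)
        draw = mean + np.linalg.solve(L.T, z)
        st["beta_qu"], st["beta_pu"] = float(draw[0]), float(draw[1])

        # --- random intercepts: conjugate per group
        fixed = st["beta_qu"] * Q + st["beta_pu"] * P
        for key, idx, cnt, size, sd_name, others in (
            ("u_meadow", m_idx, cnt_m, n_meadow, "sigma_meadow",
             lambda: st["u_allotment"][a_idx] + st["u_year"][t_idx]),
            ("u_allotment", a_idx, cnt_a, n_allot, "sigma_allotment",
             lambda: st["u_meadow"][m_idx] + st["u_year"][t_idx]),
            ("u_year", t_idx, cnt_t, n_year, "sigma_year",
             lambda: st["u_meadow"][m_idx] + st["u_allotment"][a_idx]),
        ):
            resid = U - fixed - others()
            s = np.bincount(idx, weights=resid, minlength=size)
            pr = cnt / su2 + 1.0 / st[sd_name] ** 2
            mu = (s / su2) / pr
            st[key] = mu + rng.standard_normal(size) / np.sqrt(pr)

        # --- residual and random-effect SDs
        re_u = st["u_meadow"][m_idx] + st["u_allotment"][a_idx] + st["u_year"][t_idx]
        ssr_u = float(np.sum((U - fixed - re_u) ** 2))
        mh_sd("sigma_u", ssr_u, n)
        mh_sd("sigma_meadow", float(np.sum(st["u_meadow"] ** 2)), n_meadow)
        mh_sd("sigma_allotment", float(np.sum(st["u_allotment"] ** 2)), n_allot)
        mh_sd("sigma_year", float(np.sum(st["u_year"] ** 2)), n_year)

        # --- occupancy block: joint random-walk MH (beta_uo frozen at 0
        # when the spec omits the utilization -> occupancy edge)
        dim = 3 if use_uo else 2
        theta = np.array([st["alpha"], st["beta_wo"], st["beta_uo"]])[:dim]

        def occ_logtarget(th):
            eta = th[0] + th[1] * W + (th[2] * U if dim == 3 else 0.0)
            return float(
                np.sum(O * eta - np.logaddexp(0.0, eta))
                - 0.5 * float(th @ th) * prior_prec
            )

        prop = theta + steps["occupancy"] * rng.standard_normal(dim)
        tries["occupancy"] += 1
        if np.log(rng.random()) < occ_logtarget(prop) - occ_logtarget(theta):
            st["alpha"], st["beta_wo"] = float(prop[0]), float(prop[1])
            if dim == 3:
                st["beta_uo"] = float(prop[2])
            acc["occupancy"] += 1
            acc_window["occupancy"] += 1

        # --- step adaptation, burn-in only (frozen afterwards)
        if it < burn_in and (it + 1) % 50 == 0:
            for name in mh_names:
                rate = acc_window[name] / 50.0
                target_rate = 0.3 if name == "occupancy" else 0.44
                steps[name] *= float(np.exp(0.6 * (rate - target_rate)))
                steps[name] = float(np.clip(steps[name], 1e-3, 5.0))
                acc_window[name] = 0

        # --- cache draws and log posterior
        for name in SCALAR_PARAMS:
            out[name][it] = st[name]
        latents_out["Q"][it] = st["Q"]
        latents_out["u_meadow"][it] = st["u_meadow"]
        latents_out["u_allotment"][it] = st["u_allotment"]
        latents_out["u_year"][it] = st["u_year"]
        # sufficient statistics above are all current for this state:
        # loadings/paths/coefficients were updated before their SSRs,
        # and later blocks (SDs, occupancy) do not move the residuals
        suff = {
            "ssr_cp": ssr_cp, "ssr_tp": ssr_tp, "ssr_adf": ssr_adf,
            "sqq": sqq, "spp": spp, "sqp": sqp, "ssr_u": ssr_u,
        }
        lp_out[it] = _internal_log_posterior(st, data, suff)

    return {name: acc[name] / max(tries[name], 1) for name in mh_names}


def sample_posterior(
    spec: SEMSpec,
    data: SEMData,
    n_chains: int = 3,
    n_iter: int = 6000,
    burn_in: int = 2000,
    seed: int = 0,
    rhat_threshold: float = 1.1,
) -> PosteriorSamples:
    """Fit the seasonal SEM by Metropolis-within-Gibbs.

    Chains start overdispersed (init scale grows with chain index);
    identical seeds give identical draws. Non-convergence (any
    structural-coefficient R-hat above ``rhat_threshold``) is flagged on
    the result, never raised — draws are always returned.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    if data.n < 3:
        raise ValueError("need at least 3 units")

    out = {name: np.empty((n_chains, n_iter)) for name in SCALAR_PARAMS}
    latents = {
        "Q": np.empty((n_chains, n_iter, data.n)),
        "u_meadow": np.empty((n_chains, n_iter, data.n_meadow)),
        "u_allotment": np.empty((n_chains, n_iter, data.n_allot)),
        "u_year": np.empty((n_chains, n_iter, data.n_year)),
    }
    lp = np.empty((n_chains, n_iter))
    accept: dict[str, float] = {}
    use_uo = ("U", "O") in {tuple(e) for e in spec.edges}
    child_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(child_seeds[c])
        rates = _run_chain(
            data, n_iter, burn_in, rng, 1.0 + c / 2.0,
            {k: v[c] for k, v in out.items()},
            {k: v[c] for k, v in latents.items()},
            lp[c],
            use_uo=use_uo,
        )
        for k, v in rates.items():
            accept[f"chain{c}:{k}"] = v

    samples = PosteriorSamples(
        params=out, latents=latents, lp=lp, burn_in=burn_in, thin=1,
        seed=seed, accept_rates=accept,
    )
    from .diagnostics import gelman_rubin

    flags = {}
    for name in STRUCTURAL_COEFFS:
        rhat = gelman_rubin(samples.post_burn(name))
        flags[name] = bool(rhat < rhat_threshold)
    samples.rhat_flags = flags
    return samples


def significance_flags(
    samples: PosteriorSamples, names: Sequence[str] | None = None
) -> dict[str, str]:
    """Flag each coefficient: ``**`` if the equal-tailed 95% credible
    interval excludes zero, ``*`` if only the 90% interval does, ``NS``
    otherwise."""
    names = list(names) if names is not None else list(STRUCTURAL_COEFFS)
    flags = {}
    for name in names:
        draws = samples.flat(name) if isinstance(samples, PosteriorSamples) else samples[name]
        lo95, hi95 = np.quantile(draws, [0.025, 0.975])
        lo90, hi90 = np.quantile(draws, [0.05, 0.95])
        if lo95 > 0 or hi95 < 0:
            flags[name] = "**"
        elif lo90 > 0 or hi90 < 0:
            flags[name] = "*"
        else:
            flags[name] = "NS"
    return flags
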