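"""Seeded synthetic survey-data generator.

Emulates the field study's sampling design — grazing allotments holding
meadows, five monitoring sites per meadow, three grazing seasons per
year — and a linear-Gaussian causal structure on a standardized scale:

* site wetness ranks come from a discretized normal per meadow;
* latent forage quality Q and observed productivity P respond to
  wetness with correlated disturbances;
* quality indicators CP/TP/ADF load on Q (one loading fixed to 1,
  ADF loading negative: more fiber = lower quality);
* herbaceous utilization U responds to quality and productivity;
* meadow-year occupancy is Bernoulli on a logit of wetness and mean
  utilization (the utilization path is zero by default).

All continuous variables are generated on the standardized scale and
affinely mapped to realistic field units, so the true parameters remain
interpretable as standardized path coefficients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .wetness import composite_meadow_rank

SEASONS = ("early", "mid", "late")

#: affine maps from the standardized scale to field units: (center, scale)
UNIT_MAPS = {
    "cp": (14.0, 3.2),  # crude protein, % dry matter (approx 6-22)
    "tp": (0.185, 0.045),  # total phosphorus, % dry matter (approx 0.07-0.30)
    "adf": (27.0, 4.8),  # acid detergent fiber, % dry matter (approx 15-39)
    "biomass": (2100.0, 440.0),  # peak biomass, kg/ha (approx 1000-3200)
    "utilization": (0.265, 0.09),  # herbaceous use, fraction (approx 0.04-0.49)
    "fecal": (60.0, 25.0),  # fecal pats per unit area
}


class ConfigurationError(ValueError):
    """Invalid study-design configuration."""


class ParameterError(ValueError):
    """Invalid generating-parameter values."""


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout: allotments > meadows > monitoring sites, by year/season."""

    n_allotments: int = 3
    meadows_per_allotment: tuple[int, ...] = (8, 8, 8)
    sites_per_meadow: int = 5
    years: tuple[int, ...] = (2006, 2007, 2008)
    seasons: tuple[str, ...] = SEASONS

    def __post_init__(self) -> None:
        if self.n_allotments < 1 or self.sites_per_meadow < 1:
            raise ConfigurationError("counts must be >= 1")
        if len(self.meadows_per_allotment) != self.n_allotments:
            raise ConfigurationError(
                "meadows_per_allotment length must equal n_allotments"
            )
        if any(m < 1 for m in self.meadows_per_allotment):
            raise ConfigurationError("meadow counts must be >= 1")
        if len(self.years) < 1:
            raise ConfigurationError("need at least one year")
        if tuple(self.seasons) != SEASONS:
            raise ConfigurationError(f"seasons must be exactly {SEASONS}")

    @property
    def n_meadows(self) -> int:
        return int(sum(self.meadows_per_allotment))

    @property
    def n_sites(self) -> int:
        return self.n_meadows * self.sites_per_meadow


def make_design(config: Mapping | None = None) -> StudyDesign:
    """Build a :class:`StudyDesign` from a plain mapping (e.g. parsed YAML).

    Unknown keys are rejected. With no config, returns the default
    3-allotment / 24-meadow / 120-site layout.
    """
    config = dict(config or {})
    known = {f.name for f in dataclasses.fields(StudyDesign)}
    unknown = set(config) - known
    if unknown:
        raise ConfigurationError(f"unknown design keys: {sorted(unknown)}")
    for key in ("meadows_per_allotment", "years", "seasons"):
        if key in config:
            config[key] = tuple(config[key])
    return StudyDesign(**config)


def _as_season_map(value, name: str) -> dict[str, float]:
    """Allow a coefficient to be a scalar or a per-season mapping."""
    if isinstance(value, Mapping):
        extra = set(value) - set(SEASONS)
        if extra:
            raise ParameterError(f"{name}: unknown seasons {sorted(extra)}")
        return {s: float(value.get(s, 0.0)) for s in SEASONS}
    return {s: float(value) for s in SEASONS}


@dataclass(frozen=True)
class TrueParams:
    """Generating parameters on the standardized scale.

    Path coefficients follow the causal graph wetness -> {quality,
    productivity} -> utilization, wetness/utilization -> occupancy.
    ``beta_qu``/``beta_pu`` may be scalars or per-season mappings.
    """

    gamma_wq: float = -0.6  # wetness -> latent quality
    gamma_wp: float = -0.5  # wetness -> productivity
    beta_qu: float | Mapping[str, float] = 0.45  # quality -> utilization
    beta_pu: float | Mapping[str, float] = 0.5  # productivity -> utilization
    alpha: float = 0.0  # occupancy intercept (logit)
    beta_wo: float = 1.2  # wetness -> occupancy (logit)
    beta_uo: float = 0.0  # utilization -> occupancy (logit); null by default
    lam_cp: float = 1.0  # fixed loading, sets the latent scale
    lam_tp: float = 0.9
    lam_adf: float = -0.8  # negative: high fiber = low quality
    sigma_cp: float = 0.45
    sigma_tp: float = 0.55
    sigma_adf: float = 0.5
    sigma_q: float = 0.5
    sigma_p: float = 0.6
    rho_qp: float = 0.0  # quality-productivity disturbance correlation
    sigma_u: float = 0.45
    sigma_meadow: float = 0.15
    sigma_allotment: float = 0.1
    sigma_year: float = 0.1
    sigma_fecal: float = 0.44
    beta_uf: float = 0.9  # utilization -> fecal density

    def __post_init__(self) -> None:
        if self.lam_cp != 1.0:
            raise ParameterError("lam_cp must be fixed at 1.0")
        for name in (
            "sigma_cp", "sigma_tp", "sigma_adf", "sigma_q", "sigma_p",
            "sigma_u", "sigma_meadow", "sigma_allotment", "sigma_year",
            "sigma_fecal",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not abs(self.rho_qp) < 1:
            raise ParameterError("|rho_qp| must be < 1")
        _as_season_map(self.beta_qu, "beta_qu")
        _as_season_map(self.beta_pu, "beta_pu")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_qu"] = _as_season_map(self.beta_qu, "beta_qu")
        d["beta_pu"] = _as_season_map(self.beta_pu, "beta_pu")
        return d


def implied_corr_w_indicator(params: TrueParams, loading: float) -> float:
    """Closed-form corr(site wetness, indicator) under the generative model.

    An indicator X = lam*Q + eps with Q = gamma_wq*w + group effects +
    disturbance, all terms independent of the standardized wetness w
    (variance 1), gives

        corr(w, X) = lam*gamma_wq / sqrt(var(X)),
        var(X) = lam^2*(gamma_wq^2 + s_re^2 + sigma_q^2) + sigma_eps^2

    with s_re^2 the summed random-effect variances. Used as an analytic
    oracle for moment checks on large simulations.
    """
    s_re2 = params.sigma_meadow**2 + params.sigma_allotment**2 + params.sigma_year**2
    var_q = params.gamma_wq**2 + s_re2 + params.sigma_q**2
    sigma_eps = {
        params.lam_cp: params.sigma_cp,
        params.lam_tp: params.sigma_tp,
        params.lam_adf: params.sigma_adf,
    }[loading]
    var_x = loading**2 * var_q + sigma_eps**2
    return loading * params.gamma_wq / np.sqrt(var_x)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def simulate(
    design: StudyDesign,
    params: TrueParams | None = None,
    seed: int = 0,
    include_latent: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueParams]:
    """Simulate site and meadow-year tables under the generative model.

    Returns ``(sites, meadow_years, params)``; identical seeds yield
    byte-identical tables. Site wetness ranks are a one-time assignment
    repeated across years and seasons. With ``include_latent`` the
    meadow-year table additionally carries the (normally unobservable)
    meadow-mean latent quality per season as ``q_mean_{season}`` — a
    debugging/calibration aid, not part of the observable data contract.
    """
    params = params or TrueParams()
    rng = np.random.default_rng(seed)
    b_qu = _as_season_map(params.beta_qu, "beta_qu")
    b_pu = _as_season_map(params.beta_pu, "beta_pu")

    n_m = design.n_meadows
    meadow_allot = np.repeat(
        np.arange(design.n_allotments), design.meadows_per_allotment
    )
    n_sites = design.n_sites
    site_meadow = np.repeat(np.arange(n_m), design.sites_per_meadow)

    # one-time site wetness ranks: latent normal around a meadow mean,
    # rounded half-up and clamped to the ordinal 0-6 scale
    meadow_mu = rng.normal(3.0, 1.5, size=n_m)
    latent_w = rng.normal(meadow_mu[site_meadow], 1.0)
    ranks = np.clip(np.floor(latent_w + 0.5), 0, 6).astype(int)
    w_site = _standardize(ranks.astype(float))

    # composite meadow ranks and standardized meadow wetness
    comp = [
        composite_meadow_rank(ranks[site_meadow == m].tolist()) for m in range(n_m)
    ]
    mean_scores = np.array([c.mean_score for c in comp])
    comp_ranks = np.array([c.rank for c in comp])
    w_meadow = _standardize(mean_scores)

    # equation-specific random effects, shared SDs
    def effects(n_groups: int, sd: float) -> np.ndarray:
        return rng.normal(0.0, sd, size=n_groups)

    eff = {}
    for eq in ("q", "p", "u"):
        eff[eq] = {
            "meadow": effects(n_m, params.sigma_meadow),
            "allot": effects(design.n_allotments, params.sigma_allotment),
            "year": {y: effects(1, params.sigma_year)[0] for y in design.years},
        }

    site_frames = []
    # standardized utilization accumulated per meadow-year for occupancy
    u_star_sum = np.zeros((n_m, len(design.years)))
    u_star_n = np.zeros((n_m, len(design.years)))
    q_means = {s: np.zeros((n_m, len(design.years))) for s in design.seasons}

    cov = np.array(
        [
            [params.sigma_q**2, params.rho_qp * params.sigma_q * params.sigma_p],
            [params.rho_qp * params.sigma_q * params.sigma_p, params.sigma_p**2],
        ]
    )
    chol = np.linalg.cholesky(cov) if np.all(np.diag(cov) > 0) else np.zeros((2, 2))

    for yi, year in enumerate(design.years):
        for season in design.seasons:
            z = rng.standard_normal((n_sites, 2))
            zeta = z @ chol.T
            am = site_meadow
            aa = meadow_allot[site_meadow]
            q = (
                params.gamma_wq * w_site
                + eff["q"]["meadow"][am]
                + eff["q"]["allot"][aa]
                + eff["q"]["year"][year]
                + zeta[:, 0]
            )
            p = (
                params.gamma_wp * w_site
                + eff["p"]["meadow"][am]
                + eff["p"]["allot"][aa]
                + eff["p"]["year"][year]
                + zeta[:, 1]
            )
            cp = params.lam_cp * q + rng.normal(0, params.sigma_cp, n_sites)
            tp = params.lam_tp * q + rng.normal(0, params.sigma_tp, n_sites)
            adf = params.lam_adf * q + rng.normal(0, params.sigma_adf, n_sites)
            u = (
                b_qu[season] * q
                + b_pu[season] * p
                + eff["u"]["meadow"][am]
                + eff["u"]["allot"][aa]
                + eff["u"]["year"][year]
                + rng.normal(0, params.sigma_u, n_sites)
            )
            np.add.at(u_star_sum, (am, yi), u)
            np.add.at(u_star_n, (am, yi), 1.0)
            q_means[season][:, yi] = np.bincount(
                am, weights=q, minlength=n_m
            ) / np.bincount(am, minlength=n_m)

            c, s = UNIT_MAPS["cp"]
            cp_u = np.maximum(c + s * cp, 0.1)
            c, s = UNIT_MAPS["tp"]
            tp_u = np.maximum(c + s * tp, 0.001)
            c, s = UNIT_MAPS["adf"]
            adf_u = np.maximum(c + s * adf, 0.1)
            c, s = UNIT_MAPS["biomass"]
            bio_u = np.maximum(c + s * p, 1.0)
            c, s = UNIT_MAPS["utilization"]
            util_u = np.clip(c + s * u, 0.0, 1.0)

            site_frames.append(
                pd.DataFrame(
                    {
                        "allotment": meadow_allot[site_meadow],
                        "meadow": site_meadow,
                        "site": np.tile(
                            np.arange(design.sites_per_meadow), n_m
                        ),
                        "year": int(year),
                        "season": season,
                        "rank": ranks,
                        "cp": cp_u,
                        "tp": tp_u,
                        "adf": adf_u,
                        "biomass": bio_u,
                        "utilization": util_u,
                    }
                )
            )

    sites = pd.concat(site_frames, ignore_index=True)

    # meadow-year occupancy: one Bernoulli draw on the logit of wetness
    # and mean standardized utilization, plus two extra surveys for the
    # 3-survey occupancy rate
    u_bar = u_star_sum / u_star_n
    logits = (
        params.alpha
        + params.beta_wo * w_meadow[:, None]
        + params.beta_uo * u_bar
    )
    p_occ = 1.0 / (1.0 + np.exp(-logits))
    occ = (rng.random(p_occ.shape) < p_occ).astype(int)
    extra = (rng.random(p_occ.shape + (2,)) < p_occ[..., None]).astype(int)
    occ_rate = (occ + extra.sum(axis=-1)) / 3.0

    f_star = params.beta_uf * u_bar + rng.normal(
        0, params.sigma_fecal, size=u_bar.shape
    )
    c, s = UNIT_MAPS["fecal"]
    fecal = np.maximum(c + s * f_star, 0.0)

    mm, yy = np.meshgrid(np.arange(n_m), np.arange(len(design.years)), indexing="ij")
    meadow_years = pd.DataFrame(
        {
            "meadow": mm.ravel(),
            "allotment": meadow_allot[mm.ravel()],
            "year": np.asarray(design.years)[yy.ravel()],
            "mean_score": mean_scores[mm.ravel()],
            "comp_rank": comp_ranks[mm.ravel()],
            "occupancy": occ[mm.ravel(), yy.ravel()],
            "occupancy_rate": occ_rate[mm.ravel(), yy.ravel()],
            "fecal_density": fecal[mm.ravel(), yy.ravel()],
        }
    )
    season_means = (
        sites.groupby(["meadow", "year", "season"])[
            ["cp", "tp", "adf", "biomass", "utilization"]
        ]
        .mean()
        .unstack("season")
    )
    season_means.columns = [f"{var}_{season}" for var, season in season_means.columns]
    meadow_years = meadow_years.merge(
        season_means.reset_index(), on=["meadow", "year"], how="left"
    )
    order = ["meadow", "allotment", "year", "mean_score", "comp_rank",
             "occupancy", "occupancy_rate", "fecal_density"] + [
        f"{var}_{season}"
        for season in design.seasons
        for var in ("cp", "tp", "adf", "biomass", "utilization")
    ]
    meadow_years = meadow_years[order]
    if include_latent:
        for season in design.seasons:
            meadow_years[f"q_mean_{season}"] = q_means[season][
                meadow_years["meadow"].to_numpy(),
                np.searchsorted(np.asarray(design.years), meadow_years["year"]),
            ]

    return sites, meadow_years, params


def implied_standardized_truth(
    params: TrueParams,
    season: str = "mid",
    n_meadows: int = 4000,
    sites_per_meadow: int = 5,
    years: Sequence[int] = (2007, 2008),
    seed: int = 12345,
) -> dict[str, float]:
    """Generating-parameter values on the fitted (standardized) scale.

    The seasonal model standardizes meadow-aggregated columns, so path
    coefficients are estimands on that scale, not the site-level
    generation scale. This computes the implied values by Monte Carlo
    moments of a large simulation: the latent scale is pinned by the
    fixed CP loading, so the implied quality path divides by the CP
    aggregate SD; the wetness -> occupancy path needs no rescaling
    because occupancy is generated directly from standardized meadow
    wetness.
    """
    n_allot = max(n_meadows // 8, 1)
    counts = [8] * n_allot
    counts[-1] += n_meadows - 8 * n_allot
    design = StudyDesign(
        n_allotments=n_allot,
        meadows_per_allotment=tuple(counts),
        sites_per_meadow=sites_per_meadow,
        years=tuple(years),
    )
    _, my, _ = simulate(design, params, seed=seed, include_latent=True)
    w = _standardize(my["mean_score"].to_numpy())
    q = my[f"q_mean_{season}"].to_numpy()
    cp = my[f"cp_{season}"].to_numpy()
    p = _standardize(my[f"biomass_{season}"].to_numpy())
    u = _standardize(my[f"utilization_{season}"].to_numpy())
    s_cp = cp.std(ddof=1) / UNIT_MAPS["cp"][1]  # SD on the standardized scale
    q_f = (q - q.mean()) / s_cp
    cov_wq = float(np.cov(w, q_f)[0, 1])
    cov_wp = float(np.cov(w, p)[0, 1])
    # utilization paths: population regression of U on (Q_f, P)
    s = np.cov(np.column_stack([u, q_f, p]).T)
    beta = np.linalg.solve(s[1:, 1:], s[1:, 0])
    return {
        "gamma_wq": cov_wq,
        "gamma_wp": cov_wp,
        "beta_qu": float(beta[0]),
        "beta_pu": float(beta[1]),
        "beta_wo": float(params.beta_wo),
        # exact at the default 0; a nonzero value would need the SD of the
        # cross-season utilization mean, which the occupancy process uses
        "beta_uo": float(params.beta_uo),
    }


def write_dataset(
    outdir: str | Path,
    sites: pd.DataFrame,
    meadow_years: pd.DataFrame,
    params: TrueParams,
) -> dict[str, Path]:
    """Write sites.csv, meadow_years.csv and truth.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "sites.csv",
        "meadow_years": outdir / "meadow_years.csv",
        "truth": outdir / "truth.json",
    }
    sites.to_csv(paths["sites"], index=False)
    meadow_years.to_csv(paths["meadow_years"], index=False)
    paths["truth"].write_text(json.dumps(params.to_dict(), indent=2))
    return paths
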