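"""Synthetic Mediterranean stream-site data with known ground truth.

The generator emulates the statistical structure the gradient analysis
assumes, so every downstream stage (pruning, block-combination models,
VIP selection, cross-validation) can be verified by parameter recovery:

* an **environment table** for ``n_sites`` low-order streams whose 26
  sampled climate / soil / physical variables follow scaled-Beta marginals
  matched to published mean/SD/min/max summaries of southern-Spain streams,
  tied together through a Gaussian copula carrying one latent *aridity*
  factor (arid sites: low precipitation, high temperature and
  evapotranspiration, saltier/more alkaline soils, less organic carbon);
  the aridity indices (PP/PET, de Martonne, Emberger Q2) and the soil C:N
  ratio are computed from the sampled columns, never sampled;
* a **response table** with percent cover and Simpson diversity (1-D) for
  the five plant functional types (GG, ES, ET, DS, DT) plus total canopy
  cover and total diversity. Cover effects are linear on the arcsine
  square-root scale (the scale on which the analysis models them);
  diversity comes from Dirichlet species-abundance draws whose evenness
  increases with the same linear predictor;
* a **leaf-trait table** (species-level lognormal draws) whose group
  medians encode the deciduous/evergreen/graminoid trait syndromes:
  deciduous leaves have higher SLA and %N but lower toughness and C:N than
  evergreens; giant graminoids are silicon-rich and lignin-poor.

The signed effect matrix used for the responses is echoed back in the
returned dataset so recovery tests can score against the truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import indices

__all__ = [
    "VariableTarget",
    "SimConfig",
    "SyntheticDataset",
    "generate_environment",
    "generate_pft_responses",
    "generate_leaf_traits",
    "generate_dataset",
    "TABLE1_TARGETS",
    "DEFAULT_EFFECTS",
    "DEFAULT_SPECIES_COUNTS",
    "COVER_RESPONSES",
    "DIVERSITY_RESPONSES",
    "RESPONSE_COLUMNS",
]


@dataclass(frozen=True)
class VariableTarget:
    """Marginal summary (mean, SD, min, max) and block tag for one variable."""

    block: str
    mean: float
    sd: float
    min: float
    max: float


# Published environmental characterization of the 34 surveyed streams
# (mean, SD, min, max). Sampled variables only; PP_PET, IDM, Q2 and CN are
# derived downstream from these.
TABLE1_TARGETS: dict[str, VariableTarget] = {
    # climate
    "PP": VariableTarget("climate", 833, 325, 297, 1414),
    "PET": VariableTarget("climate", 741, 65, 633, 920),
    "DaysPP": VariableTarget("climate", 58, 17, 28, 89),
    "Tmean": VariableTarget("climate", 13.8, 2.0, 10.3, 18.3),
    "Tmin_jan": VariableTarget("climate", 2.6, 2.7, -1.3, 8.2),
    "Tmax_jul": VariableTarget("climate", 29.5, 2.3, 22.9, 33.0),
    "Trange": VariableTarget("climate", 26.9, 3.8, 14.9, 31.5),
    # soil
    "EC": VariableTarget("soil", 1020, 717, 301, 3290),
    "pH_w": VariableTarget("soil", 7.37, 0.96, 5.25, 8.81),
    "CaCO3": VariableTarget("soil", 18.97, 27.38, 0.01, 85.86),
    "OC": VariableTarget("soil", 2.64, 1.79, 0.10, 5.41),
    "N": VariableTarget("soil", 0.122, 0.089, 0.017, 0.358),
    "P": VariableTarget("soil", 329, 164, 92, 783),
    "CEC": VariableTarget("soil", 14.89, 9.69, 2.68, 47.80),
    "AW": VariableTarget("soil", 4.79, 2.26, 1.26, 11.07),
    "BS": VariableTarget("soil", 88.88, 15.77, 45.69, 100.00),
    "ESP": VariableTarget("soil", 2.65, 5.71, 0.13, 32.39),
    # physical
    "altitude": VariableTarget("physical", 763, 391, 47, 1465),
    "slope": VariableTarget("physical", 20, 5, 9, 31),
    "basin_area": VariableTarget("physical", 559, 346, 12, 1480),
    "southern_orientation": VariableTarget("physical", 67, 65, 1, 180),
    "bankfull_width": VariableTarget("physical", 9, 5, 3, 19),
    "active_width": VariableTarget("physical", 2.2, 1, 0.75, 5),
    "hard_substrate": VariableTarget("physical", 34, 23, 5, 80),
    "discharge": VariableTarget("physical", 98, 147, 3, 597),
}

#: Loadings of the sampled climate variables on the latent aridity factor
#: (arid = high). PET is loaded strongly so that it tracks the PP/PET ratio
#: above the |r| = 0.85 pruning threshold, the collinearity that motivates
#: the variable-reduction step.
DEFAULT_ARIDITY_LOADINGS: dict[str, float] = {
    "PP": -0.93,
    "PET": 0.95,
    "DaysPP": -0.75,
    "Tmean": 0.70,
    "Tmin_jan": 0.55,
    "Tmax_jul": 0.60,
    "Trange": 0.25,
}

#: Aridity-to-soil coupling: salinization/alkalinization with aridity,
#: organic carbon declining.
DEFAULT_SOIL_COUPLING: dict[str, float] = {
    "EC": 0.60,
    "pH_w": 0.50,
    "ESP": 0.60,
    "BS": 0.50,
    "OC": -0.50,
}

PFTS = ["GG", "ES", "ET", "DS", "DT"]
COVER_RESPONSES = [f"cover_{p}" for p in PFTS]
DIVERSITY_RESPONSES = [f"div_{p}" for p in PFTS]
RESPONSE_COLUMNS = COVER_RESPONSES + ["cover_total_canopy"] + DIVERSITY_RESPONSES + ["div_total"]

#: Signed standardized effects (predictor -> response) on the arcsine-sqrt
#: cover scale / diversity linear-predictor scale. Encodes the reported sign
#: structure: aridity favours giant graminoids and disfavours deciduous
#: trees; precipitation and mild winters favour evergreens; deciduous trees
#: increase with altitude. Magnitudes are free parameters of the generator.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "cover_GG": {"Tmean": 0.8, "PP_PET": -0.6, "EC": 0.3, "pH_w": 0.2},
    "cover_ES": {"PP": 0.6, "Tmin_jan": 0.6},
    "cover_ET": {"PP": 0.7, "Tmin_jan": 0.4},
    "cover_DS": {},
    "cover_DT": {"altitude": 0.8, "Tmean": -0.5, "EC": -0.4, "ESP": -0.3},
    "div_GG": {"Tmean": 0.7, "PP_PET": -0.6, "pH_w": 0.4, "EC": 0.3},
    "div_ES": {"PP": 0.5, "Tmin_jan": 0.5, "hard_substrate": 0.5},
    "div_ET": {"PP": 0.6, "Trange": -0.5, "Tmax_jul": -0.4},
    "div_DS": {"PP": 0.5, "Tmean": -0.5},
    "div_DT": {"altitude": 0.7, "Tmean": -0.6, "OC": 0.4},
    "div_total": {},
}

#: Leaf-trait species counts per functional type (32 species total).
DEFAULT_SPECIES_COUNTS: dict[str, int] = {"GG": 3, "ES": 6, "ET": 5, "DS": 3, "DT": 15}

#: Group trait medians: SLA (mm^2 g^-1), toughness (g), N_mass (%), C:N,
#: lignin (%), Si (%). Chosen to encode the deciduous > evergreen SLA/%N and
#: evergreen > deciduous toughness/C:N orderings, plus the graminoid
#: high-Si / low-lignin syndrome.
DEFAULT_TRAIT_MEDIANS: dict[str, dict[str, float]] = {
    "GG": {"SLA": 9000, "toughness": 380, "N_mass": 1.6, "CN": 30, "lignin": 4.0, "Si": 2.5},
    "ES": {"SLA": 7500, "toughness": 380, "N_mass": 1.3, "CN": 35, "lignin": 13.0, "Si": 0.15},
    "ET": {"SLA": 7000, "toughness": 400, "N_mass": 1.2, "CN": 37, "lignin": 14.0, "Si": 0.12},
    "DS": {"SLA": 13000, "toughness": 200, "N_mass": 2.2, "CN": 20, "lignin": 11.0, "Si": 0.20},
    "DT": {"SLA": 12500, "toughness": 190, "N_mass": 2.3, "CN": 19, "lignin": 12.0, "Si": 0.18},
}

#: Baseline mean percent covers per functional type (arcsine-sqrt intercepts).
DEFAULT_COVER_BASELINE: dict[str, float] = {"GG": 25, "ES": 12, "ET": 15, "DS": 8, "DT": 35}


@dataclass
class SimConfig:
    """All knobs of the synthetic stream-site generator.

    Defaults are the study conditions: 34 sites spanning the published
    variable ranges, aridity-driven collinearity, the reported sign
    structure of predictor effects, and 3/6/5/3/15 trait species per
    functional type.
    """

    n_sites: int = 34
    seed: int = 0
    block_targets: dict[str, VariableTarget] = field(
        default_factory=lambda: dict(TABLE1_TARGETS))
    aridity_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARIDITY_LOADINGS))
    climate_soil_coupling: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOIL_COUPLING))
    effect_matrix: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_EFFECTS))
    noise_sd: float = 0.3
    cover_scale: float = 0.22          # radians per unit linear predictor
    cover_baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVER_BASELINE))
    cover_simplex: bool = True
    diversity_intercept: float = 0.8   # log-concentration at eta = 0
    diversity_slope: float = 0.7       # log-concentration per unit eta
    species_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_COUNTS))
    trait_medians: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_TRAIT_MEDIANS))
    trait_log_sd: float = 0.25
    trait_separation: float = 1.0      # 0 = no between-group differences

    def validate(self) -> None:
        if self.n_sites < 10:
            raise ValueError("n_sites must be at least 10")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        for var, t in self.block_targets.items():
            if t.min > t.max:
                raise ValueError(f"infeasible bounds for {var}: min {t.min} > max {t.max}")
            if t.sd <= 0:
                raise ValueError(f"SD for {var} must be positive")
        for resp, effects in self.effect_matrix.items():
            for beta in effects.values():
                if not np.isfinite(beta):
                    raise ValueError(f"non-finite effect size in {resp}")
        for pft, n in self.species_counts.items():
            if n < 1:
                raise ValueError(f"species count for {pft} must be >= 1")


@dataclass
class SyntheticDataset:
    """A complete generated study: tables plus the truth used to make them."""

    environment: pd.DataFrame
    responses: pd.DataFrame
    traits: pd.DataFrame
    truth: dict[str, dict[str, float]]
    latent_aridity: np.ndarray


def _beta_params(t: VariableTarget) -> tuple[float, float]:
    """Shape parameters of the Beta on [min, max] matching mean and SD."""
    span = t.max - t.min
    mu = (t.mean - t.min) / span
    var = (t.sd / span) ** 2
    if var >= mu * (1 - mu):
        return np.nan, np.nan  # moment condition fails; caller falls back
    nu = mu * (1 - mu) / var - 1.0
    return mu * nu, (1 - mu) * nu


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent deterministic stream per stage so each generate_* call is
    # reproducible on its own
    return np.random.default_rng([stage, config.seed])


def generate_environment(config: SimConfig) -> pd.DataFrame:
    """Sample the site x variable environment table.

    One latent aridity factor drives the loaded climate variables and the
    coupled soil variables; every marginal is a scaled Beta on its
    [min, max] range matched to the target mean/SD (Gaussian copula), so
    large-sample column means converge to the configured targets. The
    aridity indices PP/PET, de Martonne (IDM), Emberger (Q2) and the soil
    C:N ratio are computed, not sampled. The latent factor is stored in
    ``df.attrs["latent_aridity"]``.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_sites
    z = rng.standard_normal(n)

    loadings = dict(config.aridity_loadings)
    loadings.update(config.climate_soil_coupling)

    cols: dict[str, np.ndarray] = {}
    for var, t in config.block_targets.items():
        lam = float(loadings.get(var, 0.0))
        if abs(lam) > 1:
            raise ValueError(f"loading for {var} must lie in [-1, 1]")
        g = lam * z + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        u = stats.norm.cdf(g)
        a, b = _beta_params(t)
        if np.isfinite(a):
            x = t.min + (t.max - t.min) * stats.beta.ppf(u, a, b)
        else:  # fall back: truncated Gaussian via clipping
            x = np.clip(t.mean + t.sd * g, t.min, t.max)
        cols[var] = x

    df = pd.DataFrame(cols, index=[f"S{i + 1:02d}" for i in range(n)])
    df.index.name = "site"
    df["PP_PET"] = indices.unep_aridity(df["PP"].to_numpy(), df["PET"].to_numpy())
    df["IDM"] = indices.de_martonne(df["PP"].to_numpy(), df["Tmean"].to_numpy())
    df["Q2"] = indices.emberger_q2(
        df["PP"].to_numpy(), df["Tmax_jul"].to_numpy(), df["Tmin_jan"].to_numpy())
    df["CN"] = df["OC"] / df["N"]
    from .schema import ENV_COLUMNS  # canonical column order
    df = df[[c for c in ENV_COLUMNS if c in df.columns]]
    df.attrs["latent_aridity"] = z
    return df


def _linear_predictors(env: pd.DataFrame, effects: dict[str, dict[str, float]]) -> pd.DataFrame:
    zenv = (env - env.mean()) / env.std(ddof=1)
    eta = {}
    for resp, coef in effects.items():
        unknown = sorted(set(coef) - set(env.columns))
        if unknown:
            raise ValueError(f"effect matrix names unknown predictor(s) for {resp}: {unknown}")
        eta[resp] = sum((beta * zenv[var] for var, beta in coef.items()),
                        pd.Series(0.0, index=env.index))
    return pd.DataFrame(eta, index=env.index)


def generate_pft_responses(env: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate percent covers and Simpson diversities from the environment.

    Covers: theta = asin(sqrt(p0)) + cover_scale * (eta + noise) clipped to
    [0, pi/2], cover = 100 sin^2(theta). Diversity: Dirichlet abundances
    with concentration exp(a + b * (eta + noise)); Simpson 1-D computed
    from the draw. Total canopy combines the woody covers as overlapping
    layers; total diversity pools all species abundances weighted by their
    group's cover.
    """
    if env.shape[0] == 0:
        raise ValueError("environment table is empty")
    config.validate()
    rng = _rng(config, 1)
    eta = _linear_predictors(env, config.effect_matrix)
    n = env.shape[0]
    out = pd.DataFrame(index=env.index)

    covers = {}
    for pft in PFTS:
        name = f"cover_{pft}"
        e = eta[name] if name in eta else pd.Series(0.0, index=env.index)
        noise = rng.normal(0.0, config.noise_sd, n)
        theta0 = np.arcsin(np.sqrt(config.cover_baseline[pft] / 100.0))
        theta = np.clip(theta0 + config.cover_scale * (e.to_numpy() + noise), 0.0, np.pi / 2)
        covers[pft] = 100.0 * np.sin(theta) ** 2
    if config.cover_simplex:
        total = sum(covers.values())
        factor = np.minimum(1.0, 100.0 / np.maximum(total, 1e-9))
        covers = {p: c * factor for p, c in covers.items()}
    for pft in PFTS:
        out[f"cover_{pft}"] = covers[pft]

    # overlapping woody canopy layers
    woody = [covers[p] / 100.0 for p in ("ES", "ET", "DT")]
    out["cover_total_canopy"] = 100.0 * (1.0 - np.prod([1.0 - w for w in woody], axis=0))

    abundances: dict[str, np.ndarray] = {}
    for pft in PFTS:
        name = f"div_{pft}"
        e = eta[name] if name in eta else pd.Series(0.0, index=env.index)
        noise = rng.normal(0.0, config.noise_sd, n)
        conc = np.exp(config.diversity_intercept
                      + config.diversity_slope * (e.to_numpy() + noise))
        conc = np.clip(conc, 0.05, 50.0)
        s = config.species_counts.get(pft, DEFAULT_SPECIES_COUNTS[pft])
        draws = np.vstack([rng.dirichlet(np.full(s, c)) for c in conc])
        abundances[pft] = draws
        out[name] = 1.0 - np.sum(draws**2, axis=1)

    pooled = np.hstack([abundances[p] * (covers[p][:, None] + 1e-9) for p in PFTS])
    pooled /= pooled.sum(axis=1, keepdims=True)
    out["div_total"] = 1.0 - np.sum(pooled**2, axis=1)
    return out[RESPONSE_COLUMNS]


def generate_leaf_traits(config: SimConfig) -> pd.DataFrame:
    """Species-level leaf-trait table with a-priori functional-type labels.

    Lognormal draws around group medians; ``trait_separation`` scales the
    log-distance of every group median from the across-group mean (0 =
    identical groups, the ANOVA null). %C is derived as C:N x %N so the
    carbon columns stay internally consistent.
    """
    config.validate()
    rng = _rng(config, 2)
    trait_names = ["SLA", "toughness", "N_mass", "CN", "lignin", "Si"]
    log_center = {
        t: np.mean([np.log(config.trait_medians[p][t]) for p in config.species_counts])
        for t in trait_names
    }
    rows = []
    for pft in PFTS:
        if pft not in config.species_counts:
            continue
        for k in range(config.species_counts[pft]):
            row = {"species": f"{pft}_sp{k + 1:02d}", "pft": pft}
            for t in trait_names:
                mu = log_center[t] + config.trait_separation * (
                    np.log(config.trait_medians[pft][t]) - log_center[t])
                row[t] = float(np.exp(mu + config.trait_log_sd * rng.standard_normal()))
            rows.append(row)
    df = pd.DataFrame(rows).set_index("species")
    df["C_mass"] = df["CN"] * df["N_mass"]
    return df[["pft", "SLA", "toughness", "N_mass", "C_mass", "CN", "lignin", "Si"]]


def generate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the full study: environment, responses, traits, truth."""
    config = config or SimConfig()
    env = generate_environment(config)
    responses = generate_pft_responses(env, config)
    traits = generate_leaf_traits(config)
    return SyntheticDataset(
        environment=env,
        responses=responses,
        traits=traits,
        truth=copy.deepcopy(config.effect_matrix),
        latent_aridity=env.attrs["latent_aridity"],
    )
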