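"""Synthetic advanced-gastric-cancer registry generator.

Patient-level data from the multicentre registry behind the published
triplet-vs-doublet comparison are not public, so this module generates
cohorts with the same observable structure and *known* ground truth:

* n = 1376 patients by default, first-line treated 2008-2019, with the
  registry's covariate mix (ECOG performance status, Lauren subtype,
  grade, ascites, stage, liver tumour burden, number of involved
  organs, platinum compound, neutrophil/lymphocyte ratio, age, year);
* confounding by indication: the docetaxel triplet (DPF) is assigned by
  a logistic propensity that falls with age and poor performance
  status, reproducing the ~17% triplet share;
* lognormal accelerated-failure-time outcomes.  Progression-free
  survival is drawn first; overall survival is PFS plus an independent
  lognormal post-progression time, which enforces ``pfs <= os`` by
  construction.  Both components scale with the covariates, so the true
  effects remain interpretable as time ratios;
* right censoring from uniform accrual, an administrative cutoff and
  exponential dropout;
* missingness in Lauren subtype (~21%) and grade (~24%), by default
  missing-at-random on age and year (younger, earlier records lose
  their histology more often), mimicking registry behaviour.

Every stage is deterministic under the configured seed.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

__all__ = [
    "ConfigError",
    "RegistryConfig",
    "CATEGORICAL_LEVELS",
    "PATIENT_COLUMNS",
    "default_config",
    "generate_cohort",
    "assign_treatment",
    "draw_outcomes",
    "inject_missingness",
    "truth_features",
    "write_cohort",
    "read_cohort",
]


class ConfigError(ValueError):
    """Invalid registry configuration."""


CATEGORICAL_LEVELS = {
    "sex": ("female", "male"),
    "ecog": ("0", "1", "2+"),
    "lauren": ("diffuse", "intestinal"),
    "grade": ("1", "2", "3"),
    "stage": ("metastatic", "locally-advanced-unresectable"),
    "liver_burden": ("none", "<25%", "25-50%", "51-75%", ">75%"),
    "n_organs": (0, 1, 2, 3, 4, 5),
    "platin": ("oxaliplatin", "cisplatin"),
}

PATIENT_COLUMNS = [
    "id", "age", "sex", "ecog", "lauren", "grade", "ascites", "stage",
    "liver_burden", "n_organs", "platin", "nlr", "year", "arm",
    "os_time", "os_event", "pfs_time", "pfs_event",
]

COHORT_FORMAT_VERSION = "tripletaft-cohort-v1"

# -- default configuration -------------------------------------------------
# Categorical frequencies follow the published baseline table of the
# registry cohort (ECOG 0/1/>=2 = 20/65/15%, Lauren diffuse/intestinal
# = 59/41% among observed, ascites 25%, oxaliplatin 65%, ...).  The
# outcome intercepts are calibrated so the default cohort reproduces
# the registry's whole-sample medians (OS ~10.2, PFS ~5.8 months), and
# the propensity intercept reproduces the 238/1376 triplet share.

_DEFAULT_MARGINALS = {
    "age": {"dist": "truncnorm", "mean": 65.0, "sd": 11.0, "lo": 20.0, "hi": 89.0},
    "nlr": {"dist": "lognormal", "median": 3.0, "sigma": 0.55},
    "year": {"dist": "uniform_int", "lo": 2008, "hi": 2019},
    "ascites": {"p": 0.25},
    "sex": {"female": 0.33, "male": 0.67},
    "ecog": {"0": 0.20, "1": 0.65, "2+": 0.15},
    "lauren": {"diffuse": 0.59, "intestinal": 0.41},
    "grade": {"1": 0.12, "2": 0.32, "3": 0.56},
    "stage": {"metastatic": 0.96, "locally-advanced-unresectable": 0.04},
    "liver_burden": {"none": 0.65, "<25%": 0.12, "25-50%": 0.06,
                     "51-75%": 0.10, ">75%": 0.07},
    "n_organs": {0: 0.04, 1: 0.43, 2: 0.28, 3: 0.15, 4: 0.07, 5: 0.03},
    "platin": {"oxaliplatin": 0.65, "cisplatin": 0.35},
}

_DEFAULT_PROPENSITY = {
    "intercept": -1.443,
    "coef": {
        "age_dec_c": -0.55,       # per decade above 65: older -> less DPF
        "age_dec_c_sq": -0.12,    # nonlinear taper at both extremes
        "ecog_2plus": -1.10,
        "stage_la": 0.40,
    },
}

# Shared prognostic coefficients (log time-ratio scale).  The treatment
# truth anchors on the published fits: PFS effect ~ TR 1.27, OS effect
# ~ TR 1.19 overall, diffuse-vs-intestinal interaction ln(1.27/1.17),
# and a declining effect over calendar time.
_PROGNOSTIC_COEF = {
    "ecog_2plus": -0.40,
    "lauren_intestinal": 0.10,
    "grade_3": -0.12,
    "ascites": -0.15,
    "stage_la": 0.20,
    "liver_burden_ord": -0.07,
    "n_organs": -0.07,
    "platin_cisplatin": 0.02,
    "log_nlr_c": -0.20,
    "age_dec_c": -0.03,
    "year_c": 0.01,
}
_INTERACTION_COEF = {
    "arm_dpf:lauren_intestinal": float(np.log(1.27 / 1.17)),
    "arm_dpf:year_c": -0.011,
}

_DEFAULT_TRUTH = {
    "pfs": {
        "intercept": 2.051,
        "sigma": 0.85,
        "coef": {"arm_dpf": float(np.log(1.23)), **_PROGNOSTIC_COEF, **_INTERACTION_COEF},
    },
    # post-progression survival; OS = PFS + this component
    "post_progression": {
        "intercept": 1.464,
        "sigma": 1.05,
        "coef": {"arm_dpf": float(np.log(1.09)), **_PROGNOSTIC_COEF, **_INTERACTION_COEF},
    },
}

_DEFAULT_CENSORING = {
    "accrual": {"start": 2008, "end": 2019},
    "cutoff_year": 2020.25,
    "dropout_rate_per_month": 0.004,
}

_DEFAULT_MISSINGNESS = {
    "lauren": {"rate": 0.21, "mechanism": "MAR"},
    "grade": {"rate": 0.24, "mechanism": "MAR"},
}

#: MAR log-odds slopes on the fully observed predictors (rate-calibrated
#: intercept is solved per column): younger patients and earlier years
#: are more likely to lack central histology review.
_MAR_SLOPES = {"age_dec_c": -0.35, "year_c": -0.10}


@dataclass
class RegistryConfig:
    """Full generative specification of a synthetic cohort."""

    n: int = 1376
    covariate_marginals: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_MARGINALS))
    propensity: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_PROPENSITY))
    truth: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_TRUTH))
    censoring: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_CENSORING))
    missingness: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_MISSINGNESS))
    seed: int = 20080101

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ConfigError(f"cohort size n must be a positive integer, got {self.n}")
        for var, levels in CATEGORICAL_LEVELS.items():
            marg = self.covariate_marginals.get(var)
            if marg is None:
                raise ConfigError(f"missing marginal for categorical variable {var!r}")
            missing_levels = set(levels) - set(marg)
            if missing_levels:
                raise ConfigError(f"marginal for {var!r} lacks levels {sorted(missing_levels, key=str)}")
            total = float(sum(marg[lev] for lev in levels))
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigError(f"frequencies for {var!r} sum to {total:.6f}, not 1")
            if any(marg[lev] < 0 for lev in levels):
                raise ConfigError(f"negative frequency in marginal for {var!r}")
        p_asc = self.covariate_marginals.get("ascites", {}).get("p")
        if p_asc is None or not (0 <= p_asc <= 1):
            raise ConfigError(f"ascites flag probability must be in [0, 1], got {p_asc}")
        for part in ("pfs", "post_progression"):
            spec = self.truth.get(part)
            if spec is None:
                raise ConfigError(f"truth must define {part!r}")
            if not spec.get("sigma", 0) > 0:
                raise ConfigError(f"truth[{part!r}] sigma must be > 0, got {spec.get('sigma')}")
        for col, spec in self.missingness.items():
            rate = spec.get("rate")
            if rate is None or not (0 <= rate <= 1):
                raise ConfigError(f"missingness rate for {col!r} must be in [0, 1], got {rate}")
            mech = spec.get("mechanism", "MCAR")
            if mech not in ("MCAR", "MAR"):
                raise ConfigError(f"unknown missingness mechanism {mech!r} for {col!r}")
            if mech == "MAR" and col in ("age", "year"):
                # MAR conditions on age/year, which must stay observed
                raise ConfigError("MAR mechanism cannot target its own predictors (age, year)")
        if self.censoring is not None and \
                not self.censoring.get("dropout_rate_per_month", 0) >= 0:
            raise ConfigError("dropout rate must be >= 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return copy.deepcopy(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RegistryConfig":
        base = cls()
        merged = base.to_dict()
        for key, val in d.items():
            if key not in merged:
                raise ConfigError(f"unknown configuration key {key!r}")
            merged[key] = val
        # n_organs level keys may arrive as strings from YAML/JSON
        organs = merged["covariate_marginals"].get("n_organs")
        if organs is not None:
            merged["covariate_marginals"]["n_organs"] = {int(k): v for k, v in organs.items()}
        return cls(**merged)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RegistryConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_config(**overrides) -> RegistryConfig:
    """The packaged, registry-calibrated configuration."""
    cfg = RegistryConfig()
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


# -- feature coding shared by propensity and outcome truth ------------------

def truth_features(covariates: pd.DataFrame, arm=None) -> pd.DataFrame:
    """Numeric features referenced by propensity and truth coefficients.

    Continuous covariates are centred at registry-typical values (age 65,
    year 2013, median NLR 3) so intercepts stay interpretable.
    """
    f = pd.DataFrame(index=covariates.index)
    f["age_dec_c"] = (covariates["age"] - 65.0) / 10.0
    f["age_dec_c_sq"] = f["age_dec_c"] ** 2
    f["ecog_2plus"] = (covariates["ecog"] == "2+").astype(float)
    f["lauren_intestinal"] = (covariates["lauren"] == "intestinal").astype(float)
    f["grade_3"] = (covariates["grade"] == "3").astype(float)
    f["ascites"] = covariates["ascites"].astype(float)
    f["stage_la"] = (covariates["stage"] == "locally-advanced-unresectable").astype(float)
    f["liver_burden_ord"] = covariates["liver_burden"].map(
        {lev: i for i, lev in enumerate(CATEGORICAL_LEVELS["liver_burden"])}
    ).astype(float)
    f["n_organs"] = covariates["n_organs"].astype(float)
    f["platin_cisplatin"] = (covariates["platin"] == "cisplatin").astype(float)
    f["log_nlr_c"] = np.log(covariates["nlr"].astype(float)) - np.log(3.0)
    f["year_c"] = covariates["year"].astype(float) - 2013.0
    if arm is not None:
        f["arm_dpf"] = (np.asarray(arm) == "DPF").astype(float)
    return f


def _linear_predictor(features: pd.DataFrame, intercept: float, coef: dict) -> np.ndarray:
    lp = np.full(len(features), float(intercept))
    for name, value in coef.items():
        if ":" in name:
            a, b = name.split(":", 1)
            for part in (a, b):
                if part not in features.columns:
                    raise ConfigError(f"coefficient {name!r} references unknown feature {part!r}")
            col = features[a].to_numpy() * features[b].to_numpy()
        else:
            if name not in features.columns:
                raise ConfigError(f"coefficient references unknown feature {name!r}")
            col = features[name].to_numpy()
        lp += float(value) * col
    return lp


# -- generation stages -------------------------------------------------------

def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _draw_covariates(config: RegistryConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n
    m = config.covariate_marginals
    cov = pd.DataFrame(index=pd.RangeIndex(n))

    age_spec = m["age"]
    a = (age_spec["lo"] - age_spec["mean"]) / age_spec["sd"]
    b = (age_spec["hi"] - age_spec["mean"]) / age_spec["sd"]
    # truncated-normal draw via inverse CDF, driven by this rng
    u = rng.uniform(special.ndtr(a), special.ndtr(b), size=n)
    cov["age"] = age_spec["mean"] + age_spec["sd"] * special.ndtri(u)

    for var in ("sex", "ecog", "lauren", "grade", "stage", "liver_burden",
                "n_organs", "platin"):
        levels = list(CATEGORICAL_LEVELS[var])
        probs = np.array([m[var][lev] for lev in levels], dtype=float)
        idx = rng.choice(len(levels), size=n, p=probs / probs.sum())
        cov[var] = [levels[i] for i in idx]

    cov["ascites"] = (rng.uniform(size=n) < m["ascites"]["p"]).astype(int)
    nlr_spec = m["nlr"]
    cov["nlr"] = nlr_spec["median"] * np.exp(rng.normal(0.0, nlr_spec["sigma"], size=n))
    yr = m["year"]
    cov["year"] = rng.integers(yr["lo"], yr["hi"] + 1, size=n)
    return cov


def assign_treatment(covariates: pd.DataFrame, propensity: dict, rng=None) -> np.ndarray:
    """Draw the treatment arm from a per-row logistic propensity.

    Returns an array of ``"PF"`` / ``"DPF"`` labels.  With the default
    coefficients the triplet probability declines with age and with poor
    performance status (confounding by indication).
    """
    rng = _as_rng(rng)
    feats = truth_features(covariates)
    logit = _linear_predictor(feats, propensity.get("intercept", 0.0),
                              propensity.get("coef", {}))
    p_dpf = special.expit(logit)
    return np.where(rng.uniform(size=len(covariates)) < p_dpf, "DPF", "PF")


def draw_outcomes(covariates: pd.DataFrame, arm, truth: dict, censoring: dict,
                  rng=None) -> pd.DataFrame:
    """Draw censored PFS/OS responses under the lognormal AFT truth.

    The uncensored progression time is lognormal with location
    ``x'beta_pfs``; overall survival adds an independent lognormal
    post-progression time with location ``x'beta_pps``, so
    ``pfs <= os`` holds for every row.  Both are censored at the same
    per-patient time: min(administrative cutoff, dropout).
    """
    rng = _as_rng(rng)
    feats = truth_features(covariates, arm=arm)
    out = {}
    for part in ("pfs", "post_progression"):
        spec = truth[part]
        sigma = float(spec["sigma"])
        if sigma <= 0:
            raise ConfigError(f"truth[{part!r}] sigma must be > 0")
        lp = _linear_predictor(feats, spec["intercept"], spec.get("coef", {}))
        out[part] = np.exp(lp + sigma * rng.standard_normal(len(feats)))
    t_pfs = out["pfs"]
    t_os = t_pfs + out["post_progression"]

    n = len(feats)
    if censoring is None:
        c = np.full(n, np.inf)
    else:
        cutoff = float(censoring.get("cutoff_year", np.inf))
        entry = covariates["year"].to_numpy(dtype=float) + rng.uniform(0, 1, size=n)
        admin = np.maximum((cutoff - entry) * 12.0, 1e-3) if np.isfinite(cutoff) else np.full(n, np.inf)
        rate = float(censoring.get("dropout_rate_per_month", 0.0))
        dropout = rng.exponential(1.0 / rate, size=n) if rate > 0 else np.full(n, np.inf)
        c = np.minimum(admin, dropout)

    res = pd.DataFrame(index=covariates.index)
    res["os_time"] = np.minimum(t_os, c)
    res["os_event"] = (t_os <= c).astype(int)
    res["pfs_time"] = np.minimum(t_pfs, c)
    res["pfs_event"] = (t_pfs <= c).astype(int)
    return res


def _mar_probabilities(covariates: pd.DataFrame, rate: float) -> np.ndarray:
    """Per-row missingness probability with marginal mean = rate."""
    feats = truth_features(covariates)
    drift = sum(slope * feats[name].to_numpy() for name, slope in _MAR_SLOPES.items())
    if rate <= 0:
        return np.zeros(len(covariates))
    if rate >= 1:
        return np.ones(len(covariates))

    def mean_gap(intercept):
        return special.expit(intercept + drift).mean() - rate

    intercept = optimize.brentq(mean_gap, -30.0, 30.0)
    return special.expit(intercept + drift)


def inject_missingness(table: pd.DataFrame, missingness: dict, rng=None) -> pd.DataFrame:
    """Blank out entries per the configured rates; returns a copy.

    MCAR blanks uniformly at random at the given rate; MAR makes the
    probability depend on age and calendar year (both fully observed),
    with the intercept solved so the marginal rate is still the
    configured one.
    """
    rng = _as_rng(rng)
    out = table.copy()
    for col, spec in missingness.items():
        rate = float(spec["rate"])
        if not 0 <= rate <= 1:
            raise ConfigError(f"missingness rate for {col!r} must be in [0, 1]")
        mech = spec.get("mechanism", "MCAR")
        if mech == "MCAR":
            p = np.full(len(out), rate)
        elif mech == "MAR":
            if col in _MAR_SLOPES or col in ("age", "year"):
                raise ConfigError(f"MAR mechanism cannot blank its own predictor {col!r}")
            p = _mar_probabilities(table, rate)
        else:
            raise ConfigError(f"unknown missingness mechanism {mech!r}")
        mask = rng.uniform(size=len(out)) < p
        out[col] = out[col].astype(object)
        out.loc[mask, col] = np.nan
    return out


def generate_cohort(config: RegistryConfig | None = None) -> pd.DataFrame:
    """Generate one complete synthetic registry cohort.

    Covariates, treatment assignment, outcomes and missingness are drawn
    in sequence from a single generator seeded by ``config.seed``, so
    identical configurations yield byte-identical tables.
    """
    config = config if config is not None else default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = _draw_covariates(config, rng)
    arm = assign_treatment(cov, config.propensity, rng)
    outcomes = draw_outcomes(cov, arm, config.truth, config.censoring, rng)

    cohort = cov.copy()
    cohort.insert(0, "id", [f"P{i + 1:06d}" for i in range(config.n)])
    cohort["arm"] = arm
    cohort = pd.concat([cohort, outcomes], axis=1)
    cohort = inject_missingness(cohort, config.missingness, rng)
    return cohort[PATIENT_COLUMNS]


# -- cohort I/O --------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with a versioned header comment line."""
    with open(path, "w") as fh:
        fh.write(f"# {COHORT_FORMAT_VERSION}\n")
        cohort.to_csv(fh, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, comment="#",
                     dtype={"lauren": "object", "grade": "object"})
    return df
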