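"""Model design structure: encodings, splines, treatment interactions.

A :class:`ModelMatrixSpec` declares how cohort columns become design
columns — dummy coding with an explicit reference level, flags, linear
(optionally log-transformed) continuous terms, restricted cubic spline
expansions — plus treatment-by-covariate interaction blocks, and keeps
the registry mapping each design column to a coefficient label and
class (treatment / interaction / nuisance / intercept).

Continuous columns are centred and scaled by constants recorded in the
spec when it is built from a cohort, so the sampler works on unit-scale
covariates while patient profiles are transformed identically at
prediction time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import default_knots, rcs_basis

__all__ = ["Term", "ModelMatrixSpec", "default_model_spec"]

TERM_KINDS = ("categorical", "flag", "linear", "spline")


@dataclass
class Term:
    """One main-effect term of the design.

    kind:
      * ``categorical`` — dummy columns for every non-reference level;
      * ``flag`` — a single 0/1 column, never rescaled;
      * ``linear`` — one continuous column, optionally log-transformed;
      * ``spline`` — restricted cubic spline basis at ``knots``.
    """

    col: str
    kind: str = "linear"
    reference: str | None = None
    levels: tuple = ()
    knots: tuple = ()
    log: bool = False
    center: tuple = ()
    scale: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r} for column {self.col!r}")
        if self.kind == "categorical" and (self.reference is None or not self.levels):
            raise ValueError(f"categorical term {self.col!r} needs reference and levels")
        if self.kind == "spline" and len(self.knots) < 3:
            raise ValueError(f"spline term {self.col!r} needs >= 3 knots")

    def labels(self) -> list[str]:
        if self.kind == "categorical":
            return [f"{self.col}[{lev}]" for lev in self.levels]
        if self.kind == "flag":
            return [self.col]
        if self.kind == "linear":
            return [f"log({self.col})" if self.log else self.col]
        stem = f"log({self.col})" if self.log else self.col
        return [stem] + [f"{stem}_rcs{j}" for j in range(1, len(self.knots) - 1)]

    def raw(self, df: pd.DataFrame) -> np.ndarray:
        if self.col not in df.columns:
            raise KeyError(f"design term references missing column {self.col!r}")
        x = df[self.col]
        if x.isna().any():
            raise ValueError(
                f"column {self.col!r} has missing values; impute before building the design"
            )
        if self.kind == "categorical":
            vals = x.astype(str).to_numpy()
            known = set(map(str, self.levels)) | {str(self.reference)}
            unknown = set(vals) - known
            if unknown:
                raise ValueError(f"column {self.col!r} has unknown levels {sorted(unknown)}")
            return np.column_stack([(vals == str(lev)).astype(float) for lev in self.levels])
        if self.kind == "flag":
            return x.astype(float).to_numpy()[:, None]
        v = x.astype(float).to_numpy()
        if self.log:
            if np.any(v <= 0):
                raise ValueError(f"log transform of {self.col!r} needs positive values")
            v = np.log(v)
        if self.kind == "linear":
            return v[:, None]
        return rcs_basis(v, self.knots)

    @property
    def scaled(self) -> bool:
        return self.kind in ("linear", "spline")

    def fit_scaling(self, df: pd.DataFrame) -> None:
        raw = self.raw(df)
        if self.scaled:
            sd = raw.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            self.center = tuple(float(c) for c in raw.mean(axis=0))
            self.scale = tuple(float(s) for s in sd)
        else:
            self.center = tuple(0.0 for _ in range(raw.shape[1]))
            self.scale = tuple(1.0 for _ in range(raw.shape[1]))

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        raw = self.raw(df)
        if not self.center:
            raise ValueError(f"term {self.col!r} has no recorded scaling; build the spec from a cohort")
        return (raw - np.asarray(self.center)) / np.asarray(self.scale)


@dataclass
class ModelMatrixSpec:
    """Full design specification for one AFT model fit."""

    terms: list = field(default_factory=list)
    treatment_col: str = "arm"
    treatment_level: str = "DPF"
    treatment_reference: str = "PF"
    interactions: list = field(default_factory=list)

    INTERCEPT = "intercept"

    def __post_init__(self) -> None:
        declared = {t.col for t in self.terms}
        for col in self.interactions:
            if col not in declared:
                raise ValueError(
                    f"interaction with {col!r} has no declared main-effect term"
                )
        labels = self.labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate design column labels")

    # -- labels and classes ------------------------------------------------
    @property
    def treatment_label(self) -> str:
        return f"{self.treatment_col}[{self.treatment_level}]"

    def _term(self, col: str) -> Term:
        for t in self.terms:
            if t.col == col:
                return t
        raise KeyError(f"no term for column {col!r}")

    def interaction_labels(self, col: str) -> list[str]:
        return [f"{self.treatment_label}:{lab}" for lab in self._term(col).labels()]

    def labels(self) -> list[str]:
        labels = [self.INTERCEPT, self.treatment_label]
        for t in self.terms:
            labels.extend(t.labels())
        for col in self.interactions:
            labels.extend(self.interaction_labels(col))
        return labels

    def coefficient_classes(self) -> dict[str, str]:
        classes = {self.INTERCEPT: "intercept", self.treatment_label: "treatment"}
        for t in self.terms:
            for lab in t.labels():
                classes[lab] = "nuisance"
        for col in self.interactions:
            for lab in self.interaction_labels(col):
                classes[lab] = "interaction"
        return classes

    # -- matrix construction -----------------------------------------------
    def fit_scaling(self, df: pd.DataFrame) -> "ModelMatrixSpec":
        for t in self.terms:
            t.fit_scaling(df)
        return self

    def _treatment_indicator(self, df: pd.DataFrame) -> np.ndarray:
        arm = df[self.treatment_col].astype(str).to_numpy()
        known = {self.treatment_level, self.treatment_reference}
        unknown = set(arm) - known
        if unknown:
            raise ValueError(f"unknown treatment arm labels {sorted(unknown)}")
        return (arm == self.treatment_level).astype(float)

    def build(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Design matrix and column labels for a complete cohort table."""
        n = len(df)
        trt = self._treatment_indicator(df)
        blocks = [np.ones((n, 1)), trt[:, None]]
        term_cols = {}
        for t in self.terms:
            term_cols[t.col] = t.transform(df)
            blocks.append(term_cols[t.col])
        for col in self.interactions:
            blocks.append(trt[:, None] * term_cols[col])
        X = np.hstack(blocks)
        return X, self.labels()

    def profile_frame(self, profile: dict, arm: str) -> pd.DataFrame:
        """One-row cohort table from a patient profile dict."""
        needed = {t.col for t in self.terms}
        missing = sorted(needed - set(profile))
        if missing:
            raise ValueError(f"profile lacks required covariates: {missing}")
        row = {k: [v] for k, v in profile.items() if k in needed}
        row[self.treatment_col] = [arm]
        return pd.DataFrame(row)

    def profile_row(self, profile: dict, arm: str) -> np.ndarray:
        X, _ = self.build(self.profile_frame(profile, arm))
        return X[0]

    def interaction_profile_values(self, profile: dict) -> dict[str, float]:
        """Interaction-column values at a profile (treatment set to 1).

        Maps each interaction coefficient label to the covariate value
        multiplying the treatment indicator for this profile, as needed
        for conditional treatment-effect summaries.
        """
        values: dict[str, float] = {}
        for col in self.interactions:
            t = self._term(col)
            if col not in profile:
                raise ValueError(f"profile lacks interacting covariate {col!r}")
            frame = pd.DataFrame({col: [profile[col]]})
            vals = t.transform(frame)[0]
            for lab, v in zip(self.interaction_labels(col), vals):
                values[lab] = float(v)
        return values

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "treatment_col": self.treatment_col,
            "treatment_level": self.treatment_level,
            "treatment_reference": self.treatment_reference,
            "interactions": list(self.interactions),
            "terms": [copy.deepcopy(vars(t)) for t in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelMatrixSpec":
        terms = []
        for td in d.get("terms", []):
            td = dict(td)
            for key in ("levels", "knots", "center", "scale"):
                td[key] = tuple(td.get(key) or ())
            terms.append(Term(**td))
        return cls(
            terms=terms,
            treatment_col=d.get("treatment_col", "arm"),
            treatment_level=d.get("treatment_level", "DPF"),
            treatment_reference=d.get("treatment_reference", "PF"),
            interactions=list(d.get("interactions", [])),
        )


def default_model_spec(
    cohort: pd.DataFrame,
    interactions: tuple = ("lauren",),
    age_knots: int = 3,
    covariates: tuple | None = None,
) -> ModelMatrixSpec:
    """The packaged confounder set, scaled to a (completed) cohort.

    Ten registry confounders: ECOG performance status, Lauren subtype,
    histological grade, ascites, stage, liver tumour burden, number of
    involved organs, platinum compound, log neutrophil/lymphocyte
    ratio, age (restricted cubic spline, 3 knots) and treatment year.
    ``interactions`` selects which covariates get treatment-interaction
    columns (any declared main-effect column).
    """
    catalog = {
        "ecog": Term("ecog", "categorical", reference="0", levels=("1", "2+")),
        "lauren": Term("lauren", "categorical", reference="diffuse", levels=("intestinal",)),
        "grade": Term("grade", "categorical", reference="1", levels=("2", "3")),
        "ascites": Term("ascites", "flag"),
        "stage": Term("stage", "categorical", reference="metastatic",
                      levels=("locally-advanced-unresectable",)),
        "liver_burden": Term("liver_burden", "categorical", reference="none",
                             levels=("<25%", "25-50%", "51-75%", ">75%")),
        "n_organs": Term("n_organs", "linear"),
        "platin": Term("platin", "categorical", reference="oxaliplatin",
                       levels=("cisplatin",)),
        "nlr": Term("nlr", "linear", log=True),
        "age": Term("age", "spline",
                    knots=default_knots(cohort["age"].to_numpy(dtype=float), age_knots)),
        "year": Term("year", "linear"),
    }
    if covariates is None:
        # respect upstream screening: only covariates the cohort still has
        covariates = tuple(c for c in catalog if c in cohort.columns)
    unknown = set(covariates) - set(catalog)
    if unknown:
        raise ValueError(f"no packaged term for covariates {sorted(unknown)}")
    spec = ModelMatrixSpec(
        terms=[catalog[c] for c in covariates],
        interactions=list(interactions),
    )
    spec.fit_scaling(cohort)
    return spec
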