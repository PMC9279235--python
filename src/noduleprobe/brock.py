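"""Brock (PanCan) malignancy-risk model and its feature-reduced variants.

The Brock model is a published logistic regression for the probability that
a screen-detected pulmonary nodule is malignant (McWilliams et al., NEJM
2013).  Predictors: age, sex, family history of lung cancer, emphysema,
nodule size, nodule type (part-solid), upper-lobe location, nodule count,
and spiculation.  Size enters through the transform
``-5.3854 * ((size_mm / 10) ** -0.5 - sqrt(10)/2)``, i.e. centred at 4 mm,
so risk is strictly increasing in size.

Feature-reduced variants drop terms from the published linear predictor
without refitting (risk ranking, and hence AUC, is what the variants are
evaluated on):

* ``full`` — every term, including spiculation.
* ``non_morphological`` — age, sex, family history, emphysema, upper-lobe
  location, nodule count.
* ``morphological_only`` — size, part-solid type, spiculation.
* ``no_spiculation`` — every term except spiculation.

An optional refit mode (:func:`refit_variant`) re-estimates a variant's
coefficients on a labelled cohort for sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BrockCoefficients",
    "VARIANTS",
    "VARIANT_TERMS",
    "RiskPrediction",
    "load_default_coefficients",
    "brock_linear_predictor",
    "brock_risk",
    "brock_scores_table",
    "refit_variant",
]

#: Predictor terms of the full-with-spiculation model.
ALL_TERMS = (
    "age",
    "sex",
    "family_history",
    "emphysema",
    "size",
    "upper_lobe",
    "part_solid",
    "nodule_count",
    "spiculation",
)

VARIANT_TERMS: dict[str, tuple[str, ...]] = {
    "full": ALL_TERMS,
    "non_morphological": ("age", "sex", "family_history", "emphysema", "upper_lobe", "nodule_count"),
    "morphological_only": ("size", "part_solid", "spiculation"),
    "no_spiculation": tuple(t for t in ALL_TERMS if t != "spiculation"),
}
VARIANTS = tuple(VARIANT_TERMS)


@dataclass(frozen=True)
class BrockCoefficients:
    """Coefficients (log-odds scale) of the full-with-spiculation Brock model."""

    intercept: float
    age_per_year: float
    age_center_years: float
    sex_female: float
    family_history: float
    emphysema: float
    size: float
    size_center: float
    upper_lobe: float
    part_solid: float
    nonsolid: float
    nodule_count_per_nodule: float
    nodule_count_center: float
    spiculation: float

    @classmethod
    def from_dict(cls, d: dict) -> "BrockCoefficients":
        fields = {k: float(d[k]) for k in cls.__dataclass_fields__}
        return cls(**fields)


def load_default_coefficients() -> BrockCoefficients:
    """The published full-model coefficients shipped with the package."""
    text = resources.files("noduleprobe.data").joinpath("brock_coefficients.json").read_text()
    return BrockCoefficients.from_dict(json.loads(text))


@dataclass(frozen=True)
class RiskPrediction:
    """A malignancy probability and the linear predictor it came from."""

    probability: float
    linear_predictor: float


def _term_values(cov, nod, size_mm: float, coef: BrockCoefficients) -> dict[str, float]:
    """Each predictor's contribution to the linear predictor."""
    age = float(getattr(cov, "age_years"))
    female = 1.0 if str(getattr(cov, "sex")) in ("female", "F", "f", "1") else 0.0
    count = float(getattr(cov, "nodule_count"))
    return {
        "age": coef.age_per_year * (age - coef.age_center_years),
        "sex": coef.sex_female * female,
        "family_history": coef.family_history * float(bool(getattr(cov, "family_history"))),
        "emphysema": coef.emphysema * float(bool(getattr(cov, "emphysema"))),
        "size": coef.size * ((size_mm / 10.0) ** -0.5 - coef.size_center),
        "upper_lobe": coef.upper_lobe * float(bool(getattr(nod, "upper_lobe"))),
        "part_solid": coef.part_solid * float(getattr(nod, "nodule_type") == "part_solid"),
        "nodule_count": coef.nodule_count_per_nodule * (count - coef.nodule_count_center),
        "spiculation": coef.spiculation * float(bool(getattr(nod, "spiculation"))),
    }


def brock_linear_predictor(cov, nod, size_mm: float, coef: BrockCoefficients | None = None,
                           variant: str = "full") -> float:
    """Intercept plus the variant's included terms; excluded terms contribute 0.

    ``cov`` needs attributes ``age_years, sex, family_history, emphysema,
    nodule_count``; ``nod`` needs ``upper_lobe, nodule_type, spiculation``.
    A warning is issued for sizes above 30 mm, outside the calculator's
    intended range.
    """
    if size_mm <= 0:
        raise ValueError(f"size_mm must be positive, got {size_mm}")
    if size_mm > 30.0:
        warnings.warn(
            "size exceeds 30 mm; the Brock calculator was not designed for masses > 30 mm",
            stacklevel=2,
        )
    if variant not in VARIANT_TERMS:
        raise KeyError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    coef = coef or load_default_coefficients()
    terms = _term_values(cov, nod, size_mm, coef)
    return float(coef.intercept + sum(terms[t] for t in VARIANT_TERMS[variant]))


def brock_risk(cov, nod, size_mm: float, coef: BrockCoefficients | None = None,
               variant: str = "full") -> RiskPrediction:
    """Malignancy probability ``1 / (1 + exp(-lp))`` for the chosen variant."""
    lp = brock_linear_predictor(cov, nod, size_mm, coef, variant)
    return RiskPrediction(probability=float(1.0 / (1.0 + np.exp(-lp))), linear_predictor=lp)


def brock_scores_table(cohort: pd.DataFrame, size_column: str,
                       coef: BrockCoefficients | None = None,
                       variant: str = "full") -> pd.DataFrame:
    """Batch scoring of a one-row-per-nodule cohort table.

    The table must carry the covariate columns ``age_years, sex,
    family_history, emphysema, nodule_count, upper_lobe, nodule_type,
    spiculation`` and the chosen size column (mm).  Returns a frame with
    ``participant_id, nodule_id, probability, linear_predictor, variant``.
    """
    coef = coef or load_default_coefficients()
    out = []
    for row in cohort.itertuples(index=False):
        pred = brock_risk(row, row, float(getattr(row, size_column)), coef, variant)
        out.append(
            {
                "participant_id": getattr(row, "participant_id", None),
                "nodule_id": getattr(row, "nodule_id", None),
                "probability": pred.probability,
                "linear_predictor": pred.linear_predictor,
                "variant": variant,
            }
        )
    return pd.DataFrame(out)


def refit_variant(cohort: pd.DataFrame, size_column: str, variant: str,
                  labels: Iterable[int] | None = None) -> pd.Series:
    """Re-estimate a variant's coefficients on a labelled cohort (sensitivity mode).

    Uses an unpenalised logistic fit on the variant's design matrix (same
    transforms and centerings as the published model).  Returns predicted
    probabilities aligned with ``cohort``; this is *not* the published
    model and exists only to check that conclusions do not hinge on the
    drop-terms-without-refit convention.
    """
    import sklearn.linear_model as lm

    coef = load_default_coefficients()
    rows = [_term_values(r, r, float(getattr(r, size_column)), coef) for r in cohort.itertuples(index=False)]
    design = pd.DataFrame(rows)[list(VARIANT_TERMS[variant])]
    y = np.asarray(labels if labels is not None else cohort["malignant"], dtype=int)
    model = lm.LogisticRegression(C=1e6, max_iter=2000)
    model.fit(design.to_numpy(), y)
    probs = model.predict_proba(design.to_numpy())[:, 1]
    return pd.Series(probs, index=cohort.index, name=f"refit_{variant}")
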