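"""Stratified-median age-confound correction.

When case and control groups differ strongly in age, any metabolite with an
age trend separates the groups for reasons unrelated to disease.  The
correction implemented here removes that trend using the control group as the
reference population:

1. take the control subjects and bin them into fixed-width age strata
   (default 5 years, anchored at multiples of the width);
2. compute the median concentration of each metabolite within each stratum;
3. fit an ordinary least-squares line through the (stratum midpoint age,
   stratum median) points;
4. for every subject, evaluate the fitted line's delta relative to a
   reference age: ``delta = slope * (age - reference_age)``;
5. subtract that delta from the subject's absolute concentration.

The correction is estimated on controls only but applied to all subjects.  It
is a location shift at fixed age, so within-stratum variances are untouched.
Adjusted values may be negative; they are kept (the output is a statistical
transform, not a concentration estimate) unless ``clip_at_zero`` is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CONTROL, metabolite_columns

logger = logging.getLogger(__name__)

DEFAULT_STRATUM_WIDTH = 5.0
DEFAULT_MIN_STRATUM_SIZE = 2


@dataclass(frozen=True)
class AgeStratum:
    low: float                 # inclusive
    high: float                # exclusive
    member_ids: tuple[str, ...]

    @property
    def representative_age(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class AgeCorrectionModel:
    """Per-metabolite linear coefficients fitted on control stratum medians.

    ``coefficients`` has one row per metabolite with columns
    ``slope, intercept, r2, n_strata`` (slope in concentration units per
    year).  Metabolites with fewer than two usable strata get a null (NaN)
    slope and pass through correction unchanged.
    """

    coefficients: pd.DataFrame
    reference_age: float
    stratum_width: float = DEFAULT_STRATUM_WIDTH
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE
    warnings_: list[str] = field(default_factory=list)

    def delta(self, metabolite: str, age: float | np.ndarray) -> float | np.ndarray:
        """Age-associated concentration delta: ``slope * (age - reference_age)``."""
        if metabolite not in self.coefficients.index:
            raise KeyError(f"metabolite {metabolite!r} not in model")
        slope = self.coefficients.loc[metabolite, "slope"]
        if np.isnan(slope):
            return np.zeros_like(np.asarray(age, dtype=float)) if np.ndim(age) else 0.0
        return slope * (np.asarray(age, dtype=float) - self.reference_age)

    def to_frame(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out.index.name = "metabolite"
        return out.reset_index()


def stratify_by_age(
    table: pd.DataFrame,
    width: float = DEFAULT_STRATUM_WIDTH,
    offset: float = 0.0,
) -> list[AgeStratum]:
    """Bin control subjects into fixed-width age strata.

    Strata are anchored at multiples of ``width`` from ``offset`` (so with the
    default 5-year width, bins are [25, 30), [30, 35), ...).  Empty strata are
    omitted; each control falls in exactly one stratum.
    """
    if width <= 0:
        raise ValueError("stratum width must be positive")
    controls = table[table["group"] == CONTROL]
    if controls.empty:
        raise ValueError("no control subjects to stratify")
    bin_index = np.floor((controls["age"].to_numpy() - offset) / width).astype(int)
    strata = []
    for b in sorted(set(bin_index)):
        ids = controls.loc[bin_index == b, "subject_id"]
        strata.append(
            AgeStratum(low=offset + b * width, high=offset + (b + 1) * width,
                       member_ids=tuple(ids))
        )
    return strata


def stratum_medians(
    strata: list[AgeStratum],
    table: pd.DataFrame,
    metabolite: str,
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
) -> list[tuple[float, float]]:
    """(representative age, median concentration) per sufficiently large stratum.

    Strata smaller than ``min_stratum_size`` are dropped with a logged
    warning; raises if nothing is left.
    """
    values = table.set_index("subject_id")[metabolite]
    points = []
    for s in strata:
        if s.size < min_stratum_size:
            logger.warning(
                "dropping stratum [%g, %g) for %s: %d member(s) < min size %d",
                s.low, s.high, metabolite, s.size, min_stratum_size,
            )
            continue
        points.append((s.representative_age, float(values.loc[list(s.member_ids)].median())))
    if not points:
        raise ValueError(f"all strata dropped for {metabolite!r}")
    return points


def fit_age_model(
    points: list[tuple[float, float]],
    reference_age: float,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """OLS line through stratum-median points -> (slope, intercept, r2).

    Each point has weight 1 by default (the literal algorithm); ``weights``
    (e.g. stratum sizes) switches to weighted least squares.  Returns NaN
    slope (null fit) when fewer than two points with distinct ages are
    available; callers treat a null slope as "no correction".
    """
    ages = np.array([p[0] for p in points], dtype=float)
    meds = np.array([p[1] for p in points], dtype=float)
    if len(points) < 2 or np.ptp(ages) == 0:
        logger.warning("cannot fit age model on %d point(s); null slope", len(points))
        return float("nan"), float("nan"), float("nan")
    if np.ptp(meds) == 0:  # perfectly flat: slope 0, r2 undefined -> 1 by convention
        return 0.0, float(meds[0]), 1.0
    if weights is None:
        res = stats.linregress(ages, meds)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)
    w = np.asarray(weights, dtype=float)
    mx, my = np.average(ages, weights=w), np.average(meds, weights=w)
    cov = np.average((ages - mx) * (meds - my), weights=w)
    var = np.average((ages - mx) ** 2, weights=w)
    slope = cov / var
    intercept = my - slope * mx
    ss_res = np.average((meds - intercept - slope * ages) ** 2, weights=w)
    ss_tot = np.average((meds - my) ** 2, weights=w)
    return float(slope), float(intercept), float(1.0 - ss_res / ss_tot)


def fit_age_correction(
    table: pd.DataFrame,
    stratum_width: float = DEFAULT_STRATUM_WIDTH,
    reference_age: float | str = "auto",
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
    offset: float = 0.0,
    weight_by_size: bool = False,
) -> AgeCorrectionModel:
    """Fit the full per-metabolite correction model on the control group.

    ``reference_age="auto"`` anchors the correction at the control group's
    median age rounded to the nearest year, so corrected values stay centred
    on the reference population.  ``weight_by_size`` weights each stratum's
    point by its membership count instead of equally (off by default: the
    literal algorithm treats strata as equal observations).
    """
    controls = table[table["group"] == CONTROL]
    if controls.empty:
        raise ValueError("no control subjects; cannot fit age correction")
    if reference_age == "auto":
        reference_age = float(round(controls["age"].median()))
    strata = stratify_by_age(table, width=stratum_width, offset=offset)
    sizes = {s.representative_age: s.size for s in strata}

    rows, warns = {}, []
    for m in metabolite_columns(table):
        try:
            pts = stratum_medians(strata, controls, m, min_stratum_size)
        except ValueError:
            warns.append(f"{m}: all strata below min size; left uncorrected")
            rows[m] = (np.nan, np.nan, np.nan, 0)
            continue
        w = np.array([sizes[a] for a, _ in pts]) if weight_by_size else None
        slope, intercept, r2 = fit_age_model(pts, reference_age, weights=w)
        if np.isnan(slope):
            warns.append(f"{m}: <2 usable strata; left uncorrected")
        rows[m] = (slope, intercept, r2, len(pts))

    coef = pd.DataFrame.from_dict(
        rows, orient="index", columns=["slope", "intercept", "r2", "n_strata"]
    )
    coef["n_strata"] = coef["n_strata"].astype(int)
    for w in warns:
        logger.warning("%s", w)
    return AgeCorrectionModel(
        coefficients=coef,
        reference_age=float(reference_age),
        stratum_width=stratum_width,
        min_stratum_size=min_stratum_size,
        warnings_=warns,
    )


def age_delta(model: AgeCorrectionModel, metabolite: str, age: float) -> float:
    """Delta to subtract for one metabolite at one age (0 at the reference age)."""
    return float(model.delta(metabolite, age))


def apply_correction(
    table: pd.DataFrame, model: AgeCorrectionModel, clip_at_zero: bool = False
) -> pd.DataFrame:
    """Subtract each subject's age delta from every metabolite, both groups.

    The input table is left untouched.  Metabolites with a null slope pass
    through unchanged.  Negative adjusted values are kept by default and
    counted in the log; ``clip_at_zero`` floors them at 0 for consumers that
    need positivity.
    """
    mets = metabolite_columns(table)
    missing = [m for m in mets if m not in model.coefficients.index]
    if missing:
        raise KeyError(f"model lacks coefficients for: {missing[:5]}...")
    out = table.copy()
    ages = table["age"].to_numpy(dtype=float)
    n_negative = 0
    for m in mets:
        slope = model.coefficients.loc[m, "slope"]
        if np.isnan(slope):
            continue
        adjusted = table[m].to_numpy(dtype=float) - slope * (ages - model.reference_age)
        n_negative += int((adjusted < 0).sum())
        if clip_at_zero:
            adjusted = np.maximum(adjusted, 0.0)
        out[m] = adjusted
    if n_negative:
        logger.info("age correction produced %d negative adjusted value(s)", n_negative)
    return out


__all__ = [
    "AgeStratum",
    "AgeCorrectionModel",
    "stratify_by_age",
    "stratum_medians",
    "fit_age_model",
    "fit_age_correction",
    "age_delta",
    "apply_correction",
]
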