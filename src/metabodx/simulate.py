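"""Synthetic case-control cohort generator.

Generates wide concentration tables (subjects x metabolites) with known linear
age trends, multiplicative log-normal noise and configurable case/control
effects, so that age correction, univariate screening and the classifier stage
can all be tested against ground truth.

Generative model for metabolite ``m`` of subject ``i``::

    conc = max(eps, (baseline_m + age_slope_m * (age_i - reference_age))
                    * 2**(group_log2_effect_m * affected)
                    * noise)

where ``affected`` is 1 for case subjects when ``m`` is in the configured
affected set, and ``noise`` is log-normal with median 1 and coefficient of
variation ``noise_cv`` (sigma = sqrt(ln(1 + cv^2))).  With median-1 noise the
conditional median of a concentration sits exactly on the age line, which is
the quantity the stratified-median age correction estimates.

Ages are drawn from a normal distribution matched to the target (median,
[Q1, Q3]) summary — mean = median, sd = IQR/1.349 — truncated to [18, 95].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .panel import _PANEL, CLASS_LABELS, CONSENSUS_SIGNATURE, panel_class_map

logger = logging.getLogger(__name__)

#: floor preventing non-positive concentrations under steep negative trends
EPSILON = 1e-9

#: default age at which the generative age trend contributes nothing
DEFAULT_REFERENCE_AGE = 40.0

AGE_BOUNDS = (18.0, 95.0)
IQR_TO_SD = 1.349  # Q3 - Q1 of a normal in units of sigma

META_COLUMNS = ["subject_id", "group", "age", "sex"]
CONTROL, CASE = "control", "case"


@dataclass(frozen=True)
class MetaboliteSpec:
    """Ground-truth generative parameters for one metabolite."""

    name: str
    class_label: str
    baseline: float          # concentration at the reference age, µmol/L
    age_slope: float = 0.0   # µmol/L per year
    group_log2_effect: float = 0.0  # log2 fold change applied to cases
    noise_cv: float = 0.2    # CV of multiplicative log-normal noise

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"{self.name}: baseline must be positive")
        if self.noise_cv <= 0:
            raise ValueError(f"{self.name}: noise_cv must be positive")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"{self.name}: unknown class {self.class_label!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Sampling configuration for one synthetic cohort."""

    n_control: int = 36
    n_case: int = 76
    control_age_dist: tuple[float, float, float] = (34.0, 26.0, 44.0)  # median, Q1, Q3
    case_age_dist: tuple[float, float, float] = (64.0, 58.0, 71.0)
    seed: int = 0
    affected_metabolites: frozenset[str] = field(
        default_factory=lambda: frozenset(CONSENSUS_SIGNATURE)
    )
    reference_age: float = DEFAULT_REFERENCE_AGE

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("group sizes must be positive")
        for dist in (self.control_age_dist, self.case_age_dist):
            med, lo, hi = dist
            if not (lo <= med <= hi):
                raise ValueError(f"age summary must satisfy Q1 <= median <= Q3: {dist}")
        # rough stratum occupancy check: controls spread over ~2 IQRs of 5y bins
        _, lo, hi = self.control_age_dist
        approx_strata = max(1.0, 2.0 * (hi - lo) / 5.0)
        if self.n_control / approx_strata < 2:
            warnings.warn(
                f"n_control={self.n_control} averages fewer than 2 subjects per "
                "5-year age stratum; stratified-median fits will be unstable",
                stacklevel=2,
            )
        object.__setattr__(self, "affected_metabolites", frozenset(self.affected_metabolites))


@dataclass(frozen=True)
class GroundTruth:
    """The panel and configuration that produced a generated table."""

    panel: tuple[MetaboliteSpec, ...]
    config: CohortConfig

    def to_dict(self) -> dict:
        d = {"panel": [asdict(s) for s in self.panel], "config": asdict(self.config)}
        d["config"]["affected_metabolites"] = sorted(self.config.affected_metabolites)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        cfg = dict(d["config"])
        cfg["control_age_dist"] = tuple(cfg["control_age_dist"])
        cfg["case_age_dist"] = tuple(cfg["case_age_dist"])
        cfg["affected_metabolites"] = frozenset(cfg["affected_metabolites"])
        return cls(
            panel=tuple(MetaboliteSpec(**s) for s in d["panel"]),
            config=CohortConfig(**cfg),
        )


def build_default_panel(noise_cv: float = 0.2) -> list[MetaboliteSpec]:
    """The default 87-analyte targeted panel with its generative ground truth.

    Age slopes in the source table are stored as fractions of baseline per
    year and converted to absolute units here.
    """
    specs = [
        MetaboliteSpec(
            name=name,
            class_label=cls,
            baseline=baseline,
            age_slope=baseline * slope_frac,
            group_log2_effect=effect,
            noise_cv=noise_cv,
        )
        for name, cls, baseline, slope_frac, effect in _PANEL
    ]
    names = [s.name for s in specs]
    assert len(names) == len(set(names)), "panel names must be unique"
    return specs


def sample_ages(
    group_dist: tuple[float, float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` ages from a truncated normal matched to (median, Q1, Q3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    med, q1, q3 = group_dist
    sd = max((q3 - q1) / IQR_TO_SD, 1e-6)
    lo, hi = AGE_BOUNDS
    a, b = (lo - med) / sd, (hi - med) / sd
    return stats.truncnorm.rvs(a, b, loc=med, scale=sd, size=n, random_state=rng)


def generate_cohort(
    config: CohortConfig, panel: list[MetaboliteSpec] | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a concentration table and the ground truth behind it.

    Returns a wide DataFrame with columns ``subject_id, group, age, sex`` then
    one numeric column per panel metabolite, and the :class:`GroundTruth`
    capturing every generative parameter.  Deterministic given ``config.seed``.
    """
    if panel is None:
        panel = build_default_panel()
    if not panel:
        raise ValueError("panel must not be empty")
    names = [s.name for s in panel]
    if len(names) != len(set(names)):
        raise ValueError("panel names must be unique")

    rng = np.random.default_rng(config.seed)
    ages_ctrl = sample_ages(config.control_age_dist, config.n_control, rng)
    ages_case = sample_ages(config.case_age_dist, config.n_case, rng)
    ages = np.concatenate([ages_ctrl, ages_case])
    n = config.n_control + config.n_case
    is_case = np.concatenate(
        [np.zeros(config.n_control, dtype=bool), np.ones(config.n_case, dtype=bool)]
    )
    sex = rng.choice(["m", "f"], size=n, p=[0.8, 0.2])  # assay cohorts skew male

    cols: dict[str, np.ndarray] = {}
    for spec in panel:
        mean = spec.baseline + spec.age_slope * (ages - config.reference_age)
        if spec.name in config.affected_metabolites:
            mean = mean * np.power(2.0, spec.group_log2_effect * is_case)
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=0.0, sigma=sigma, size=n)  # median-1 noise
        cols[spec.name] = np.maximum(EPSILON, mean * noise)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": np.where(is_case, CASE, CONTROL),
            "age": ages,
            "sex": sex,
            **cols,
        }
    )
    return df, GroundTruth(panel=tuple(panel), config=config)


def cohort_flow_filter(enrolled: int, **exclusions: int) -> int:
    """Final group size after subtracting named exclusion counts.

    >>> cohort_flow_filter(84, diet=5, alcohol=3)
    76
    """
    if enrolled < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("counts must be non-negative")
    total_excluded = sum(exclusions.values())
    if total_excluded > enrolled:
        raise ValueError(
            f"exclusions ({total_excluded}) exceed enrolled ({enrolled})"
        )
    return enrolled - total_excluded


def metabolite_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a concentration table that hold metabolite values."""
    return [c for c in table.columns if c not in META_COLUMNS]


__all__ = [
    "MetaboliteSpec",
    "CohortConfig",
    "GroundTruth",
    "build_default_panel",
    "sample_ages",
    "generate_cohort",
    "cohort_flow_filter",
    "metabolite_columns",
    "panel_class_map",
    "CONSENSUS_SIGNATURE",
    "META_COLUMNS",
    "CONTROL",
    "CASE",
    "EPSILON",
    "DEFAULT_REFERENCE_AGE",
]
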