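"""Per-metabolite case-control screening statistics.

For every metabolite (and derived ratio) the screen reports a two-sided
p-value from a normality-routed test (Student t when both groups pass
Shapiro–Wilk, Mann–Whitney U otherwise), the direction of change in cases, a
rank-based ROC AUC, the Youden statistic from an exhaustive cutoff scan, and
the median-based log2 fold change.  A metabolite passes the significance
filter when p < 0.05 and AUC > 0.65 (both thresholds configurable).

AUC is reported direction-agnostically as max(a, 1 - a) >= 0.5 — the
direction column carries the orientation.  Alongside the classical Youden
index J = sensitivity + specificity - 1 the screen also reports
sensitivity + specificity itself (J + 1), the form some clinical reports
print on a 1–2 scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .simulate import CASE, metabolite_columns

logger = logging.getLogger(__name__)

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"
INCREASED, DECREASED, UNCHANGED = "increased", "decreased", "unchanged"

DEFAULT_P_THRESH = 0.05
DEFAULT_AUC_THRESH = 0.65


@dataclass(frozen=True)
class RatioDefinition:
    """A derived concentration ratio: sum(numerator) / sum(denominator)."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]


#: (Val + Ile + Leu) / (Phe + Tyr): branched-chain over aromatic amino acids
FISHER_RATIO = RatioDefinition(
    "Fisher ratio",
    ("Valine", "Isoleucine", "Leucine"),
    ("Phenylalanine", "Tyrosine"),
)
#: Glu / (Ser + Gly): glutathione-synthesis amino-acid ratio
GSG_RATIO = RatioDefinition("GSG ratio", ("Glutamate",), ("Serine", "Glycine"))

DEFAULT_RATIOS = (FISHER_RATIO, GSG_RATIO)


@dataclass(frozen=True)
class UnivariateResult:
    metabolite: str
    class_label: str
    test_used: str
    p_value: float
    direction: str
    auc: float
    youden_j: float
    sens_plus_spec: float
    optimal_cutoff: float
    log2fc: float
    passes_filter: bool

    def to_dict(self) -> dict:
        return asdict(self)


def normality_route(
    control_values: np.ndarray, case_values: np.ndarray, alpha: float = 0.05
) -> str:
    """Choose the comparison test: t-test iff both groups look normal.

    Shapiro–Wilk at ``alpha`` in each group; groups with fewer than 3 values
    or zero variance cannot be assessed and route to Mann–Whitney with a
    warning.
    """
    for vals in (control_values, case_values):
        v = np.asarray(vals, dtype=float)
        if len(v) < 3 or np.ptp(v) == 0:
            logger.warning("group too small/degenerate for normality check; using Mann-Whitney")
            return MANN_WHITNEY
        if stats.shapiro(v).pvalue < alpha:
            return MANN_WHITNEY
    return T_TEST


def compare_groups(
    control_values: np.ndarray, case_values: np.ndarray, route: str
) -> tuple[float, str]:
    """Two-sided group comparison -> (p-value, direction of change in cases)."""
    ctrl = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    med_c, med_k = np.median(ctrl), np.median(case)
    if med_k > med_c:
        direction = INCREASED
    elif med_k < med_c:
        direction = DECREASED
    else:
        direction = UNCHANGED
    pooled = np.concatenate([ctrl, case])
    if np.ptp(pooled) == 0:  # identical constant groups
        return 1.0, UNCHANGED
    if route == T_TEST:
        p = stats.ttest_ind(ctrl, case).pvalue
    elif route == MANN_WHITNEY:
        p = stats.mannwhitneyu(ctrl, case, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test route {route!r}")
    return float(p), direction


def rank_auc(control_values: np.ndarray, case_values: np.ndarray) -> float:
    """Rank-based ROC AUC with midrank tie handling, oriented >= 0.5.

    AUC = U / (n1 * n2) where U is the Mann–Whitney statistic of the case
    group; equals the probability that a random case exceeds a random
    control (ties counted 1/2), folded to max(a, 1 - a).
    """
    ctrl = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    if len(ctrl) == 0 or len(case) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([ctrl, case])
    ranks = stats.rankdata(pooled)
    u_case = ranks[len(ctrl):].sum() - len(case) * (len(case) + 1) / 2.0
    a = u_case / (len(ctrl) * len(case))
    return float(max(a, 1.0 - a))


def youden(
    control_values: np.ndarray, case_values: np.ndarray
) -> tuple[float, float, float]:
    """Best Youden statistic over all empirical cutoffs.

    Scans midpoints between adjacent sorted unique pooled values (plus open
    cutoffs below and above the data) in both orientations and returns
    ``(J, J + 1, cutoff)`` with J = max(sensitivity + specificity - 1).  Ties
    in J are broken toward the cutoff with higher specificity.
    """
    ctrl = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    if len(ctrl) == 0 or len(case) == 0:
        raise ValueError("both groups must be non-empty")
    uniq = np.unique(np.concatenate([ctrl, case]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    cutoffs = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])

    best = (-np.inf, -np.inf, np.nan)  # (J, specificity, cutoff)
    for c in cutoffs:
        for positive_above in (True, False):
            if positive_above:
                sens = float((case > c).mean())
                spec = float((ctrl <= c).mean())
            else:
                sens = float((case < c).mean())
                spec = float((ctrl >= c).mean())
            j = sens + spec - 1.0
            if (j, spec) > (best[0], best[1]):
                best = (j, spec, float(c))
    j = max(best[0], 0.0)
    return j, j + 1.0, best[2]


def derive_ratios(
    table: pd.DataFrame, definitions: tuple[RatioDefinition, ...] = DEFAULT_RATIOS
) -> pd.DataFrame:
    """Append one column per ratio definition; non-positive denominators -> NaN."""
    out = table.copy()
    for d in definitions:
        missing = [m for m in (*d.numerator, *d.denominator) if m not in table.columns]
        if missing:
            raise KeyError(f"ratio {d.name!r} needs missing columns: {missing}")
        num = table[list(d.numerator)].sum(axis=1)
        den = table[list(d.denominator)].sum(axis=1)
        bad = den <= 0
        if bad.any():
            logger.warning(
                "ratio %s: %d subject(s) with non-positive denominator set to NaN",
                d.name, int(bad.sum()),
            )
        out[d.name] = np.where(bad, np.nan, num / den.where(~bad, np.nan))
    return out


def log2fc(control_values: np.ndarray, case_values: np.ndarray) -> float:
    """log2 of (case median / control median); NaN when a median is non-positive."""
    med_c = float(np.median(np.asarray(control_values, dtype=float)))
    med_k = float(np.median(np.asarray(case_values, dtype=float)))
    if med_c <= 0 or med_k <= 0:
        logger.warning("non-positive group median; log2FC undefined")
        return float("nan")
    return float(np.log2(med_k / med_c))


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] by (x - min)/(max - min); constant input -> zeros."""
    v = np.asarray(values, dtype=float)
    rng = np.ptp(v)
    if rng == 0:
        warnings.warn("constant column in min-max normalization; returning zeros",
                      stacklevel=2)
        return np.zeros_like(v)
    return (v - v.min()) / rng


def screen(
    table: pd.DataFrame,
    p_thresh: float = DEFAULT_P_THRESH,
    auc_thresh: float = DEFAULT_AUC_THRESH,
    class_map: dict[str, str] | None = None,
    raw_table: pd.DataFrame | None = None,
    bh_adjust: bool = False,
) -> list[UnivariateResult]:
    """Screen every metabolite column of a (typically age-adjusted) table.

    ``raw_table`` optionally supplies the pre-correction concentrations used
    for log2 fold changes (fold changes on the adjusted scale can be distorted
    by negative values); defaults to ``table`` itself.  ``bh_adjust`` applies
    Benjamini–Hochberg to the p-values before filtering (off by default: the
    screen reports raw per-metabolite p-values).  Results are sorted by class
    label then p-value.
    """
    mets = metabolite_columns(table)
    if not mets:
        raise ValueError("table has no metabolite columns")
    class_map = class_map or {}
    fc_source = raw_table if raw_table is not None else table
    is_case = (table["group"] == CASE).to_numpy()

    results, pvals = [], []
    for m in mets:
        vals = table[m].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        ctrl, case = vals[ok & ~is_case], vals[ok & is_case]
        route = normality_route(ctrl, case)
        p, direction = compare_groups(ctrl, case, route)
        a = rank_auc(ctrl, case)
        j, sps, cutoff = youden(ctrl, case)
        fc_vals = fc_source[m].to_numpy(dtype=float) if m in fc_source else vals
        fc_ok = ~np.isnan(fc_vals)
        fc = log2fc(fc_vals[fc_ok & ~is_case], fc_vals[fc_ok & is_case])
        pvals.append(p)
        results.append(
            UnivariateResult(
                metabolite=m,
                class_label=class_map.get(m, "ratio" if " ratio" in m else "other"),
                test_used=route,
                p_value=p,
                direction=direction,
                auc=a,
                youden_j=j,
                sens_plus_spec=sps,
                optimal_cutoff=cutoff,
                log2fc=fc,
                passes_filter=False,
            )
        )

    eff_p = _bh(np.array(pvals)) if bh_adjust else np.array(pvals)
    results = [
        UnivariateResult(**{**r.to_dict(),
                            "p_value": float(pe),
                            "passes_filter": bool(pe < p_thresh and r.auc > auc_thresh)})
        for r, pe in zip(results, eff_p)
    ]
    results.sort(key=lambda r: (r.class_label, r.p_value))
    return results


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def results_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    """Tabular view of screen results (one row per metabolite/ratio)."""
    return pd.DataFrame([r.to_dict() for r in results])


def pca_overview(
    table: pd.DataFrame, outlier_quantile: float = 0.99
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardized 2-component PCA of the metabolite matrix + outlier flags.

    Columns are z-scored first (concentration scales span orders of
    magnitude).  Subjects whose Mahalanobis distance in score space exceeds
    the chi-square quantile ``outlier_quantile`` (2 df) are flagged — never
    removed.  Constant columns are dropped with a warning; if fewer than two
    informative columns remain, no scores are computed and nothing is flagged.
    """
    mets = metabolite_columns(table)
    if len(table) < 3:
        raise ValueError("PCA overview needs at least 3 subjects")
    X = table[mets].to_numpy(dtype=float)
    keep = np.ptp(X, axis=0) > 0
    if keep.sum() < 2:
        warnings.warn("degenerate concentration matrix; PCA skipped", stacklevel=2)
        scores = pd.DataFrame(
            {"subject_id": table["subject_id"], "pc1": 0.0, "pc2": 0.0,
             "outlier": False}
        )
        return scores, np.zeros(len(table), dtype=bool)
    Z = StandardScaler().fit_transform(X[:, keep])
    pcs = PCA(n_components=2, random_state=0).fit_transform(Z)
    cov = np.cov(pcs, rowvar=False)
    try:
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ij,jk,ik->i", pcs, inv, pcs)
        flags = d2 > stats.chi2.ppf(outlier_quantile, df=2)
    except np.linalg.LinAlgError:
        warnings.warn("singular PC covariance; no outliers flagged", stacklevel=2)
        flags = np.zeros(len(table), dtype=bool)
    scores = pd.DataFrame(
        {"subject_id": table["subject_id"], "group": table["group"],
         "pc1": pcs[:, 0], "pc2": pcs[:, 1], "outlier": flags}
    )
    return scores, flags


__all__ = [
    "RatioDefinition",
    "UnivariateResult",
    "FISHER_RATIO",
    "GSG_RATIO",
    "DEFAULT_RATIOS",
    "normality_route",
    "compare_groups",
    "rank_auc",
    "youden",
    "derive_ratios",
    "log2fc",
    "minmax_normalize",
    "screen",
    "results_frame",
    "pca_overview",
    "T_TEST",
    "MANN_WHITNEY",
    "INCREASED",
    "DECREASED",
    "UNCHANGED",
]
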