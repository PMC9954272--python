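"""Screening analysis pipeline: group comparison, step-up feature
selection, single-marker and combined ROC/AUC, and the basic-education
subgroup analysis.

Statistical conventions:

* Continuous variables are summarized as median [P25, P75] and compared
  between the two groups with the tie-corrected Kruskal–Wallis H rank-sum
  test (chi-square reference, df = 1; for two groups this coincides with
  the Wilcoxon/Mann–Whitney rank-sum test up to the reference law).
* Dichotomous variables use the Pearson chi-square test without continuity
  correction (switchable).
* No multiple-testing correction is applied; the report records the number
  of tests performed. p < 0.05 is the nominal significance level.
* ROC scores are oriented so a higher score indicates the impaired group:
  markers whose MCI median exceeds the NC median enter as-is, others (MMSE
  in particular) are negated. AUC is the trapezoidal area, identical to the
  midrank Mann–Whitney estimator.
* Dimension reduction is pure step-up (forward) selection on a logistic
  model of group membership: at each step the candidate with the smallest
  likelihood-ratio entry p-value joins if p < 0.05. Perfect separation is
  handled by a ridge-stabilized refit and flagged on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

BIOMARKERS = (
    "metr_total",
    "med_total_px",
    "met_first_s",
    "mee_first",
    "et_crossing_s",
    "ed_crossing_px",
    "et_above_s",
    "ed_above_px",
)

ENTRY_P = 0.05


# --------------------------------------------------------------------------
# Elementary tests
# --------------------------------------------------------------------------

def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-group Kruskal–Wallis H rank-sum test (tie-corrected, df=1).

    Returns (H, p). Degenerate input with every pooled value identical
    gives (0, 1) by convention. Invariant under strictly monotone
    transforms of the pooled values.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: every pooled value identical
        return 0.0, 1.0
    h, p = sps.kruskal(x, y)
    return float(h), float(p)


def chi_square_2x2(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, no Yates correction
    by default. A zero marginal makes the statistic undefined: (nan, nan).
    """
    table = np.asarray(counts, float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan, math.nan
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    """Empirical ROC curve and its area for one marker (or combination)."""

    label: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "auc": self.auc,
        }


def roc_auc(scores, labels, label: str = "") -> RocResult:
    """Empirical ROC over all thresholds; AUC by trapezoid (= midrank
    Mann–Whitney estimator). ``labels`` are 1/True for MCI; higher scores
    must indicate MCI (orientation is the caller's contract).
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return RocResult(label, fpr, tpr, thr, float(roc_auc_score(y, s)))


def orient_scores(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Orient a marker so higher oriented score indicates the MCI group.

    Markers elevated in MCI (median) pass through (+1); markers reduced in
    MCI, such as MMSE, are negated (-1). Returns (oriented, sign)."""
    v = np.asarray(values, float)
    y = np.asarray(labels).astype(bool)
    sign = 1 if np.nanmedian(v[y]) >= np.nanmedian(v[~y]) else -1
    return sign * v, sign


# --------------------------------------------------------------------------
# Logistic fits and step-up selection
# --------------------------------------------------------------------------

@dataclass
class _Fit:
    llf: float
    params: np.ndarray
    ridged: bool


def _fit_logit(X: np.ndarray, y: np.ndarray) -> _Fit:
    """Logistic MLE; falls back to a ridge-stabilized fit under (quasi-)
    separation, evaluating the unpenalized log-likelihood at the ridge
    solution."""
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
        if np.isfinite(res.llf) and np.abs(res.params).max() < 1e3:
            return _Fit(float(res.llf), np.asarray(res.params), False)
    except Exception:
        pass
    ridge = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
        alpha=1e-4, L1_wt=0.0)
    params = np.asarray(ridge.params)
    return _Fit(float(model.loglike(params)), params, True)


def _lrt_p(ll_full: float, ll_null: float, df: int = 1) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_null))
    return float(sps.chi2.sf(stat, df))


@dataclass
class SelectionResult:
    """Outcome of step-up selection: retained names in entry order, the
    entry p-value of each, the per-step candidate p-value trace, final
    coefficients (direction only is interpreted) and a separation flag."""

    selected: list[str] = field(default_factory=list)
    entry_pvalues: list[float] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)
    coefficients: dict[str, float] = field(default_factory=dict)
    separation_flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "entry_pvalues": self.entry_pvalues,
            "steps": self.steps,
            "coefficients": self.coefficients,
            "separation_flagged": self.separation_flagged,
        }


def _design(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    return df[list(cols)].to_numpy(float)


def stepup_select(
    cohort: pd.DataFrame,
    candidates: Sequence[str] = BIOMARKERS,
    entry_p: float = ENTRY_P,
    familywise: bool = True,
) -> SelectionResult:
    """Forward (step-up) logistic selection of screening markers.

    Complete-case rows only. At each step every remaining candidate is
    offered to the current model; the one with the smallest likelihood-
    ratio entry p-value is added if it clears the entry threshold, else
    selection stops. No removal step.

    With ``familywise`` (default) the per-step threshold is Bonferroni-
    adjusted to ``entry_p / m`` over the m remaining candidates, holding
    the chance of any spurious entry per step at ~``entry_p`` regardless
    of how many markers compete (a flat per-candidate 0.05 would admit a
    noise marker in roughly 1 - 0.95^m ~ 30% of steps with m=8).
    ``familywise=False`` restores the flat threshold.
    """
    data = cohort.dropna(subset=list(candidates))
    y = (data["group"] == "MCI").to_numpy(int)
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    result = SelectionResult()
    remaining = list(candidates)
    null_fit = _fit_logit(np.empty((len(y), 0)), y)
    current_ll = null_fit.llf
    while remaining:
        trace = {}
        best: Optional[tuple[float, str, _Fit]] = None
        for cand in remaining:
            fit = _fit_logit(_design(data, result.selected + [cand]), y)
            p = _lrt_p(fit.llf, current_ll)
            trace[cand] = p
            if best is None or p < best[0]:
                best = (p, cand, fit)
        result.steps.append(trace)
        p, cand, fit = best
        threshold = entry_p / len(remaining) if familywise else entry_p
        if p >= threshold:
            break
        result.selected.append(cand)
        result.entry_pvalues.append(p)
        result.separation_flagged |= fit.ridged
        current_ll = fit.llf
        remaining.remove(cand)
        result.coefficients = dict(zip(["const"] + result.selected, fit.params))
    return result


def fit_combination(cohort: pd.DataFrame, selected: Sequence[str]) -> pd.Series:
    """Logistic linear predictor over the selected markers, usable directly
    as the ROC score of the combination."""
    if not selected:
        raise ValueError("at least one selected variable required")
    data = cohort.dropna(subset=list(selected))
    y = (data["group"] == "MCI").to_numpy(int)
    fit = _fit_logit(_design(data, selected), y)
    Xc = sm.add_constant(_design(data, selected), has_constant="add")
    return pd.Series(Xc @ fit.params, index=data.index, name="combination")


def filter_basic_education(cohort: pd.DataFrame, min_years: float = 9) -> pd.DataFrame:
    """Basic-education subgroup: strictly more than ``min_years`` of
    schooling (9-year compulsory education)."""
    return cohort[cohort["education_years"] > min_years]


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

@dataclass
class ComparisonRow:
    variable: str
    test: str
    nc_summary: str
    mci_summary: str
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ScreeningReport:
    """Structured output of one pipeline run."""

    comparisons: list[ComparisonRow]
    selection: SelectionResult
    rocs: dict[str, RocResult]
    n_tests: int
    n_nc: int
    n_mci: int
    notes: list[str] = field(default_factory=list)
    subgroup: Optional["ScreeningReport"] = None

    @property
    def aucs(self) -> dict[str, float]:
        return {k: r.auc for k, r in self.rocs.items()}

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.comparisons])

    def to_dict(self) -> dict:
        d = {
            "n_nc": self.n_nc,
            "n_mci": self.n_mci,
            "n_tests": self.n_tests,
            "comparisons": [c.to_dict() for c in self.comparisons],
            "selection": self.selection.to_dict(),
            "aucs": self.aucs,
            "notes": self.notes,
        }
        if self.subgroup is not None:
            d["subgroup"] = self.subgroup.to_dict()
        return d


def _median_iqr(v: np.ndarray) -> str:
    q1, q2, q3 = np.nanpercentile(v, [25, 50, 75])
    return f"{q2:.2f} ({q1:.2f}, {q3:.2f})"


def analyze(
    cohort: pd.DataFrame,
    subgroup_education: Optional[float] = None,
    candidates: Sequence[str] = BIOMARKERS,
) -> ScreeningReport:
    """Run the full screening pipeline on a cohort table.

    Produces the group-comparison table (demographics, MMSE and all eight
    biomarkers), the step-up selection result, and ROC/AUC for MMSE, each
    retained marker and their logistic combination. With
    ``subgroup_education`` set, the identical pipeline is rerun on the rows
    with strictly more years of education and attached as ``subgroup``.
    Deterministic: the same table always yields the same report.
    """
    nc = cohort[cohort["group"] == "NC"]
    mci = cohort[cohort["group"] == "MCI"]
    if len(nc) == 0 or len(mci) == 0:
        raise ValueError("both groups must be nonempty")
    notes: list[str] = []
    comparisons: list[ComparisonRow] = []

    continuous = ["age", "education_years", "mmse", *candidates]
    continuous = [c for c in continuous if c in cohort.columns]
    for var in continuous:
        a = nc[var].dropna().to_numpy(float)
        b = mci[var].dropna().to_numpy(float)
        h, p = rank_sum_test(a, b)
        comparisons.append(ComparisonRow(
            var, "kruskal-wallis", _median_iqr(a), _median_iqr(b), h, p))
    if "sex" in cohort.columns:
        counts = [
            [(nc["sex"] == "female").sum(), (nc["sex"] == "male").sum()],
            [(mci["sex"] == "female").sum(), (mci["sex"] == "male").sum()],
        ]
        stat, p = chi_square_2x2(counts)
        comparisons.insert(1, ComparisonRow(
            "sex", "chi-square",
            f"{counts[0][0]}/{counts[0][1]}", f"{counts[1][0]}/{counts[1][1]}",
            stat, p))
    n_tests = len(comparisons)
    notes.append(f"{n_tests} hypothesis tests performed; no multiplicity correction applied")

    selection = stepup_select(cohort, candidates)
    if selection.separation_flagged:
        notes.append("separation encountered; ridge-stabilized logistic fit used")

    labels = (cohort["group"] == "MCI").to_numpy(int)
    rocs: dict[str, RocResult] = {}
    if "mmse" in cohort.columns:
        oriented, sign = orient_scores(cohort["mmse"].to_numpy(float), labels)
        rocs["mmse"] = roc_auc(oriented, labels, "mmse")
        if sign < 0:
            notes.append("mmse negated for ROC (higher oriented score = MCI)")
    for var in selection.selected:
        mask = cohort[var].notna()
        oriented, _ = orient_scores(cohort.loc[mask, var].to_numpy(float), labels[mask.to_numpy()])
        rocs[var] = roc_auc(oriented, labels[mask.to_numpy()], var)
    if selection.selected:
        score = fit_combination(cohort, selection.selected)
        comb_labels = (cohort.loc[score.index, "group"] == "MCI").to_numpy(int)
        rocs["combination"] = roc_auc(score.to_numpy(), comb_labels, "combination")

    report = ScreeningReport(
        comparisons=comparisons,
        selection=selection,
        rocs=rocs,
        n_tests=n_tests,
        n_nc=len(nc),
        n_mci=len(mci),
        notes=notes,
    )
    if subgroup_education is not None:
        sub = filter_basic_education(cohort, subgroup_education)
        report.subgroup = analyze(sub, None, candidates)
        report.subgroup.notes.append(
            f"basic-education subgroup: education_years > {subgroup_education}")
    return report
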