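"""Evaluation machinery: repeated stratified cross-validation,
concordance/displacement accounting, Fisher's exact group comparison,
and per-gene differential tests.

Cross-validation follows the study protocol: samples are split into five
random folds, re-drawn until every test fold contains at least one
sample of each reference class; the full model (scaling, Horn's k,
centroids, covariance) is refitted from scratch on each training split,
test samples receive the most probable of the three reference classes,
and the unweighted mean of per-class recall ("macro accuracy") is
averaged over 100 repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .beready_model import classify_reference_only, fit_reference
from .panel_io import (
    REFERENCE_CLASSES,
    CountMatrix,
    ReceptivityClass,
)
from .preprocess import NormalizedMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Repeated stratified k-fold cross-validation summary."""

    n_folds: int
    n_repeats: int
    seed: int | None
    macro_accuracy: float                 # mean over repeats of macro recall
    micro_accuracy: float                 # overall fraction correct
    per_class_recall: dict[ReceptivityClass, float]
    per_repeat_macro: np.ndarray
    fold_assignments: list[np.ndarray]    # per repeat: fold index per sample


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator, classes) -> np.ndarray:
    """Random near-equal partition, rejection-resampled until every fold
    contains at least one sample of each class."""
    n = len(labels)
    base = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    for _ in range(10000):
        folds = rng.permutation(base)
        if all(
            all((labels[folds == f] == c).any() for c in classes)
            for f in range(n_folds)
        ):
            return folds
    raise RuntimeError("could not stratify folds; too few samples per class")


def crossvalidate(m: CountMatrix, housekeepers, *, n_folds: int = 5,
                  n_repeats: int = 100, seed: int | None = None,
                  horn_iter: int = 100, quantile: float = 0.05) -> CVResult:
    """Repeated stratified k-fold CV of the full classification pipeline."""
    labels = m.reference_labels()
    if labels.isna().any():
        raise ValueError("all samples need a known phase label for CV")
    counts = labels.value_counts()
    for c in REFERENCE_CLASSES:
        if counts.get(c, 0) < n_folds:
            raise ValueError(
                f"class {c.value!r} has {counts.get(c, 0)} samples, fewer than "
                f"n_folds={n_folds}; lower the fold count"
            )
    rng = np.random.default_rng(seed)
    lab_arr = np.array([c.value for c in labels])  # plain strings for numpy ops
    sample_ids = np.asarray(m.sample_ids)
    per_repeat_macro = np.empty(n_repeats)
    assignments: list[np.ndarray] = []
    confusion = {c: {p: 0 for p in REFERENCE_CLASSES} for c in REFERENCE_CLASSES}
    class_values = [c.value for c in REFERENCE_CLASSES]
    for r in range(n_repeats):
        folds = _stratified_folds(lab_arr, n_folds, rng, class_values)
        assignments.append(folds)
        pred = pd.Series(index=labels.index, dtype=object)
        for f in range(n_folds):
            test_ids = sample_ids[folds == f]
            train_ids = sample_ids[folds != f]
            if set(test_ids) & set(train_ids):
                raise RuntimeError("leakage: test sample present in training split")
            model = fit_reference(
                m.subset(train_ids), housekeepers, n_iter=horn_iter,
                quantile=quantile,
                seed=int(rng.integers(2**31 - 1)),
            )
            pred.loc[test_ids] = classify_reference_only(m.subset(test_ids), model)
        recalls = []
        for c in REFERENCE_CLASSES:
            mask = labels == c
            recalls.append(float((pred[mask] == c).mean()))
            for p in REFERENCE_CLASSES:
                confusion[c][p] += int((pred[mask] == p).sum())
        per_repeat_macro[r] = float(np.mean(recalls))
    total = sum(sum(row.values()) for row in confusion.values())
    correct = sum(confusion[c][c] for c in REFERENCE_CLASSES)
    per_class = {
        c: confusion[c][c] / max(sum(confusion[c].values()), 1)
        for c in REFERENCE_CLASSES
    }
    return CVResult(
        n_folds=n_folds, n_repeats=n_repeats, seed=seed,
        macro_accuracy=float(per_repeat_macro.mean()),
        micro_accuracy=correct / total,
        per_class_recall=per_class,
        per_repeat_macro=per_repeat_macro,
        fold_assignments=assignments,
    )


# ---------------------------------------------------------------------------
# Concordance / displacement accounting
# ---------------------------------------------------------------------------

#: Expected (concordant) prediction sets by collection phase.  A
#: transitionary call at MSE counts as in-range variability of the
#: window of implantation.
_EXPECTED = {
    "ESE": {ReceptivityClass.PRE},
    "MSE": {ReceptivityClass.EARLY, ReceptivityClass.RECEPTIVE,
            ReceptivityClass.LATE},
    "LSE": {ReceptivityClass.POST},
}
_IN_RANGE = {ReceptivityClass.EARLY, ReceptivityClass.RECEPTIVE,
             ReceptivityClass.LATE}


@dataclass
class ConcordanceTable:
    """Cross-tabulation of expected collection phase vs predicted class,
    with displaced / in-range-shift accounting."""

    table: pd.DataFrame                  # phases x 5 predicted classes
    n: int
    concordant: int
    displaced: int
    in_range_shift: int                  # early/late calls at MSE
    n_mse: int                           # samples expected receptive (MSE)
    excluded: int = 0

    @property
    def concordance_pct(self) -> float:
        return 100.0 * self.concordant / self.n

    @property
    def displaced_pct(self) -> float:
        return 100.0 * self.displaced / self.n

    @property
    def in_range_shift_pct(self) -> float:
        """Early-/late-receptive calls as a share of the MSE-expected
        samples (the denominator used when reporting the shift rate)."""
        return 100.0 * self.in_range_shift / self.n_mse if self.n_mse else 0.0

    def summary(self) -> dict:
        return {
            "n": self.n,
            "concordant": self.concordant,
            "concordance_pct": round(self.concordance_pct, 1),
            "displaced": self.displaced,
            "displaced_pct": round(self.displaced_pct, 1),
            "in_range_shift": self.in_range_shift,
            "n_mse": self.n_mse,
            "in_range_shift_pct": round(self.in_range_shift_pct, 1),
            "excluded": self.excluded,
        }


def evaluate_concordance(predicted, expected_phase) -> ConcordanceTable:
    """Tabulate predicted 5-way classes against the phase expected from
    biopsy timing.

    A prediction is *concordant* when it lies in the expected set
    (ESE -> pre-receptive; MSE -> any in-range class; LSE ->
    post-receptive).  *Displaced* means the window of implantation is
    shifted: a pre-/post-receptive call at MSE, or an in-range call when
    pre- or post-receptive was expected.  Early-/late-receptive at MSE
    is counted separately as an in-range shift.
    """
    pred = [ReceptivityClass(p) for p in predicted]
    phases = list(expected_phase)
    if len(pred) != len(phases):
        raise ValueError("predicted and expected_phase lengths differ")
    keep = [(p, ph) for p, ph in zip(pred, phases) if ph in _EXPECTED]
    excluded = len(pred) - len(keep)
    if excluded:
        log.warning("%d sample(s) with unknown expected phase excluded", excluded)
    if not keep:
        raise ValueError("no samples with a known expected phase")
    tab = pd.DataFrame(
        0, index=list(_EXPECTED), columns=[c.value for c in ReceptivityClass]
    )
    concordant = displaced = in_range = 0
    for p, ph in keep:
        tab.loc[ph, p.value] += 1
        if p in _EXPECTED[ph]:
            concordant += 1
            if ph == "MSE" and p in (ReceptivityClass.EARLY, ReceptivityClass.LATE):
                in_range += 1
        else:
            if ph == "MSE" and p in (ReceptivityClass.PRE, ReceptivityClass.POST):
                displaced += 1
            elif ph == "ESE" and p in _IN_RANGE | {ReceptivityClass.POST}:
                displaced += 1
            elif ph == "LSE" and p in _IN_RANGE | {ReceptivityClass.PRE}:
                displaced += 1
    return ConcordanceTable(
        table=tab, n=len(keep), concordant=concordant, displaced=displaced,
        in_range_shift=in_range, n_mse=sum(1 for _, ph in keep if ph == "MSE"),
        excluded=excluded,
    )


def concordance_from_table(counts: dict[str, dict[str, int]]) -> ConcordanceTable:
    """Build a ConcordanceTable from tabulated counts
    {expected_phase: {predicted_class_value: n}}."""
    pred, phases = [], []
    for ph, row in counts.items():
        for cls_val, n in row.items():
            pred.extend([ReceptivityClass(cls_val)] * n)
            phases.extend([ph] * n)
    return evaluate_concordance(pred, phases)


# ---------------------------------------------------------------------------
# Fisher's exact test (lower tail)
# ---------------------------------------------------------------------------

def fisher_lower(table) -> float:
    """Lower-tailed Fisher's exact p-value for a 2x2 table.

    With margins fixed, the first cell is hypergeometric; the p-value is
    P[X <= x11].  Used to test whether the displaced-WOI proportion in
    one group is smaller than in another.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or (t != np.floor(t)).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        log.warning("degenerate all-zero table; p = 1")
        return 1.0
    n = int(t.sum())
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    return float(stats.hypergeom.cdf(int(t[0, 0]), n, c1, r1))


# ---------------------------------------------------------------------------
# Differential expression tests
# ---------------------------------------------------------------------------

def de_test(m: NormalizedMatrix, groups, correction: str = "bonferroni",
            equal_var: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene independent two-sample t-test on shifted-log expression.

    Welch's unequal-variance form is the default.  ``correction`` is
    ``bonferroni`` or ``bh`` (Benjamini–Hochberg FDR).  A gene constant
    in both groups gets t = 0, p = 1 (defined, not NaN).
    """
    if m.state != "shifted-log":
        raise ValueError("de_test expects a shifted-log matrix")
    groups = pd.Series(groups).reindex(m.values.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    a = m.values[groups == levels[0]]
    b = m.values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=equal_var, axis=0)
    t = np.asarray(t)
    p = np.asarray(p)
    flat = ~np.isfinite(t)
    t[flat] = 0.0
    p[flat] = 1.0
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    return pd.DataFrame(
        {
            "mean_" + str(levels[0]): a.mean(axis=0),
            "mean_" + str(levels[1]): b.mean(axis=0),
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=m.values.columns,
    )


def anova_interaction(m: NormalizedMatrix, factor1, factor2) -> pd.DataFrame:
    """Per-gene two-way ANOVA; the interaction F statistic and p-value
    are reported alongside the main effects (type II sums of squares)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if m.state != "shifted-log":
        raise ValueError("anova_interaction expects a shifted-log matrix")
    f1 = pd.Series(factor1).reindex(m.values.index)
    f2 = pd.Series(factor2).reindex(m.values.index)
    cells = pd.crosstab(f1, f2)
    empty = [(i, j) for i in cells.index for j in cells.columns
             if cells.loc[i, j] == 0]
    rows = {}
    for gene in m.values.columns:
        if empty:
            log.warning("gene %s skipped: empty design cell(s) %s", gene, empty)
            continue
        df = pd.DataFrame({"y": m.values[gene], "f1": f1, "f2": f2})
        fit = smf.ols("y ~ C(f1) * C(f2)", data=df).fit()
        an = sm.stats.anova_lm(fit, typ=2)
        rows[gene] = {
            "F_f1": an.loc["C(f1)", "F"],
            "p_f1": an.loc["C(f1)", "PR(>F)"],
            "F_f2": an.loc["C(f2)", "F"],
            "p_f2": an.loc["C(f2)", "PR(>F)"],
            "F_interaction": an.loc["C(f1):C(f2)", "F"],
            "p_interaction": an.loc["C(f1):C(f2)", "PR(>F)"],
        }
    if not rows:
        raise ValueError(f"all genes skipped; empty design cell(s) {empty}")
    return pd.DataFrame.from_dict(rows, orient="index")
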