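"""Group-comparison statistical battery.

For every feature the cohort is compared across the three groups with a
one-way fixed-effects ANOVA as the global test, followed by pairwise
Welch t-tests (unequal-variance independent t-tests with
Welch–Satterthwaite degrees of freedom) for HC-vs-PD, HC-vs-PR and
PD-vs-PR.  The binary sex variable is compared with Pearson's
chi-squared test of independence (no continuity correction).  P-values
are adjusted with the Benjamini–Hochberg step-up procedure, applied
jointly to all p-values within each of the four category tables
(demographics, volumes, Euclidean distances, cosine distances).  All
tests are two-sided at alpha = 0.05; descriptives use the sample (n-1)
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .registry import StructureRegistry, default_registry

logger = logging.getLogger(__name__)

ALPHA = 0.05

# Canonical pairwise contrasts, in reporting order.
PAIRS: Tuple[Tuple[str, str, str], ...] = (
    ("HCvPD", "CONTROL", "PARKINSON"),
    ("HCvPR", "CONTROL", "PRODROMAL"),
    ("PDvPR", "PARKINSON", "PRODROMAL"),
)


def describe_by_group(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mean and sample standard deviation per feature per group.

    Returns a frame indexed by feature with one ``mean``/``sd`` column
    pair per group.
    """
    numeric = table.select_dtypes(include=[np.number])
    groups = table[group_col]
    if groups.value_counts().min() < 1:
        raise ValueError("every group needs at least one subject")
    out: Dict[str, pd.Series] = {}
    for g, sub in numeric.groupby(groups):
        out[f"{g}_mean"] = sub.mean()
        out[f"{g}_sd"] = sub.std(ddof=1)
    return pd.DataFrame(out)


def anova_oneway(*samples: Sequence[float]) -> Tuple[float, float]:
    """Classical one-way fixed-effects F test across >= 2 groups."""
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    if all(np.var(a) == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        raise ValueError("zero within-group variance everywhere: F undefined")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Welch's t statistic and two-sided p-value.

    Degenerate conventions: if both samples have zero variance, equal
    means give ``t=0, p=1``; different means give an infinite statistic,
    reported with ``p=0`` and a logged warning.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if len(av) < 2 or len(bv) < 2:
        raise ValueError("each sample needs at least two values")
    if av.var(ddof=1) == 0 and bv.var(ddof=1) == 0:
        if av.mean() == bv.mean():
            return 0.0, 1.0
        logger.warning("Welch t-test: zero variance in both samples with unequal means; p -> 0")
        return float(np.sign(av.mean() - bv.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(av, bv, equal_var=False)
    return float(t), float(p)


def chi_squared_independence(table: pd.DataFrame | np.ndarray) -> Tuple[float, float, int]:
    """Pearson chi-squared test of independence, no continuity correction."""
    counts = np.asarray(table, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def sex_contingency(table: pd.DataFrame, group_col: str = "group", sex_col: str = "Sex",
                    group_order: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """2 x k contingency table of sex (rows M=0, F=1) by group (columns)."""
    groups = group_order if group_order is not None else sorted(table[group_col].unique())
    data = {g: [int(((table[group_col] == g) & (table[sex_col] == s)).sum()) for s in (0, 1)] for g in groups}
    return pd.DataFrame(data, index=pd.Index(["M", "F"], name="sex"))


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparison:
    """ANOVA plus pairwise Welch results for one feature."""

    feature: str
    anova_f: float
    anova_p: float
    pairwise_t: Dict[str, float]
    pairwise_p: Dict[str, float]
    # Filled in during per-table FDR adjustment:
    anova_p_adj: float = float("nan")
    pairwise_p_adj: Dict[str, float] = None  # type: ignore[assignment]

    def significant(self, slot: str, alpha: float = ALPHA) -> bool:
        if slot == "anova":
            return bool(self.anova_p_adj <= alpha)
        return bool(self.pairwise_p_adj[slot] <= alpha)


def _compare_feature(feature: str, values: pd.Series, groups: pd.Series) -> GroupComparison:
    by = {g: values[groups == g].to_numpy(dtype=float) for g in groups.unique()}
    f, p = anova_oneway(*by.values())
    pt: Dict[str, float] = {}
    pp: Dict[str, float] = {}
    for slot, g1, g2 in PAIRS:
        if g1 in by and g2 in by:
            t, tp = welch_ttest(by[g1], by[g2])
            pt[slot], pp[slot] = t, tp
    return GroupComparison(feature=feature, anova_f=f, anova_p=p, pairwise_t=pt, pairwise_p=pp)


def _adjust_table(comparisons: List[GroupComparison], extra_p: Optional[List[float]] = None) -> Optional[List[float]]:
    """Apply BH jointly across every p-value of one category table.

    ``extra_p`` carries table-level tests that are not per-feature
    comparisons (the sex chi-squared); their adjusted values are
    returned.
    """
    flat: List[float] = []
    for c in comparisons:
        flat.append(c.anova_p)
        flat.extend(c.pairwise_p[slot] for slot, *_ in PAIRS if slot in c.pairwise_p)
    n_extra = len(extra_p) if extra_p else 0
    if extra_p:
        flat.extend(extra_p)
    if not flat:
        return [] if extra_p is not None else None
    adj = fdr_adjust(flat)
    i = 0
    for c in comparisons:
        c.anova_p_adj = float(adj[i])
        i += 1
        c.pairwise_p_adj = {}
        for slot, *_ in PAIRS:
            if slot in c.pairwise_p:
                c.pairwise_p_adj[slot] = float(adj[i])
                i += 1
    return list(adj[len(adj) - n_extra :]) if extra_p else None


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabular layout: one row per feature, ANOVA plus three pairwise columns."""
    rows = []
    for c in comparisons:
        row: Dict[str, object] = {
            "feature": c.feature,
            "anova_F": c.anova_f,
            "anova_p": c.anova_p,
            "anova_p_adj": c.anova_p_adj,
            "anova_sig": c.significant("anova"),
        }
        for slot, *_ in PAIRS:
            if slot in c.pairwise_p:
                row[f"{slot}_t"] = c.pairwise_t[slot]
                row[f"{slot}_p"] = c.pairwise_p[slot]
                row[f"{slot}_p_adj"] = c.pairwise_p_adj[slot]
                row[f"{slot}_sig"] = c.significant(slot)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def build_category_tables(
    table: pd.DataFrame,
    registry: Optional[StructureRegistry] = None,
    group_col: str = "group",
    updrs_col: str = "updrs3",
) -> Dict[str, pd.DataFrame]:
    """The four category tables: demographics, volumes, Euclidean, cosine.

    The volumes table covers the raw reference (thalamus) volume plus
    every normalised volume; the distance tables exclude the reference
    structure (it is the reference point of the distance metrics).  BH
    adjustment is applied within each table across all of its p-values.
    The demographics table reports the age ANOVA and pairwise tests, the
    sex chi-squared, and — when present — the UPDRS3 motor score.
    """
    reg = registry if registry is not None else default_registry()
    groups = table[group_col]

    def compare_cols(cols: List[str]) -> List[GroupComparison]:
        return [_compare_feature(c, table[c], groups) for c in cols if c in table.columns]

    out: Dict[str, pd.DataFrame] = {}

    # Demographics: age (+ optional UPDRS3) ANOVA/pairwise, sex chi-squared.
    demo_cols = [c for c in ("Age", updrs_col) if c in table.columns]
    if "Age" not in table.columns or "Sex" not in table.columns:
        raise ValueError("feature table lacks Age/Sex demographics columns")
    demo = compare_cols(demo_cols)
    sex_tab = sex_contingency(table, group_col=group_col)
    chi2, chi_p, dof = chi_squared_independence(sex_tab)
    (chi_p_adj,) = _adjust_table(demo, extra_p=[chi_p])
    demo_frame = comparisons_frame(demo)
    sex_row = pd.DataFrame(
        {
            "anova_F": [np.nan], "anova_p": [np.nan], "anova_p_adj": [np.nan], "anova_sig": [False],
            "chi2": [chi2], "chi2_df": [dof], "chi2_p": [chi_p], "chi2_p_adj": [chi_p_adj],
            "chi2_sig": [chi_p_adj <= ALPHA],
        },
        index=pd.Index(["Sex"], name="feature"),
    )
    out["demographics"] = pd.concat([demo_frame, sex_row])

    vol_cols = [f"{reg.reference}_vol"] + [f"{n}_normvol" for n in reg.non_reference]
    euc_cols = [f"{n}_euclid" for n in reg.non_reference]
    cos_cols = [f"{n}_cosine" for n in reg.non_reference]
    for key, cols in (("volumes", vol_cols), ("euclidean", euc_cols), ("cosine", cos_cols)):
        comps = compare_cols(cols)
        _adjust_table(comps)
        out[key] = comparisons_frame(comps)
    return out
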