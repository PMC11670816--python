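"""Repeated-measures group statistics.

Fully-crossed within-subject ANOVA (any number of 2+-level factors),
paired t-tests on subject-level medians, paired Cohen's d, and a
leave-p-out robustness analysis that reruns the RM-ANOVA on every
subject subset of each size and reports the worst-case (maximum)
p-value per subset size.

The ANOVA is fitted with statsmodels' AnovaRM (conventional
within-subject sums of squares with subject x effect error terms);
partial eta squared is derived from F and the degrees of freedom.
No sphericity correction is applied by default: two-level factors need
none, and corrected output for a 3+-level factor can be requested
explicitly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM


@dataclass
class RMDesign:
    """Long-format balanced within-subject design."""

    data: pd.DataFrame  # columns: subject, <factors...>, value
    factors: list
    subject_col: str = "subject"
    value_col: str = "value"

    def __post_init__(self):
        df = self.data
        for col in [self.subject_col, self.value_col, *self.factors]:
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        counts = df.groupby([self.subject_col, *self.factors], observed=True).size()
        n_cells = int(np.prod([df[f].nunique() for f in self.factors]))
        per_subject = counts.groupby(level=0).size()
        if counts.min() < 1 or (per_subject != n_cells).any():
            raise ValueError("design must be fully crossed within every subject")
        if counts.nunique() != 1:
            raise ValueError("design must be balanced (equal replicates per cell)")

    @property
    def subjects(self) -> list:
        return sorted(self.data[self.subject_col].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subset(self, subjects) -> "RMDesign":
        sub = self.data[self.data[self.subject_col].isin(list(subjects))]
        return RMDesign(sub.reset_index(drop=True), list(self.factors),
                        self.subject_col, self.value_col)


@dataclass
class AnovaTable:
    """Per-effect F, degrees of freedom, p, and partial eta squared."""

    table: pd.DataFrame  # index: effect; columns: F, df1, df2, p, partial_eta_sq

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def p(self, name: str) -> float:
        return float(self.table.loc[name, "p"])

    def F(self, name: str) -> float:
        return float(self.table.loc[name, "F"])


def rm_anova(design: RMDesign) -> AnovaTable:
    """Repeated-measures ANOVA with all main effects and interactions.

    Requires a balanced, fully crossed design and at least 3 subjects.
    Replicates within a cell are averaged before fitting (the standard
    cell-means reduction for within-subject ANOVA).
    """
    if design.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    df = (
        design.data.groupby([design.subject_col, *design.factors], observed=True)[design.value_col]
        .mean()
        .reset_index()
    )
    res = AnovaRM(
        df, depvar=design.value_col, subject=design.subject_col, within=list(design.factors)
    ).fit()
    tab = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"}
    )
    tab.index = [i.replace(":", " x ") for i in tab.index]
    tab["partial_eta_sq"] = (tab["F"] * tab["df1"]) / (tab["F"] * tab["df1"] + tab["df2"])
    return AnovaTable(tab[["F", "df1", "df2", "p", "partial_eta_sq"]])


def paired_t_medians(medians_a, medians_b):
    """Paired t-test on per-subject medians: returns (t, df, p)."""
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    if np.all(a == b):  # zero differences: no evidence of any effect
        return 0.0, int(a.size - 1), 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


def cohens_d_paired(differences) -> float:
    """Cohen's d for paired data: mean(diff) / sd(diff).

    Degenerate inputs (zero variance) raise: the effect size is
    undefined for identical differences and infinite for a constant
    nonzero shift.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: Cohen's d undefined/degenerate")
    return float(d.mean() / sd)


@dataclass
class LeavePOutResult:
    effect: str
    max_p: dict  # subset size -> max p over all subsets of that size
    n_subsets: dict  # subset size -> number of subsets evaluated
    degenerate: list = field(default_factory=list)  # skipped subsets


def leave_p_out_cv(design: RMDesign, effect: str, subset_sizes=None) -> LeavePOutResult:
    """Worst-case robustness: rerun the ANOVA on every subject subset.

    For each size k, evaluates all C(n, k) subsets and records the
    maximum p-value of ``effect``; a subset on which the fit is
    degenerate is recorded and excluded with a warning.
    """
    subjects = design.subjects
    n = len(subjects)
    if subset_sizes is None:
        subset_sizes = range(3, n)
    max_p: dict = {}
    n_subsets: dict = {}
    degenerate: list = []
    for k in subset_sizes:
        if k > n:
            raise ValueError(f"subset size {k} exceeds {n} subjects")
        worst = -np.inf
        count = 0
        for combo in itertools.combinations(subjects, k):
            try:
                tab = rm_anova(design.subset(combo))
                p = tab.p(effect)
                if not np.isfinite(p):
                    raise ValueError("non-finite p")
            except (ValueError, np.linalg.LinAlgError) as exc:
                degenerate.append((k, combo, str(exc)))
                warnings.warn(f"degenerate fit for subset {combo}: {exc}")
                continue
            worst = max(worst, p)
            count += 1
        max_p[k] = float(worst) if count else float("nan")
        n_subsets[k] = count
    return LeavePOutResult(effect=effect, max_p=max_p, n_subsets=n_subsets,
                           degenerate=degenerate)


def make_design(values: np.ndarray, factor_levels: dict, subjects=None) -> RMDesign:
    """Build an RMDesign from an array of cell values.

    ``values`` has shape (n_subjects, *n_levels_per_factor) in the order
    of ``factor_levels`` (an ordered mapping factor -> list of levels).
    """
    values = np.asarray(values, dtype=float)
    names = list(factor_levels)
    shapes = tuple(len(v) for v in factor_levels.values())
    if values.shape[1:] != shapes:
        raise ValueError("values shape does not match factor levels")
    n_sub = values.shape[0]
    subjects = list(subjects) if subjects is not None else [f"s{i+1}" for i in range(n_sub)]
    rows = []
    for si, sub in enumerate(subjects):
        for combo in itertools.product(*(range(k) for k in shapes)):
            row = {"subject": sub, "value": values[(si, *combo)]}
            for name, li in zip(names, combo):
                row[name] = factor_levels[name][li]
            rows.append(row)
    return RMDesign(pd.DataFrame(rows), names)
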