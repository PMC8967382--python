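"""Statistical conventions: hierarchical averaging and group comparisons.

The fly (animal) is the statistical unit throughout: quantities measured
on many ROIs are first averaged within each fly, and all tests run on the
per-fly means.  An experimental genotype is called significant only when
it differs from *both* of its genetic controls after multiple-comparison
correction.  Test routing follows normality: when every group passes a
Lilliefors test (p > 0.05) a two-tailed t-test is used, otherwise the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "hierarchical_mean",
    "compare_to_controls",
    "anova_bonferroni",
]


@dataclass
class GroupComparison:
    """Outcome of a family of pairwise group comparisons."""

    test_used: str  # "t", "wilcoxon" or "anova"
    pairings: list[tuple[str, str]]
    p_raw: np.ndarray
    p_corrected: np.ndarray
    correction: str
    significant_vs_both: bool | None = None
    omnibus_p: float | None = None
    omnibus_stat: float | None = None
    notes: list[str] = field(default_factory=list)


def hierarchical_mean(values: pd.DataFrame | dict, value_col: str = "value") -> dict:
    """Mean ± SEM with the fly as the statistical unit.

    ``values`` is a table with columns ``fly_id`` and ``value`` (or a
    mapping fly -> array of per-ROI values).  Per-ROI values are first
    averaged within each fly; the grand mean and SEM are then computed
    over the fly means, so the result is invariant to duplicating ROIs
    within a fly.
    """
    if isinstance(values, dict):
        fly_means = np.array([np.mean(v) for v in values.values()], dtype=float)
    else:
        if values.empty:
            raise ValueError("no values supplied")
        fly_means = values.groupby("fly_id")[value_col].mean().to_numpy()
    if fly_means.size == 0:
        raise ValueError("no values supplied")
    n = len(fly_means)
    if n == 1:
        return {"mean": float(fly_means[0]), "sem": 0.0, "n_flies": 1,
                "degenerate": True}
    sem = float(fly_means.std(ddof=1) / np.sqrt(n))
    return {"mean": float(fly_means.mean()), "sem": sem, "n_flies": n,
            "degenerate": False}


def _groups_normal(groups: list[np.ndarray], alpha: float = 0.05) -> bool:
    """True when every group passes the Lilliefors normality test."""
    for g in groups:
        if np.ptp(g) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = lilliefors(g, dist="norm")
        if p <= alpha:
            return False
    return True


def compare_to_controls(
    experimental: np.ndarray,
    control1: np.ndarray,
    control2: np.ndarray,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare an experimental group against its two genetic controls.

    Normality-routed pairwise tests (t-test when all three groups pass
    Lilliefors at p > 0.05, Wilcoxon rank-sum otherwise), Holm-Bonferroni
    corrected over the two comparisons; the experimental group is flagged
    significant only when it differs from both controls at corrected
    ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in (experimental, control1, control2)]
    notes = []
    for name, g in zip(("experimental", "control1", "control2"), groups):
        if len(g) < 2:
            raise ValueError(f"group {name} needs at least 2 flies")
        if np.ptp(g) == 0:
            notes.append(f"group {name} is constant")
    exp, c1, c2 = groups
    if _groups_normal(groups):
        test = "t"
        p1 = sps.ttest_ind(exp, c1).pvalue
        p2 = sps.ttest_ind(exp, c2).pvalue
    else:
        test = "wilcoxon"
        p1 = sps.ranksums(exp, c1).pvalue
        p2 = sps.ranksums(exp, c2).pvalue
    p_raw = np.array([p1, p2], dtype=float)
    reject, p_corr, _, _ = multipletests(p_raw, alpha=alpha, method="holm")
    return GroupComparison(
        test_used=test,
        pairings=[("experimental", "control1"), ("experimental", "control2")],
        p_raw=p_raw,
        p_corrected=p_corr,
        correction="holm",
        significant_vs_both=bool(reject.all()),
        notes=notes,
    )


def anova_bonferroni(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA followed by Bonferroni-corrected pairwise t-tests."""
    if len(groups) < 3:
        raise ValueError("ANOVA harness needs at least 3 groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f_stat, omnibus_p = sps.f_oneway(*arrays)
    pairings = []
    p_raw = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairings.append((names[i], names[j]))
            p_raw.append(sps.ttest_ind(arrays[i], arrays[j]).pvalue)
    p_raw = np.array(p_raw, dtype=float)
    _, p_corr, _, _ = multipletests(p_raw, alpha=alpha, method="bonferroni")
    return GroupComparison(
        test_used="anova",
        pairings=pairings,
        p_raw=p_raw,
        p_corrected=p_corr,
        correction="bonferroni",
        omnibus_p=float(omnibus_p),
        omnibus_stat=float(f_stat),
    )
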