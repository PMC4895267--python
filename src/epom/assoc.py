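"""Steps 1 and 2 of the testing procedure.

Step 1 filters candidate windows with a one-way fixed-effects ANOVA per
window (H0: all group means equal), Bonferroni-corrected by the number of
windows in the matrix and thresholded at alpha1. Step 2 runs one-sided
Welch t-tests for every ordered group pair (H0: mu_i <= mu_j) on the
surviving windows; a window is associated with group i when the rejection
count over j != i exceeds m. Results from several marks are combined by
per-group set union (default) or intersection.

All tests are vectorised across windows; p-values come from scipy's F and
t distribution tails. Degenerate windows follow the limits of the
statistics: zero variance everywhere -> p = 1; zero within-group variance
with unequal means -> p = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenomicWindow
from .prep import SignalMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestingThresholds:
    """Thresholds of the two filtering steps.

    alpha1: level for the Bonferroni-corrected ANOVA p-value (step 1).
    alpha2: level for the raw one-sided t-test p-value (step 2).
    m: a window is associated with a group when rejected against more than
       m other groups (strictly greater by default; set strict=False for
       >= m).
    """

    __test__ = False  # not a pytest class, despite the name

    alpha1: float = 1e-10
    alpha2: float = 0.01
    m: int = 14
    strict: bool = True
    correct_step2: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha1 <= 1:
            raise ValueError(f"alpha1 must be in (0, 1], got {self.alpha1}")
        if not 0 < self.alpha2 <= 1:
            raise ValueError(f"alpha2 must be in (0, 1], got {self.alpha2}")
        if self.m < 0:
            raise ValueError("m must be non-negative")

    def validate_for_groups(self, n_groups: int) -> None:
        if self.m >= n_groups:
            raise ValueError(
                f"m={self.m} must be smaller than the number of groups "
                f"({n_groups})"
            )


@dataclass
class AssociationResult:
    """Per-group associated windows for one region class, with provenance."""

    marks: list[str]
    region_class: str
    associated: dict[str, set[GenomicWindow]]
    candidate_counts: dict[str, int] = field(default_factory=dict)
    thresholds: TestingThresholds | None = None
    combine_mode: str = "single"

    @property
    def groups(self) -> list[str]:
        return sorted(self.associated)

    def population(self) -> set[GenomicWindow]:
        """Union of all groups' associated windows (step-3 population)."""
        out: set[GenomicWindow] = set()
        for s in self.associated.values():
            out |= s
        return out


def _group_stats(matrix: SignalMatrix) -> tuple[list[str], np.ndarray,
                                                np.ndarray, np.ndarray]:
    """Per-group sample counts, means and (ddof=1) variances per window."""
    groups = matrix.groups
    R = len(matrix.windows)
    ns = np.empty(len(groups))
    means = np.empty((len(groups), R))
    variances = np.empty((len(groups), R))
    for g_idx, g in enumerate(groups):
        vals = matrix.group_values(g)
        ns[g_idx] = vals.shape[1]
        means[g_idx] = vals.mean(axis=1)
        variances[g_idx] = vals.var(axis=1, ddof=1)
    return groups, ns, means, variances


def anova_filter(
    matrix: SignalMatrix, thresholds: TestingThresholds
) -> tuple[list[GenomicWindow], np.ndarray]:
    """One-way ANOVA per window; keep windows with corrected p < alpha1.

    Returns the kept windows and the full vector of Bonferroni-corrected
    p-values (corrected by the number of windows in this matrix).
    """
    groups, ns, means, variances = _group_stats(matrix)
    G = len(groups)
    if G < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    small = [g for g, n in zip(groups, ns) if n < 2]
    if small:
        raise ValueError(f"groups with < 2 samples: {small}")
    N = ns.sum()
    grand = (ns[:, None] * means).sum(axis=0) / N
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = ((ns - 1)[:, None] * variances).sum(axis=0)
    df1, df2 = G - 1, int(N) - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(F, df1, df2)
    # degenerate limits: no within-variance
    zero_within = ss_within <= 0
    p[zero_within & (ss_between > 0)] = 0.0   # infinite F
    p[zero_within & (ss_between <= 0)] = 1.0  # all values identical
    R = len(matrix.windows)
    corrected = np.minimum(1.0, p * R)
    keep = corrected < thresholds.alpha1
    kept = [w for w, k in zip(matrix.windows, keep) if k]
    logger.info("%s/%s: ANOVA kept %d of %d windows at alpha1=%g",
                matrix.mark, matrix.region_class, len(kept), R,
                thresholds.alpha1)
    return kept, corrected


def _welch_one_sided(mi, vi, ni, mj, vj, nj):
    """Vectorised one-sided Welch p-values for H0: mu_i <= mu_j.

    Zero-variance limits: p=0 when mi>mj, p=1 when mi<mj, p=0.5 when equal.
    """
    se2 = vi / ni + vj / nj
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mi - mj) / np.sqrt(se2)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
    p = np.where(np.isfinite(t), stats.t.sf(np.nan_to_num(t), np.where(np.isfinite(df), df, 1.0)), 0.5)
    degenerate = se2 <= 0
    if np.any(degenerate):
        diff = mi - mj
        p = np.where(degenerate & (diff > 0), 0.0, p)
        p = np.where(degenerate & (diff < 0), 1.0, p)
        p = np.where(degenerate & (diff == 0), 0.5, p)
    return p


def pairwise_ttest(
    matrix: SignalMatrix, thresholds: TestingThresholds
) -> dict[str, set[GenomicWindow]]:
    """Step 2: per-group associated windows from pairwise one-sided t-tests.

    ``matrix`` should already be restricted to post-ANOVA windows. For each
    window and ordered pair (i, j), rejects H0: mu_i <= mu_j at alpha2
    (raw p by default); group i collects the window when its rejection
    count over j != i exceeds m.
    """
    groups, ns, means, variances = _group_stats(matrix)
    thresholds.validate_for_groups(len(groups))
    G = len(groups)
    R = len(matrix.windows)
    alpha = thresholds.alpha2
    n_tests = R * G * (G - 1) if thresholds.correct_step2 else 1
    rejections = np.zeros((G, R), dtype=int)
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            p = _welch_one_sided(means[i], variances[i], ns[i],
                                 means[j], variances[j], ns[j])
            rejections[i] += np.minimum(1.0, p * n_tests) < alpha
    if thresholds.strict:
        assoc_mask = rejections > thresholds.m
    else:
        assoc_mask = rejections >= thresholds.m
    windows = np.array(matrix.windows, dtype=object)
    out: dict[str, set[GenomicWindow]] = {}
    for g_idx, g in enumerate(groups):
        out[g] = {matrix.windows[k] for k in np.nonzero(assoc_mask[g_idx])[0]}
    return out


def associate(
    matrix: SignalMatrix, thresholds: TestingThresholds | None = None
) -> AssociationResult:
    """Run steps 1 and 2 on one mark's matrix."""
    thresholds = thresholds or TestingThresholds()
    kept, corrected = anova_filter(matrix, thresholds)
    if len(kept) == 0:
        associated = {g: set() for g in matrix.groups}
    else:
        kept_set = set(kept)
        mask = np.array([w in kept_set for w in matrix.windows])
        associated = pairwise_ttest(matrix.restrict(mask), thresholds)
    counts = {
        "candidates": len(matrix.windows),
        "post_anova": len(kept),
    }
    for g, s in associated.items():
        counts[f"associated_{g}"] = len(s)
    return AssociationResult(
        marks=[matrix.mark],
        region_class=matrix.region_class,
        associated=associated,
        candidate_counts=counts,
        thresholds=thresholds,
        combine_mode="single",
    )


def combine_marks(
    results: list[AssociationResult], mode: str = "union"
) -> AssociationResult:
    """Combine per-mark results by per-group set union or intersection."""
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union or intersection, got {mode!r}")
    if not results:
        raise ValueError("no results to combine")
    classes = {r.region_class for r in results}
    if len(classes) > 1:
        raise ValueError(f"mixed region classes {sorted(classes)}")
    group_sets = [set(r.associated) for r in results]
    if any(gs != group_sets[0] for gs in group_sets[1:]):
        raise ValueError("results have mismatched group sets")
    combined: dict[str, set[GenomicWindow]] = {}
    for g in results[0].associated:
        sets = [r.associated[g] for r in results]
        acc = set(sets[0])
        for s in sets[1:]:
            acc = acc | s if mode == "union" else acc & s
        combined[g] = acc
    counts = {"candidates": max(r.candidate_counts.get("candidates", 0)
                                for r in results)}
    for g, s in combined.items():
        counts[f"associated_{g}"] = len(s)
    return AssociationResult(
        marks=sorted({m for r in results for m in r.marks}),
        region_class=results[0].region_class,
        associated=combined,
        candidate_counts=counts,
        thresholds=results[0].thresholds,
        combine_mode=mode,
    )


def rank_marks_by_differential_regions(
    matrices: list[SignalMatrix], alpha1: float = 1e-10
) -> list[tuple[str, int]]:
    """Rank marks by how many windows show differential signal (step-1 count).

    Descending count; ties broken alphabetically by mark name. Useful for
    choosing marks when none are of prior interest.
    """
    th = TestingThresholds(alpha1=alpha1)
    counts = []
    for m in matrices:
        kept, _ = anova_filter(m, th)
        counts.append((m.mark, len(kept)))
    return sorted(counts, key=lambda mc: (-mc[1], mc[0]))


def association_percentages(
    associated_counts: dict[str, int], candidate_count: int
) -> dict[str, float]:
    """Percent of associated regions among candidate regions, per group.

    100 * associated / candidates, rounded to 2 decimals — the reporting
    convention of the per-group summary table.
    """
    if candidate_count <= 0:
        raise ValueError("candidate_count must be positive")
    return {
        g: round(100.0 * c / candidate_count, 2)
        for g, c in associated_counts.items()
    }


def stage_count_report(result: AssociationResult, candidate_count: int):
    """Per-group counts and association percentages as a DataFrame."""
    import pandas as pd

    rows = []
    pct = association_percentages(
        {g: len(s) for g, s in result.associated.items()}, candidate_count
    )
    for g in result.groups:
        rows.append({
            "group": g,
            "region_class": result.region_class,
            "marks": "+".join(result.marks),
            "associated": len(result.associated[g]),
            "candidates": candidate_count,
            "pct_associated": pct[g],
        })
    return pd.DataFrame(rows)
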