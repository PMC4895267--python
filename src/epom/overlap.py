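"""The exact overlap test and the EPOM score.

Two region sets A and B drawn from a finite population of n regions share
|A ∩ B| elements. Under independence the shared count X follows a
hypergeometric distribution; the test p-value is the upper tail

    p = sum_{i = |A∩B|}^{min(|A|,|B|)}  C(a,i) C(n-a, b-i) / C(n,b)

and the EPOM score is -log10 of the Bonferroni-corrected p. On realistic
inputs p underflows double precision by hundreds of orders of magnitude
(scores above 300 occur), so the tail is accumulated entirely in log
space: log binomial coefficients from log-gamma, summed with
log-sum-exp. Raw binomials are never multiplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .assoc import AssociationResult

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class OverlapTestInput:
    """Population size n, set sizes |A| and |B|, and the observed overlap."""

    n: int
    size_a: int
    size_b: int
    overlap: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be positive")
        if not (0 <= self.size_a <= self.n and 0 <= self.size_b <= self.n):
            raise ValueError("set sizes must lie in [0, n]")
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError("overlap exceeds the smaller set")
        if self.overlap < max(0, self.size_a + self.size_b - self.n):
            raise ValueError("overlap below its feasible minimum")


@dataclass(frozen=True)
class OverlapTestResult:
    log10_p: float
    bonferroni_factor: int
    epom_score: float

    @property
    def p(self) -> float:
        """Linear-scale p; underflows to 0.0 for very significant overlaps."""
        return 10.0 ** self.log10_p


def _log_binom(n, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def overlap_log_pvalue(inp: OverlapTestInput) -> float:
    """log10 of the upper-tail overlap-test p-value, exact in log space.

    Equals log10 P(X >= overlap) for X ~ Hypergeometric(n, |A|, |B|).
    """
    n, a, b, ov = inp.n, inp.size_a, inp.size_b, inp.overlap
    hi = min(a, b)
    if ov <= max(0, a + b - n):
        return 0.0  # tail covers the whole support
    i = np.arange(ov, hi + 1)
    log_terms = (
        _log_binom(a, i) + _log_binom(n - a, b - i) - _log_binom(n, b)
    )
    log10_p = float(logsumexp(log_terms)) / _LN10
    # guard against rounding pushing the total above 1
    return min(log10_p, 0.0)


def epom_score(log10_p: float, num_tests: int) -> float:
    """-log10 of the Bonferroni-corrected p, computed in log space.

    corrected p = min(1, p * num_tests); score = max(0, -log10 p
    - log10 num_tests). Scores are clamped at 0 when the corrected p
    reaches 1.
    """
    if num_tests < 1:
        raise ValueError("num_tests must be >= 1")
    if log10_p > 0:
        raise ValueError("log10_p must be <= 0")
    return max(0.0, -log10_p - math.log10(num_tests))


@dataclass
class EPOMMatrix:
    """Symmetric G × G matrix of pairwise EPOM scores for one region class."""

    groups: list[str]
    scores: np.ndarray
    log10_pvalues: np.ndarray
    region_class: str
    population_size: int
    bonferroni_factor: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.groups, columns=self.groups)

    def saturated(self, cap: float = 20.0) -> np.ndarray:
        return saturate(self, cap)


def epom_matrix(assoc: AssociationResult,
                bonferroni_factor: int | None = None) -> EPOMMatrix:
    """Pairwise EPOM scores between all groups' associated region sets.

    The population is the union of all groups' associated windows. The
    default Bonferroni factor is the number of unordered group pairs
    G(G-1)/2, applied to off-diagonal entries; diagonal entries (full
    self-overlap) are reported uncorrected since a self-comparison is not
    a hypothesis test. Groups with empty sets score 0 with a warning.
    """
    groups = assoc.groups
    G = len(groups)
    if G < 2:
        raise ValueError("need at least 2 groups")
    population = assoc.population()
    n = len(population)
    empty = [g for g in groups if not assoc.associated[g]]
    if empty:
        logger.warning("groups with empty associated sets score 0: %s", empty)
    factor = bonferroni_factor if bonferroni_factor is not None else G * (G - 1) // 2
    scores = np.zeros((G, G))
    log10p = np.zeros((G, G))
    for i, gi in enumerate(groups):
        A = assoc.associated[gi]
        if A and n:
            d = overlap_log_pvalue(OverlapTestInput(n, len(A), len(A), len(A)))
            log10p[i, i] = d
            scores[i, i] = epom_score(d, 1)
        for j in range(i + 1, G):
            B = assoc.associated[groups[j]]
            if not A or not B:
                continue
            lp = overlap_log_pvalue(
                OverlapTestInput(n, len(A), len(B), len(A & B))
            )
            log10p[i, j] = log10p[j, i] = lp
            s = epom_score(lp, factor)
            scores[i, j] = scores[j, i] = s
    return EPOMMatrix(
        groups=groups,
        scores=scores,
        log10_pvalues=log10p,
        region_class=assoc.region_class,
        population_size=n,
        bonferroni_factor=factor,
    )


def saturate(matrix: EPOMMatrix, cap: float = 20.0) -> np.ndarray:
    """Display copy of the score matrix with entries capped at ``cap``.

    The input matrix is left unmodified.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.minimum(matrix.scores, cap)


def plot_heatmap(matrix: EPOMMatrix, path, cap: float = 20.0,
                 group_colors: dict[str, str] | None = None) -> None:
    """Render the (saturated) EPOM matrix as a heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = saturate(matrix, cap) if np.isfinite(cap) else matrix.scores
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(matrix.groups)),) * 2)
    im = ax.imshow(data, cmap="Reds", vmin=0, vmax=cap if np.isfinite(cap) else None)
    ax.set_xticks(range(len(matrix.groups)), matrix.groups, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.groups)), matrix.groups, fontsize=7)
    if group_colors:
        for tick in ax.get_xticklabels() + ax.get_yticklabels():
            tick.set_color(group_colors.get(tick.get_text(), "black"))
    fig.colorbar(im, ax=ax, label="EPOM score")
    ax.set_title(f"EPOM ({matrix.region_class})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
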