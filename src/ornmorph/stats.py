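"""Statistical battery for population morphometrics.

Within-sensillum comparisons use paired two-tailed t-tests; comparisons
between non-neighboring neurons use unpaired two-tailed t-tests when both
groups pass Shapiro-Wilk normality at alpha = 0.05 and Mann-Whitney rank-sum
tests otherwise.  Multi-group comparisons use Kruskal-Wallis one-way ANOVA
on ranks with a tie-corrected Dunn post-hoc (Holm-adjusted) rendered as a
compact letter display: groups sharing a letter do not differ significantly.
Correlations are ordinary least-squares fits reported with R².

Underlying distributions come from :mod:`scipy.stats`; the Dunn post-hoc
and letter assignment are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import StatisticsError

__all__ = [
    "TestResult",
    "LetterDisplay",
    "paired_t",
    "auto_two_sample",
    "mann_whitney",
    "kruskal_letters",
    "dunn_posthoc",
    "linear_fit",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    alpha: float = ALPHA
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatisticsError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: group -> set of letters."""

    letters: dict[str, str]

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def paired_t(x, y) -> TestResult:
    """Paired two-tailed t-test on element-wise differences.

    Identical samples give statistic 0 and p = 1; non-zero constant
    differences (zero variance) are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("paired test needs equal-length 1D samples")
    if len(x) < 2:
        raise StatisticsError("paired test needs n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult("paired_t", 0.0, 1.0, (len(x), len(y)))
        raise StatisticsError("zero-variance non-zero differences")
    t, p = sps.ttest_rel(x, y)
    return TestResult("paired_t", float(t), float(p), (len(x), len(y)))


def mann_whitney(x, y) -> TestResult:
    """Two-tailed Mann-Whitney rank-sum test.

    Exact null enumeration when the pooled sample has <= 12 observations and
    no ties; the normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise StatisticsError("each group needs n >= 1")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        u = len(x) * len(y) / 2.0
        return TestResult("mann_whitney", u, 1.0, (len(x), len(y)),
                          detail={"method": "degenerate"})
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 12 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                            use_continuity=True)
    return TestResult("mann_whitney", float(u), float(p), (len(x), len(y)),
                      detail={"method": method})


def auto_two_sample(x, y, alpha: float = ALPHA) -> TestResult:
    """Normality-gated two-sample comparison.

    Shapiro-Wilk on each group; if both pass at ``alpha`` the comparison is
    an unpaired two-tailed t-test, otherwise a Mann-Whitney rank-sum test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise StatisticsError("normality gate needs n >= 3 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return TestResult("unpaired_t", 0.0, 1.0, (len(x), len(y)),
                          detail={"gate": "degenerate"})
    normal = all(np.ptp(g) > 0 and sps.shapiro(g).pvalue > alpha for g in (x, y))
    if normal:
        t, p = sps.ttest_ind(x, y)
        return TestResult("unpaired_t", float(t), float(p), (len(x), len(y)),
                          detail={"gate": "shapiro_passed"})
    res = mann_whitney(x, y)
    return TestResult("mann_whitney", res.statistic, res.p_value, res.n,
                      detail={"gate": "shapiro_failed", **res.detail})


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn post-hoc and compact letter display
# ---------------------------------------------------------------------------


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "holm") -> dict[tuple[str, str], float]:
    """Pairwise Dunn z-tests on pooled ranks, tie-corrected, Holm-adjusted.

    Returns adjusted two-sided p-values keyed by group-name pairs.
    """
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([groups[k] for k in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for k in names:
        mean_rank[k] = float(ranks[start : start + sizes[k]].mean())
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    raw: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0:
                raw[(a, b)] = 1.0
                continue
            z = (mean_rank[a] - mean_rank[b]) / se
            raw[(a, b)] = float(2 * sps.norm.sf(abs(z)))
    if adjust == "none":
        return raw
    # Holm step-down with monotonicity enforcement
    pairs = sorted(raw, key=lambda k: raw[k])
    m = len(pairs)
    adjusted, running = {}, 0.0
    for rank_i, pair in enumerate(pairs):
        running = max(running, min(1.0, (m - rank_i) * raw[pair]))
        adjusted[pair] = running
    return adjusted


def _compact_letters(
    names: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Piepho insert-and-absorb letter assignment.

    Start from one column containing every group; for each significant pair
    sharing a column, duplicate the column and separate the pair; absorb
    columns that are subsets of others.  Guarantees: significant pairs never
    share a letter, non-significant pairs always do.
    """
    columns: list[set[str]] = [set(names)]
    for a, b in significant:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(c < d or (c == d and i > j) for j, d in enumerate(columns) if j != i)
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # stable letter order: columns sorted by the first group they contain
    order = {k: i for i, k in enumerate(names)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    out = {k: "" for k in names}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g] += letter
    return {k: "".join(sorted(v)) for k, v in out.items()}


def kruskal_letters(
    groups: dict[str, np.ndarray], alpha: float = ALPHA
) -> tuple[TestResult, LetterDisplay]:
    """Kruskal-Wallis omnibus plus Dunn/Holm post-hoc letter display.

    Groups are lettered in order of mean rank; two groups share a letter iff
    their Holm-adjusted Dunn comparison is non-significant.  When the
    omnibus test is itself non-significant all groups share one letter.
    """
    if len(groups) < 3:
        raise StatisticsError("Kruskal-Wallis needs >= 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) < 2 for v in arrays.values()):
        raise StatisticsError("each group needs n >= 2")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        raise StatisticsError("all observations identical")
    h, p = sps.kruskal(*arrays.values())
    names = list(arrays)
    result = TestResult(
        "kruskal_wallis", float(h), float(p),
        tuple(len(arrays[k]) for k in names),
        alpha=alpha,
    )
    if p >= alpha:
        letters = {k: "a" for k in names}
        return result, LetterDisplay(letters)
    adjusted = dunn_posthoc(arrays)
    significant = {pair for pair, padj in adjusted.items() if padj < alpha}
    # letter order by mean rank
    ranks = sps.rankdata(pooled)
    start, mean_rank = 0, {}
    for k in names:
        mean_rank[k] = ranks[start : start + len(arrays[k])].mean()
        start += len(arrays[k])
    ordered = sorted(names, key=lambda k: mean_rank[k])
    letters = _compact_letters(ordered, significant)
    return result, LetterDisplay(letters)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least-squares fit: (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatisticsError("linear fit needs n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise StatisticsError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
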