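"""Exact and asymptotic enrichment statistics.

Hypergeometric overrepresentation, Fisher's exact test on 2x2 tables,
unconditional odds ratios, Benjamini-Hochberg FDR, an EnrichR-style
combined score for dot sizing, and the chi-square test of independence
with Pearson residuals. These are the statistical workhorses shared by
the divergence-set, disease-intersection and network modules.

Conventions
-----------
* 2x2 tables are laid out ``[[a, b], [c, d]]`` with rows = category 1/2
  and columns = hit/miss.
* The odds ratio is the unconditional sample odds ratio ``a*d / (b*c)``,
  not the conditional MLE; this is what comparative studies print.
* The two-sided Fisher p-value uses the point-probability rule: all
  tables with point probability at most the observed one (up to a
  relative tolerance of 1e-7 for floating-point ties) contribute.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "Chi2Result",
    "hypergeom_upper_tail",
    "odds_ratio",
    "fisher_exact",
    "bh_fdr",
    "combined_score",
    "chi_square_independence",
    "enrich",
]

#: relative tolerance for point-probability ties in the two-sided Fisher test
_FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 count table; rows = category 1/2, columns = hit/miss."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x for x in cells):
            raise ValueError("contingency table entries must be integers")
        if any(x < 0 for x in cells):
            raise ValueError("contingency table entries must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table must have at least one positive margin")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class EnrichmentResult:
    """Overrepresentation of a named gene list in a query set.

    ``k`` of the ``n`` query genes fall in the list of size ``K`` drawn
    from a universe of ``N`` genes.
    """

    name: str
    k: int
    K: int
    n: int
    N: int
    odds_ratio: float
    p: float
    fdr: float = math.nan
    combined_score: float = math.nan

    @property
    def table(self) -> ContingencyTable2x2:
        return ContingencyTable2x2(
            self.k, self.n - self.k, self.K - self.k, self.N - self.K - self.n + self.k
        )


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    pearson_residuals: np.ndarray
    low_expected: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), bool))
    dropped_rows: list = field(default_factory=list)
    dropped_cols: list = field(default_factory=list)
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` observed hits, ``K`` marked items, ``n`` draws, ``N`` population.
    """
    if not 0 <= k <= min(K, n) <= N or n > N or K > N:
        raise ValueError(
            f"hypergeometric bounds violated: k={k}, K={K}, n={n}, N={N}"
        )
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Unconditional sample odds ratio (a*d)/(b*c) with inf/0 conventions."""
    ad = t.a * t.d
    bc = t.b * t.c
    if bc == 0:
        if ad == 0:
            warnings.warn("odds ratio undefined: both diagonals zero", stacklevel=2)
            return math.nan
        return math.inf
    if ad == 0:
        return 0.0
    return ad / bc


def _hypergeom_pmf_support(t: ContingencyTable2x2):
    """Point probabilities over all tables with the observed margins."""
    r1, c1, N = t.a + t.b, t.a + t.c, t.total
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(xs, N, r1, c1)
    return xs, pmf


def fisher_exact(t: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Exact p-value of Fisher's test on a 2x2 table.

    ``greater`` tests enrichment of hits in row 1 (upper tail in ``a``),
    ``less`` the depletion, ``two_sided`` sums all margin-fixed tables
    whose point probability does not exceed the observed one.
    """
    xs, pmf = _hypergeom_pmf_support(t)
    p_obs = pmf[int(t.a) - xs[0]]
    if alternative == "greater":
        p = pmf[xs >= t.a].sum()
    elif alternative == "less":
        p = pmf[xs <= t.a].sum()
    elif alternative == "two_sided":
        p = pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_RTOL)].sum()
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combined_score(odds_ratio: float, p: float, max_or: float = 1e6) -> float:
    """EnrichR-style visualization score ln(OR) * (-ln p).

    Infinite odds ratios are clamped to ``max_or`` before scoring; the
    score sizes dots and never decides significance.
    """
    if math.isnan(odds_ratio):
        return math.nan
    or_ = min(max(odds_ratio, 1.0 / max_or), max_or)
    p = min(max(p, 1e-300), 1.0)
    return math.log(or_) * (-math.log(p))


def chi_square_independence(
    table,
    expected_floor: float = 5.0,
    row_labels=None,
    col_labels=None,
) -> Chi2Result:
    """Chi-square test of independence with Pearson residuals.

    Rows or columns whose margin is zero are dropped with a warning
    (mirroring heatmaps where sparse cell types are blanked); cells with
    expected count below ``expected_floor`` are flagged, not removed.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row_labels = list(row_labels) if row_labels is not None else list(range(obs.shape[0]))
    col_labels = list(col_labels) if col_labels is not None else list(range(obs.shape[1]))

    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    dropped_rows = [row_labels[i] for i in np.flatnonzero(~keep_r)]
    dropped_cols = [col_labels[j] for j in np.flatnonzero(~keep_c)]
    if dropped_rows or dropped_cols:
        warnings.warn(
            f"dropping zero-margin rows {dropped_rows} / cols {dropped_cols}",
            stacklevel=2,
        )
        obs = obs[np.ix_(keep_r, keep_c)]
        row_labels = [row_labels[i] for i in np.flatnonzero(keep_r)]
        col_labels = [col_labels[j] for j in np.flatnonzero(keep_c)]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table degenerate after dropping empty margins")

    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    residuals = (obs - expected) / np.sqrt(expected)
    return Chi2Result(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        observed=obs,
        expected=expected,
        pearson_residuals=residuals,
        low_expected=expected < expected_floor,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
        row_labels=row_labels,
        col_labels=col_labels,
    )


def enrich(query, gene_list, universe, name: str = "") -> EnrichmentResult:
    """Hypergeometric overrepresentation of ``gene_list`` in ``query``.

    Both sets are intersected with the universe first; list members
    absent from the universe do not count toward ``K``.
    """
    universe = set(universe)
    q = set(query) & universe
    gl = set(gene_list) & universe
    k, K, n, N = len(q & gl), len(gl), len(q), len(universe)
    if not universe:
        raise ValueError("empty universe")
    p = hypergeom_upper_tail(k, K, n, N)
    table = ContingencyTable2x2(k, n - k, K - k, N - K - n + k)
    or_ = odds_ratio(table) if table.total else math.nan
    return EnrichmentResult(
        name=name, k=k, K=K, n=n, N=N, odds_ratio=or_, p=p,
        combined_score=combined_score(or_, p),
    )
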