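"""Risk categories, reclassification matrices and tiered testing strategies.

Women are assigned to half-open 5-year-risk categories before and after
genotyping; the reclassification matrix tabulates the joint category
distribution.  A testing strategy restricts SNP testing to a band of prior
risk: women inside the band get their posterior, women outside keep their
prior, and the yield is counted as crossings of the treatment threshold
(default 3% 5-year risk, the chemoprevention-consideration cut-off) in each
direction.  The benefit fraction of a strategy is its total crossings
relative to testing everyone on the same cohort, a paired comparison that
cancels Monte-Carlo noise between strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .population import Cohort

__all__ = [
    "CategoryScheme",
    "DEFAULT_SCHEME",
    "TREAT_THRESHOLD",
    "categorize",
    "ReclassMatrix",
    "reclass_matrix",
    "StrategyResult",
    "apply_strategy",
    "benefit_curve",
    "summarize_above_threshold",
    "DEFAULT_STRATEGIES",
]

#: treatment threshold: 5-year risk at or above which chemoprevention is
#: recommended for consideration
TREAT_THRESHOLD = 0.03


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered cut-points defining half-open risk categories.

    ``edges = (e1, ..., ek)`` yields k+1 categories
    [0, e1), [e1, e2), ..., [ek, 1).  The default reproduces the standard
    7-category layout: <1.0%, 1.0-1.4%, 1.5-1.9%, 2.0-2.4%, 2.5-2.9%,
    3.0-3.9%, >=4.0%.
    """

    edges: tuple[float, ...] = (0.01, 0.015, 0.02, 0.025, 0.03, 0.04)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) == 0 or np.any(np.diff(e) <= 0) or np.any((e <= 0) | (e >= 1)):
            raise ValueError("edges must be strictly increasing and inside (0, 1)")

    @property
    def n_categories(self) -> int:
        return len(self.edges) + 1

    @property
    def labels(self) -> list[str]:
        pct = [e * 100 for e in self.edges]
        labels = [f"<{pct[0]:g}%"]
        for lo, hi in zip(pct, pct[1:]):
            labels.append(f"{lo:g}-{hi:g}%")
        labels.append(f">={pct[-1]:g}%")
        return labels


DEFAULT_SCHEME = CategoryScheme()


def categorize(risk, scheme: CategoryScheme = DEFAULT_SCHEME):
    """Index of the half-open category containing each risk (scalar or array)."""
    arr = np.asarray(risk, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("risk must lie strictly inside (0, 1)")
    idx = np.searchsorted(np.asarray(scheme.edges), arr, side="right")
    return int(idx) if np.ndim(risk) == 0 else idx


@dataclass
class ReclassMatrix:
    """Joint pre/post category distribution as population proportions.

    ``cells[i, j]`` is the fraction of the cohort in pre-test category i and
    post-test category j; rows and columns follow the scheme's category
    order and the whole matrix sums to 1.
    """

    cells: np.ndarray
    scheme: CategoryScheme

    @property
    def row_marginals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def to_frame(self, include_marginals: bool = True, percent: bool = False) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        labels = self.scheme.labels
        df = pd.DataFrame(self.cells * scale, index=labels, columns=labels)
        df.index.name = "pre_test"
        df.columns.name = "post_test"
        if include_marginals:
            df["Total"] = self.row_marginals * scale
            total_row = np.append(self.col_marginals * scale, self.cells.sum() * scale)
            df.loc["Total"] = total_row
        return df

    def crossing_mass(self, threshold: float, upward: bool) -> float:
        """Total cell mass crossing ``threshold`` in the given direction.

        ``threshold`` must coincide with a category edge; categories at or
        above it count as the treated side.
        """
        edges = np.asarray(self.scheme.edges)
        k = int(np.searchsorted(edges, threshold - 1e-12, side="left")) + 1
        if upward:
            return float(self.cells[:k, k:].sum())
        return float(self.cells[k:, :k].sum())


def reclass_matrix(cohort: Cohort, scheme: CategoryScheme = DEFAULT_SCHEME) -> ReclassMatrix:
    """Empirical joint distribution of (pre, post) risk categories."""
    pre = categorize(cohort.prior, scheme)
    post = categorize(cohort.posterior, scheme)
    k = scheme.n_categories
    counts = np.zeros((k, k))
    np.add.at(counts, (pre, post), 1.0)
    return ReclassMatrix(cells=counts / cohort.n, scheme=scheme)


@dataclass(frozen=True)
class StrategyResult:
    """Yield of one tiered testing strategy.

    ``pct_*`` fields are population proportions (0-1 scale despite the
    name): fraction tested, fraction reclassified upward across the
    treatment threshold, fraction reclassified downward.
    ``benefit_fraction`` is (up + down) relative to testing everyone on the
    same cohort; 1.0 when everyone is tested.
    """

    test_lower: float
    test_upper: float | None
    treat_threshold: float
    pct_tested: float
    pct_up: float
    pct_down: float
    benefit_fraction: float


def _tested_mask(cohort: Cohort, test_lower: float, test_upper: float | None) -> np.ndarray:
    mask = cohort.prior >= test_lower
    if test_upper is not None:
        mask &= cohort.prior < test_upper
    return mask


def _crossings(cohort: Cohort, tested: np.ndarray, threshold: float) -> tuple[float, float]:
    final = np.where(tested, cohort.posterior, cohort.prior)
    up = float(((cohort.prior < threshold) & (final >= threshold)).mean())
    down = float(((cohort.prior >= threshold) & (final < threshold)).mean())
    return up, down


def apply_strategy(
    cohort: Cohort,
    test_lower: float,
    test_upper: float | None = None,
    treat_threshold: float = TREAT_THRESHOLD,
) -> StrategyResult:
    """Evaluate one testing band [test_lower, test_upper) on a cohort.

    Women with prior risk inside the band are SNP-tested (their posterior
    becomes the acted-on risk); everyone else keeps the prior.  Crossings of
    ``treat_threshold`` in each direction are tallied as fractions of the
    whole cohort, and the benefit fraction is measured against the
    test-everyone run on the identical cohort.
    """
    if not 0.0 <= test_lower < 1.0:
        raise ValueError(f"test_lower must be in [0, 1), got {test_lower}")
    if test_upper is not None and not test_lower < test_upper <= 1.0:
        raise ValueError(f"need test_lower < test_upper <= 1, got {test_upper}")
    if not 0.0 < treat_threshold < 1.0:
        raise ValueError(f"treat_threshold must be in (0, 1), got {treat_threshold}")
    tested = _tested_mask(cohort, test_lower, test_upper)
    up, down = _crossings(cohort, tested, treat_threshold)
    up_all, down_all = _crossings(cohort, np.ones(cohort.n, dtype=bool), treat_threshold)
    total_all = up_all + down_all
    benefit = (up + down) / total_all if total_all > 0 else 0.0
    return StrategyResult(
        test_lower=test_lower,
        test_upper=test_upper,
        treat_threshold=treat_threshold,
        pct_tested=float(tested.mean()),
        pct_up=up,
        pct_down=down,
        benefit_fraction=float(benefit),
    )


#: the six canonical strategies: a 2.5-3.9% band, then nested open bands
#: >=2.5%, >=2%, >=1.5%, >=1%, and test-everyone
DEFAULT_STRATEGIES: tuple[tuple[float, float | None], ...] = (
    (0.025, 0.04),
    (0.025, None),
    (0.02, None),
    (0.015, None),
    (0.01, None),
    (0.0, None),
)


def benefit_curve(
    cohort: Cohort,
    strategies: Iterable[tuple[float, float | None]] = DEFAULT_STRATEGIES,
    treat_threshold: float = TREAT_THRESHOLD,
) -> list[StrategyResult]:
    """Evaluate a family of strategies, ordered by fraction tested.

    For nested bands the benefit fraction is non-decreasing in the fraction
    tested (a larger band can only add crossings).
    """
    strategies = list(strategies)
    if not strategies:
        raise ValueError("need at least one strategy")
    results = [apply_strategy(cohort, lo, hi, treat_threshold) for lo, hi in strategies]
    return sorted(results, key=lambda r: r.pct_tested)


def strategy_table(results: Sequence[StrategyResult]) -> pd.DataFrame:
    """Machine-readable strategy summary (raw proportions and rounded %)."""
    rows = []
    for i, r in enumerate(results, start=1):
        upper = "" if r.test_upper is None else f"{r.test_upper * 100:g}%"
        rows.append(
            {
                "strategy": i,
                "band_lower": r.test_lower,
                "band_upper": r.test_upper if r.test_upper is not None else np.inf,
                "band_label": f">={r.test_lower * 100:g}%" + (f" to <{upper}" if upper else ""),
                "pct_tested": r.pct_tested,
                "pct_up": r.pct_up,
                "pct_down": r.pct_down,
                "benefit_fraction": r.benefit_fraction,
                "pct_tested_rounded": round(r.pct_tested * 100, 1),
                "pct_up_rounded": round(r.pct_up * 100, 1),
                "pct_down_rounded": round(r.pct_down * 100, 1),
                "benefit_pct_rounded": round(r.benefit_fraction * 100, 1),
            }
        )
    return pd.DataFrame(rows)


def summarize_above_threshold(
    cohort: Cohort,
    treat_threshold: float = TREAT_THRESHOLD,
    by: np.ndarray | str | None = None,
) -> pd.DataFrame:
    """Pre- and post-test proportions at or above the treatment threshold.

    ``by`` may be a boolean/categorical array aligned with the cohort or the
    string ``"fh_positive"`` to stratify on family history; the overall row
    is always included.
    """
    if isinstance(by, str):
        if by != "fh_positive":
            raise ValueError(f"unknown stratification flag {by!r}")
        by = cohort.fh_positive
    pre = cohort.prior >= treat_threshold
    post = cohort.posterior >= treat_threshold
    rows = [{"stratum": "all", "n": cohort.n, "pre": pre.mean(), "post": post.mean()}]
    if by is not None:
        by = np.asarray(by)
        for level in np.unique(by):
            sel = by == level
            rows.append(
                {
                    "stratum": str(level),
                    "n": int(sel.sum()),
                    "pre": float(pre[sel].mean()) if sel.any() else np.nan,
                    "post": float(post[sel].mean()) if sel.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)
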