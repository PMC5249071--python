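"""Top-level model/results interface for the reclassification analysis.

:class:`SnpRiskReclassification` bundles the inputs — a SNP panel, a binned
prior-risk distribution, the prevalence constant, the treatment threshold
and the testing strategies — and its :meth:`~SnpRiskReclassification.fit`
runs the whole simulation (cohort synthesis, posterior update,
case/control discrimination, reclassification and strategy accounting),
returning a :class:`ReclassificationResults` with the estimates and a
``summary()`` table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import discrimination as disc
from .genotypes import PanelGenotypeModel
from .panel import SnpPanel
from .population import (
    Cohort,
    LognormalRiskFit,
    RiskDistribution,
    bcsc_screening_marginals,
    fit_smooth_distribution,
    sample_cohort,
)
from .prs import FamilyHistoryAdjustment, estimate_proportion_explained
from .reclassification import (
    DEFAULT_SCHEME,
    DEFAULT_STRATEGIES,
    TREAT_THRESHOLD,
    CategoryScheme,
    ReclassMatrix,
    StrategyResult,
    benefit_curve,
    reclass_matrix,
    strategy_table,
    summarize_above_threshold,
)

__all__ = ["SnpRiskReclassification", "ReclassificationResults"]


class SnpRiskReclassification:
    """Model of SNP-testing-driven risk reclassification in a screening population.

    Parameters
    ----------
    panel : SnpPanel
        Independent risk SNPs (risk-allele frequency + per-allele OR).
    prior_distribution : RiskDistribution or LognormalRiskFit, optional
        Binned (or fitted continuous) distribution of prior 5-year risk.
        Defaults to the coarse BCSC screening-population marginals.
    prevalence : float
        Disease prevalence constant used to derive control genotype
        frequencies; must stay in the low-prevalence regime (0, 0.10].
    treat_threshold : float
        5-year risk at or above which treatment is considered (default 0.03).
    fh_rate : float
        Population prevalence of positive first-degree family history
        (default 0.114); set to 0 to simulate population genotypes for all.
    fh_relative_risk : float
        Marginal relative risk conferred by positive family history.
    scheme : CategoryScheme
        Risk categories for the reclassification matrix.
    strategies : sequence of (lower, upper or None)
        Prior-risk testing bands to evaluate.
    """

    def __init__(
        self,
        panel: SnpPanel,
        prior_distribution: RiskDistribution | LognormalRiskFit | None = None,
        *,
        prevalence: float = 0.05,
        treat_threshold: float = TREAT_THRESHOLD,
        fh_rate: float = 0.114,
        fh_relative_risk: float = 2.0,
        scheme: CategoryScheme = DEFAULT_SCHEME,
        strategies: Sequence[tuple[float, float | None]] = DEFAULT_STRATEGIES,
    ):
        self.panel = panel
        self.prior_distribution = (
            prior_distribution if prior_distribution is not None else bcsc_screening_marginals()
        )
        self.prevalence = prevalence
        self.treat_threshold = treat_threshold
        self.fh_rate = fh_rate
        self.fh_relative_risk = fh_relative_risk
        self.scheme = scheme
        self.strategies = tuple(strategies)
        # validates the panel/prevalence combination eagerly
        self.genotype_model = PanelGenotypeModel(panel, prevalence)
        self._fh_adjustment: FamilyHistoryAdjustment | None = None

    @classmethod
    def from_config(cls, config) -> "SnpRiskReclassification":
        """Build the model from a :class:`~snpreclass.config.RunConfig`."""
        from .config import build_panel, build_prior_distribution

        return cls(
            build_panel(config),
            build_prior_distribution(config),
            prevalence=config.prevalence,
            treat_threshold=config.treat_threshold,
            fh_rate=config.fh_rate,
            fh_relative_risk=config.fh_relative_risk,
            strategies=tuple(tuple(s) for s in config.strategies),
        )

    @property
    def fh_adjustment(self) -> FamilyHistoryAdjustment:
        """Family-history correction implied by the panel (computed once)."""
        if self._fh_adjustment is None:
            pi = (
                estimate_proportion_explained(self.panel, self.fh_relative_risk, self.prevalence)
                if self.fh_relative_risk > 1
                else 0.0
            )
            self._fh_adjustment = FamilyHistoryAdjustment(self.fh_relative_risk, pi)
        return self._fh_adjustment

    @property
    def closed_form_auc(self) -> float:
        """Analytic normal-approximation AUC of the panel."""
        return disc.closed_form_auc(self.panel)

    def fit(
        self,
        n: int = 200_000,
        n_cases: int = 5000,
        n_controls: int = 5000,
        seed: int | np.random.SeedSequence = 0,
    ) -> "ReclassificationResults":
        """Run the full simulation and return results.

        All randomness flows from ``seed`` through two spawned, independent
        streams (cohort synthesis; case/control discrimination), so stages
        are individually reproducible and two fits with identical arguments
        are bitwise identical.
        """
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        cohort_ss, disc_ss = ss.spawn(2)
        cohort = sample_cohort(
            self.prior_distribution,
            n,
            self.panel,
            fh_rate=self.fh_rate,
            fh_adjustment=self.fh_adjustment if self.fh_rate > 0 else None,
            prevalence=self.prevalence,
            seed=np.random.default_rng(cohort_ss),
        )
        discrimination = disc.assess_discrimination(
            self.panel, n_cases, n_controls, self.prevalence, np.random.default_rng(disc_ss)
        )
        matrix = reclass_matrix(cohort, self.scheme)
        strategy_results = benefit_curve(cohort, self.strategies, self.treat_threshold)
        above = summarize_above_threshold(cohort, self.treat_threshold, by="fh_positive")
        return ReclassificationResults(
            model=self,
            cohort=cohort,
            discrimination=discrimination,
            matrix=matrix,
            strategies=strategy_results,
            above_threshold=above,
            seed=seed if not isinstance(seed, np.random.SeedSequence) else None,
        )


@dataclass
class ReclassificationResults:
    """Fitted results: cohort, discrimination, matrix and strategy yields."""

    model: SnpRiskReclassification
    cohort: Cohort
    discrimination: disc.DiscriminationResult
    matrix: ReclassMatrix
    strategies: list[StrategyResult]
    above_threshold: pd.DataFrame
    seed: object = None

    # -- headline quantities ------------------------------------------------
    @property
    def auc(self) -> float:
        return self.discrimination.auc

    @property
    def pre_frac_above(self) -> float:
        """Fraction with prior risk at or above the treatment threshold."""
        return float((self.cohort.prior >= self.model.treat_threshold).mean())

    @property
    def post_frac_above(self) -> float:
        """Fraction with posterior risk at or above the treatment threshold."""
        return float((self.cohort.posterior >= self.model.treat_threshold).mean())

    @property
    def frac_top_category(self) -> float:
        """Fraction whose posterior lands in the top risk category."""
        top = self.model.scheme.edges[-1]
        return float((self.cohort.posterior >= top).mean())

    @property
    def test_everyone(self) -> StrategyResult:
        """The strategy with every subject tested (benefit denominator)."""
        return max(self.strategies, key=lambda r: r.pct_tested)

    @property
    def frac_high_reclassified_down(self) -> float:
        """Among priors >= threshold, the fraction moved below by testing."""
        thr = self.model.treat_threshold
        high = self.cohort.prior >= thr
        return float((self.cohort.posterior[high] < thr).mean())

    def strategy_frame(self) -> pd.DataFrame:
        return strategy_table(self.strategies)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        m = self.model
        lines = [
            "SNP risk reclassification results",
            "=" * 49,
            f"panel size:            {len(m.panel)} SNPs",
            f"odds-ratio range:      {m.panel.odds_ratios.min():.3f} - "
            f"{m.panel.odds_ratios.max():.3f}",
            f"prevalence K:          {m.prevalence:.3f}",
            f"cohort size:           {self.cohort.n}",
            f"family-history rate:   {m.fh_rate:.3f}"
            + (
                f" (RR {m.fh_adjustment.fh_relative_risk:g}, "
                f"proportion explained {m.fh_adjustment.proportion_explained:.3f})"
                if m.fh_rate > 0
                else ""
            ),
            f"simulated AUC:         {self.auc:.4f}  "
            f"(closed form {m.closed_form_auc:.4f}; "
            f"{self.discrimination.n_cases}+{self.discrimination.n_controls})",
            f"treatment threshold:   {m.treat_threshold * 100:.1f}% 5-year risk",
            f"  pre-test  >= threshold: {self.pre_frac_above * 100:.1f}%",
            f"  post-test >= threshold: {self.post_frac_above * 100:.1f}%",
            f"  post-test top category: {self.frac_top_category * 100:.1f}%",
            f"  reclassified up (test all):   {self.test_everyone.pct_up * 100:.1f}%",
            f"  reclassified down (test all): {self.test_everyone.pct_down * 100:.1f}%",
            f"  of pre-test high, moved down: {self.frac_high_reclassified_down * 100:.1f}%",
            "",
            "testing strategies (band -> tested %, up %, down %, benefit %):",
        ]
        for i, r in enumerate(self.strategies, start=1):
            band = f">={r.test_lower * 100:g}%"
            if r.test_upper is not None:
                band += f" to <{r.test_upper * 100:g}%"
            lines.append(
                f"  {i}. {band:<16} {r.pct_tested * 100:6.1f}  {r.pct_up * 100:5.1f}  "
                f"{r.pct_down * 100:5.1f}  {r.benefit_fraction * 100:6.1f}"
            )
        return "\n".join(lines)

    def save_tables(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write the machine-readable output tables; returns name -> path.

        ``table1.csv`` pre/post above-threshold proportions by stratum,
        ``table2.csv`` the reclassification matrix with marginals,
        ``table3.csv`` the strategy yields, ``fig2.csv`` the benefit-curve
        points, ``auc.csv`` the discrimination summary.
        """
        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
            path = os.path.join(os.fspath(outdir), name)
            df.to_csv(path, index=index, lineterminator="\n")
            paths[name] = path

        _write("table1.csv", self.above_threshold)
        _write("table2.csv", self.matrix.to_frame(percent=True), index=True)
        _write("table3.csv", self.strategy_frame())
        fig2 = pd.DataFrame(
            {
                "pct_tested": [r.pct_tested for r in self.strategies],
                "benefit_fraction": [r.benefit_fraction for r in self.strategies],
                "up_fraction": [
                    r.pct_up / self.test_everyone.pct_up if self.test_everyone.pct_up else np.nan
                    for r in self.strategies
                ],
                "down_fraction": [
                    r.pct_down / self.test_everyone.pct_down
                    if self.test_everyone.pct_down
                    else np.nan
                    for r in self.strategies
                ],
            }
        )
        _write("fig2.csv", fig2)
        _write(
            "auc.csv",
            pd.DataFrame(
                [
                    {
                        "auc": self.auc,
                        "closed_form_auc": self.model.closed_form_auc,
                        "n_cases": self.discrimination.n_cases,
                        "n_controls": self.discrimination.n_controls,
                        "log_lr_case_mean": self.discrimination.log_lr_case_mean,
                        "log_lr_control_mean": self.discrimination.log_lr_control_mean,
                    }
                ]
            ),
        )
        return paths
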