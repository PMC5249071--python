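"""Prior-risk distributions and synthetic screening cohorts.

The screening population enters the analysis as a binned distribution of
prior 5-year absolute risk (the output of a clinical risk model such as the
BCSC model, tabulated over risk categories).  This module reconstructs a
continuous distribution from those bin masses, and samples synthetic
cohorts of women — prior risk, family-history flag, panel genotypes, log
likelihood ratio and posterior risk — for the downstream reclassification
analysis.

Within-bin placement is uniform (the maximum-entropy choice; midpoints
create artifacts at decision thresholds).  The open-ended top bin is filled
from the conditional tail of a lognormal fitted to all the bin masses,
capped at a 5-year risk of 0.30.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import PanelGenotypeModel
from .panel import SnpPanel
from .prs import FamilyHistoryAdjustment, estimate_proportion_explained, posterior_risk

__all__ = [
    "RiskBin",
    "RiskDistribution",
    "bcsc_screening_marginals",
    "read_risk_distribution",
    "write_risk_distribution",
    "LognormalRiskFit",
    "fit_smooth_distribution",
    "Cohort",
    "sample_cohort",
    "RISK_CAP",
]

#: hard upper bound on 5-year absolute risk when imputing the open top bin
RISK_CAP = 0.30


@dataclass(frozen=True)
class RiskBin:
    """One category of prior 5-year risk: [lower, upper) with population mass.

    ``upper`` may be ``inf`` for an open-ended top category.  Masses need
    not be normalised (published tables often sum to ~100% with rounding
    slack); :class:`RiskDistribution` normalises on demand.
    """

    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper:
            raise ValueError(f"need 0 <= lower < upper, got [{self.lower}, {self.upper})")
        if self.mass < 0.0:
            raise ValueError(f"bin mass must be >= 0, got {self.mass}")


class RiskDistribution:
    """Ordered, contiguous, non-overlapping collection of :class:`RiskBin`."""

    def __init__(self, bins):
        self.bins: tuple[RiskBin, ...] = tuple(bins)
        if not self.bins:
            raise ValueError("a risk distribution needs at least one bin")
        for a, b in zip(self.bins, self.bins[1:]):
            if not np.isclose(a.upper, b.lower):
                raise ValueError(
                    f"bins must be contiguous: [{a.lower}, {a.upper}) then "
                    f"[{b.lower}, {b.upper})"
                )
        if self.total_mass <= 0.0:
            raise ValueError("total mass must be positive")

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    @property
    def lowers(self) -> np.ndarray:
        return np.array([b.lower for b in self.bins])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([b.upper for b in self.bins])

    @property
    def masses(self) -> np.ndarray:
        """Raw (possibly unnormalised) bin masses."""
        return np.array([b.mass for b in self.bins])

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Bin masses normalised to sum to 1."""
        m = self.masses
        return m / m.sum()

    def normalized(self) -> "RiskDistribution":
        probs = self.probabilities
        return RiskDistribution(
            RiskBin(b.lower, b.upper, p) for b, p in zip(self.bins, probs)
        )

    def mass_above(self, threshold: float, normalized: bool = True) -> float:
        """Total mass of bins whose lower edge is at or above ``threshold``.

        Exact when ``threshold`` is a bin edge; bins are half-open so a bin
        with ``lower == threshold`` counts fully.
        """
        m = self.probabilities if normalized else self.masses
        return float(m[self.lowers >= threshold - 1e-12].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_lower": self.lowers, "bin_upper": self.uppers, "proportion": self.masses}
        )


#: Coarse 7-category pre-genotyping distribution of 5-year BCSC risk among
#: 796,294 non-Hispanic White screening-mammography participants ages 35-69.
#: Categories are half-open; the published percentages sum to 100.1 (rounding
#: slack) and are kept raw here.
_BCSC_COARSE = (
    (0.000, 0.010, 0.417),
    (0.010, 0.015, 0.218),
    (0.015, 0.020, 0.157),
    (0.020, 0.025, 0.094),
    (0.025, 0.030, 0.046),
    (0.030, 0.040, 0.046),
    (0.040, np.inf, 0.023),
)


def bcsc_screening_marginals() -> RiskDistribution:
    """The coarse 7-bin pre-test risk distribution of the BCSC screening cohort.

    Masses are the published percentages as proportions, unnormalised (they
    sum to 1.001; use :meth:`RiskDistribution.normalized` or the
    ``probabilities`` property for sampling weights).
    """
    return RiskDistribution(RiskBin(*row) for row in _BCSC_COARSE)


def read_risk_distribution(path: str | os.PathLike) -> RiskDistribution:
    """Read a binned risk distribution from delimited text.

    Columns ``bin_lower``, ``bin_upper``, ``proportion``; ``bin_upper`` may
    be blank or ``inf`` for the open top bin.  Accepts both fine-resolution
    (0.2%-bin) and coarse category tables; tab or comma delimited by
    extension.
    """
    sep = "\t" if os.path.splitext(os.fspath(path))[1].lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("bin_lower", "bin_upper", "proportion") if c not in df.columns]
    if missing:
        raise ValueError(f"risk distribution file {path}: missing column(s) {missing}")
    upper = pd.to_numeric(df["bin_upper"], errors="coerce").fillna(np.inf)
    return RiskDistribution(
        RiskBin(float(lo), float(up), float(m))
        for lo, up, m in zip(df["bin_lower"], upper, df["proportion"])
    )


def write_risk_distribution(dist: RiskDistribution, path: str | os.PathLike) -> None:
    sep = "\t" if os.path.splitext(os.fspath(path))[1].lower() in (".tsv", ".tab", ".txt") else ","
    df = dist.to_frame()
    df["bin_upper"] = df["bin_upper"].replace(np.inf, "inf")
    df.to_csv(path, sep=sep, index=False)


@dataclass
class LognormalRiskFit:
    """Lognormal distribution fitted to binned risk masses, truncated at a cap.

    ``mu`` and ``sigma`` parameterise the underlying lognormal on the
    natural-log risk scale; the distribution is truncated to (0, ``cap``].
    ``residuals`` are (model - observed) bin masses at the fitted optimum.
    """

    mu: float
    sigma: float
    cap: float = RISK_CAP
    residuals: np.ndarray = field(default=None, repr=False)
    fitted_masses: np.ndarray = field(default=None, repr=False)

    def _raw(self):
        return stats.lognorm(self.sigma, scale=np.exp(self.mu))

    def cdf(self, x) -> np.ndarray:
        """CDF of the truncated distribution."""
        raw = self._raw()
        z = raw.cdf(self.cap)
        return np.clip(raw.cdf(np.minimum(x, self.cap)) / z, 0.0, 1.0)

    def sf(self, x):
        """Survival function P(risk >= x), strictly decreasing below the cap."""
        return 1.0 - self.cdf(x)

    def ppf(self, q):
        raw = self._raw()
        return raw.ppf(np.asarray(q) * raw.cdf(self.cap))

    def bin_masses(self, lowers, uppers) -> np.ndarray:
        return self.cdf(np.asarray(uppers, dtype=float)) - self.cdf(np.asarray(lowers, dtype=float))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.random(n))

    def sample_conditional(self, lower: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample from the conditional tail [lower, cap]."""
        lo = self.cdf(lower)
        return self.ppf(rng.uniform(lo, 1.0, n))


def fit_smooth_distribution(marginals: RiskDistribution, cap: float = RISK_CAP) -> LognormalRiskFit:
    """Fit a truncated lognormal to binned risk masses by least squares.

    Minimises the sum of squared differences between model and observed
    (normalised) bin masses over (mu, sigma), from several moment-informed
    starting points with a Nelder-Mead polish.  Requires at least three bins
    with positive mass — a cruder histogram cannot identify two parameters.
    """
    if np.count_nonzero(marginals.masses > 0) < 3:
        raise ValueError("need at least 3 bins with positive mass to fit a lognormal")
    lowers, uppers = marginals.lowers, marginals.uppers
    target = marginals.probabilities

    def objective(params):
        mu, log_sigma = params
        fit = LognormalRiskFit(mu, np.exp(log_sigma), cap)
        return float(((fit.bin_masses(lowers, uppers) - target) ** 2).sum())

    # moment start: mean of bin midpoints (top bin at its lower edge)
    mids = np.where(np.isfinite(uppers), (lowers + uppers) / 2.0, lowers)
    mean = float((target * np.maximum(mids, 1e-6)).sum())
    best = None
    for sigma0 in (0.4, 0.7, 1.0, 1.5):
        res = optimize.minimize(
            objective,
            x0=[np.log(mean) - sigma0**2 / 2.0, np.log(sigma0)],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], float(np.exp(best.x[1]))
    fit = LognormalRiskFit(mu, sigma, cap)
    fitted = fit.bin_masses(lowers, uppers)
    fit.fitted_masses = fitted
    fit.residuals = fitted - target
    return fit


@dataclass
class Cohort:
    """A simulated screening cohort.

    Arrays are aligned by subject: ``prior`` (5-year risk before
    genotyping), ``fh_positive`` (first-degree family history flag),
    ``genotypes`` ((n, n_snps) risk-allele counts), ``log_lr`` (panel log
    likelihood ratio) and ``posterior`` (risk after genotyping, with the
    family-history double-count removed for FH+ women).
    """

    prior: np.ndarray
    fh_positive: np.ndarray
    genotypes: np.ndarray
    log_lr: np.ndarray
    posterior: np.ndarray
    fh_adjustment: FamilyHistoryAdjustment
    prevalence: float
    seed: object = None

    @property
    def n(self) -> int:
        return len(self.prior)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.arange(self.n),
                "prior": self.prior,
                "fh_positive": self.fh_positive,
                "log_lr": self.log_lr,
                "posterior": self.posterior,
            }
        )

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def _sample_priors(
    dist: RiskDistribution | LognormalRiskFit, n: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(dist, LognormalRiskFit):
        return dist.sample(n, rng)
    probs = dist.probabilities
    lowers, uppers = dist.lowers, dist.uppers
    which = rng.choice(len(probs), size=n, p=probs)
    priors = np.empty(n)
    smooth = None
    for b in range(len(probs)):
        sel = which == b
        if not sel.any():
            continue
        if np.isfinite(uppers[b]):
            priors[sel] = rng.uniform(lowers[b], uppers[b], sel.sum())
        else:
            if smooth is None:
                smooth = fit_smooth_distribution(dist)
            priors[sel] = smooth.sample_conditional(lowers[b], int(sel.sum()), rng)
    # risk 0 has no odds; nudge into the open interval
    return np.clip(priors, 1e-9, RISK_CAP)


def sample_cohort(
    dist: RiskDistribution | LognormalRiskFit,
    n: int,
    panel: SnpPanel,
    fh_rate: float = 0.114,
    fh_adjustment: FamilyHistoryAdjustment | None = None,
    prevalence: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Sample a cohort of women with priors, genotypes and posteriors.

    Priors come from ``dist`` (uniform within bins when binned, the fitted
    conditional tail for an open top bin).  Family history is Bernoulli at
    ``fh_rate`` (default 0.114, the first-degree family-history prevalence
    of the BCSC screening population), independent of the prior — the prior
    already embeds family history through the clinical risk model, and the
    family-history adjustment handles the interaction with the panel.
    FH- women draw genotypes from the population triples and update via the
    plain odds-scale posterior; FH+ women draw from Hardy-Weinberg triples
    at the family-history-conditioned allele frequencies and have the
    double-counted share of familial risk removed.

    If ``fh_adjustment`` is omitted it is built from the panel: relative
    risk 2.0 with ``proportion_explained`` estimated by
    :func:`~snpreclass.prs.estimate_proportion_explained`.

    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= fh_rate <= 1.0:
        raise ValueError(f"fh_rate must be in [0, 1], got {fh_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fh_adjustment is None:
        if fh_rate > 0:
            fh_adjustment = FamilyHistoryAdjustment(
                2.0, estimate_proportion_explained(panel, 2.0, prevalence)
            )
        else:
            fh_adjustment = FamilyHistoryAdjustment(2.0, 0.0)

    priors = _sample_priors(dist, n, rng)
    fh = rng.random(n) < fh_rate
    model = PanelGenotypeModel(panel, prevalence)
    genotypes = np.empty((n, len(panel)), dtype=np.uint8)
    n_fh = int(fh.sum())
    if n_fh < n:
        genotypes[~fh] = model.draw("population", n - n_fh, rng)
    if n_fh:
        genotypes[fh] = model.draw("fh", n_fh, rng)
    log_lr = model.score(genotypes)
    lr = np.exp(log_lr)
    posterior = np.empty(n)
    if n_fh < n:
        posterior[~fh] = np.atleast_1d(posterior_risk(priors[~fh], lr[~fh]))
    if n_fh:
        posterior[fh] = np.atleast_1d(
            posterior_risk(priors[fh], lr[fh] / fh_adjustment.odds_deflator)
        )
    return Cohort(
        prior=priors,
        fh_positive=fh,
        genotypes=genotypes,
        log_lr=log_lr,
        posterior=posterior,
        fh_adjustment=fh_adjustment,
        prevalence=prevalence,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )
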