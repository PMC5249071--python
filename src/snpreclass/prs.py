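"""Genotype likelihood ratios and Bayesian absolute-risk updates.

The multi-SNP likelihood ratio is the product over independent loci of
P(g | case) / P(g | control).  A 5-year absolute risk prior is updated on
the odds scale:

    posterior odds = prior odds * LR,    posterior = odds / (1 + odds).

For women whose prior already includes a family-history relative risk, part
of that risk is re-counted by the SNPs (risk alleles run in families).  The
family-history adjustment removes the double-counted share by deflating the
prior odds by RR_FH ** pi, where pi is the fraction of log RR_FH the panel
accounts for, before applying the LR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeDistribution, PanelGenotypeModel
from .panel import SnpPanel

__all__ = [
    "FamilyHistoryAdjustment",
    "snp_lr",
    "panel_lr",
    "log_panel_lr",
    "posterior_risk",
    "fh_adjusted_posterior",
    "estimate_proportion_explained",
]


@dataclass(frozen=True)
class FamilyHistoryAdjustment:
    """Correction for family-history risk partly explained by the panel.

    Parameters
    ----------
    fh_relative_risk : float
        Marginal relative risk conferred by a positive first-degree family
        history, >= 1 (2.0 is the standard first-degree-relative figure).
    proportion_explained : float
        Fraction of ``log(fh_relative_risk)`` accounted for by the SNP
        panel, in [0, 1].
    """

    fh_relative_risk: float = 2.0
    proportion_explained: float = 0.0

    def __post_init__(self) -> None:
        if not float(self.fh_relative_risk) >= 1.0:
            raise ValueError(f"fh_relative_risk must be >= 1, got {self.fh_relative_risk}")
        if not 0.0 <= float(self.proportion_explained) <= 1.0:
            raise ValueError(
                f"proportion_explained must be in [0, 1], got {self.proportion_explained}"
            )

    @property
    def odds_deflator(self) -> float:
        """RR_FH ** pi, the double-counted share removed from prior odds."""
        return float(self.fh_relative_risk) ** float(self.proportion_explained)


def snp_lr(genotype_count: int, dist: GenotypeDistribution) -> float:
    """Likelihood ratio P(g|case)/P(g|control) for one genotype at one SNP."""
    g = int(genotype_count)
    if g not in (0, 1, 2):
        raise ValueError(f"genotype count must be 0, 1 or 2, got {genotype_count}")
    return float(dist.probs_cases[g] / dist.probs_controls[g])


def log_panel_lr(genotypes: np.ndarray, model: PanelGenotypeModel) -> np.ndarray:
    """Log multi-SNP LR for one genotype vector or a matrix of them.

    Accumulated as a sum of per-SNP log LRs (numerically robust for long
    panels where the naive product drifts).
    """
    return model.score(genotypes)


def panel_lr(genotypes: np.ndarray, model: PanelGenotypeModel) -> float | np.ndarray:
    """Multi-SNP likelihood ratio, product over independent loci."""
    log_lr = log_panel_lr(genotypes, model)
    lr = np.exp(log_lr)
    return float(lr[0]) if np.asarray(genotypes).ndim == 1 else lr


def _check_prior(prior):
    prior = np.asarray(prior, dtype=float)
    if np.any(prior <= 0.0) or np.any(prior >= 1.0):
        raise ValueError("prior risk must lie strictly inside (0, 1)")
    return prior


def posterior_risk(prior, lr):
    """Update an absolute risk by a likelihood ratio on the odds scale.

    ``posterior = odds / (1 + odds)`` with ``odds = prior/(1-prior) * lr``.
    Accepts scalars or arrays (broadcast); strictly increasing in both
    arguments and the identity when ``lr == 1``.
    """
    prior = _check_prior(prior)
    lr = np.asarray(lr, dtype=float)
    if np.any(lr <= 0.0):
        raise ValueError("likelihood ratio must be positive")
    odds = prior / (1.0 - prior) * lr
    post = odds / (1.0 + odds)
    return float(post) if post.ndim == 0 else post


def fh_adjusted_posterior(prior_with_fh, lr, adj: FamilyHistoryAdjustment):
    """Posterior risk for a woman whose prior already embeds family history.

    The prior odds are divided by ``fh_relative_risk ** proportion_explained``
    — the share of the family-history risk the panel re-measures — and the
    likelihood ratio is then applied as usual.  With
    ``proportion_explained = 0`` this reduces exactly to
    :func:`posterior_risk`.
    """
    if not isinstance(adj, FamilyHistoryAdjustment):
        adj = FamilyHistoryAdjustment(*adj)
    lr = np.asarray(lr, dtype=float)
    return posterior_risk(prior_with_fh, lr / adj.odds_deflator)


def estimate_proportion_explained(
    panel: SnpPanel,
    fh_relative_risk: float = 2.0,
    prevalence: float = 0.05,
) -> float:
    """Fraction of family-history log relative risk carried by the panel.

    The panel implies a mean likelihood ratio among family-history-positive
    women: each SNP's genotype distribution shifts to Hardy-Weinberg at its
    family-history-conditioned allele frequency, and independence makes the
    panel mean LR the product of per-SNP means.  The statistic is

        pi = log( E[LR | FH+] ) / log( RR_FH ),  clamped to [0, 1].

    Defined through the mean LR (not the mean log LR) so that deflating the
    prior odds by ``RR_FH ** pi`` exactly cancels the expected LR uplift of
    FH+ genotypes: averaging the adjusted posterior over FH-conditioned
    genotype draws restores the family-history prior.  A null panel gives 0;
    a panel carrying the whole familial relative risk gives 1.
    """
    if not float(fh_relative_risk) > 1.0:
        raise ValueError(f"fh_relative_risk must be > 1, got {fh_relative_risk}")
    model = PanelGenotypeModel(panel, prevalence)
    # per-SNP mean LR under HWE at the FH-conditioned frequency
    mean_lr = (model.fh * np.exp(model.log_lr)).sum(axis=1)
    log_mean = np.log(mean_lr).sum()
    return float(np.clip(log_mean / np.log(float(fh_relative_risk)), 0.0, 1.0))
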