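"""Per-SNP genotype distributions in population, cases and controls.

Under Hardy-Weinberg equilibrium a locus with risk-allele frequency ``p``
has population genotype probabilities ((1-p)^2, 2p(1-p), p^2) over 0/1/2
risk-allele copies.  With a per-allele relative risk ``gamma`` (multiplicative
across alleles, so per-genotype relative risks (1, gamma, gamma^2)) and
disease prevalence ``K``, the case and control genotype distributions are

    P(g | D+) = P(g) * gamma_g / sum_g P(g) gamma_g
    P(g | D-) = (P(g) - P(g | D+) * K) / (1 - K)

so that the mixture identity K*P(g|D+) + (1-K)*P(g|D-) = P(g) holds exactly.
The case expression approximates the true retrospective distribution and is
accurate while prevalence stays low; the model therefore refuses K > 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import SnpPanel, SnpRecord

__all__ = [
    "GenotypeDistribution",
    "PanelGenotypeModel",
    "hwe_genotype_freqs",
    "genotype_dist",
    "fh_conditioned_freq",
    "simulate_genotypes",
    "MAX_PREVALENCE",
]

MAX_PREVALENCE = 0.10
_STATUSES = ("population", "case", "control")


def _check_prevalence(prevalence: float) -> float:
    k = float(prevalence)
    if not 0.0 < k <= MAX_PREVALENCE:
        raise ValueError(
            f"prevalence must be in (0, {MAX_PREVALENCE}] (low-prevalence "
            f"approximation regime), got {prevalence}"
        )
    return k


def hwe_genotype_freqs(p: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


@dataclass(frozen=True)
class GenotypeDistribution:
    """Genotype probability triples for one SNP in three reference groups.

    Triples are ordered by risk-allele count (0, 1, 2).  ``probs_controls``
    is derived so the prevalence-weighted mixture of cases and controls
    reproduces the population triple exactly.
    """

    snp_id: str
    probs_population: np.ndarray
    probs_cases: np.ndarray
    probs_controls: np.ndarray
    prevalence: float

    @property
    def log_lr(self) -> np.ndarray:
        """Per-genotype log likelihood ratio log(P(g|D+)/P(g|D-))."""
        return np.log(self.probs_cases) - np.log(self.probs_controls)


def genotype_dist(snp: SnpRecord, prevalence: float = 0.05) -> GenotypeDistribution:
    """Population/case/control genotype triples for one SNP.

    Cases reweight the Hardy-Weinberg population triple by the per-genotype
    relative risks (1, gamma, gamma^2); controls are the complementary
    mixture component at prevalence ``prevalence``.
    """
    k = _check_prevalence(prevalence)
    pop = hwe_genotype_freqs(snp.risk_allele_freq)
    gamma = float(snp.odds_ratio)
    weights = pop * np.array([1.0, gamma, gamma * gamma])
    cases = weights / weights.sum()
    controls = (pop - cases * k) / (1.0 - k)
    if np.any(controls <= 0.0):
        raise ValueError(
            f"SNP {snp.snp_id!r}: control genotype probabilities are not all "
            f"positive at prevalence {k} (odds ratio too large for the "
            "low-prevalence approximation)"
        )
    return GenotypeDistribution(
        snp_id=snp.snp_id,
        probs_population=pop,
        probs_cases=cases,
        probs_controls=controls,
        prevalence=k,
    )


def fh_conditioned_freq(snp: SnpRecord, prevalence: float = 0.05) -> float:
    """Risk-allele frequency among women with an affected first-degree relative.

    The affected relative carries the case allele frequency
    ``p_case = P(g1|D+)/2 + P(g2|D+)``; a first-degree relative shares half
    her genome with the proband, so the proband inherits half of the case
    enrichment:

        p_FH = p + (p_case - p) / 2

    Equal to ``p`` when the SNP is null (gamma = 1) and strictly above ``p``
    whenever gamma > 1.
    """
    dist = genotype_dist(snp, prevalence)
    p = float(snp.risk_allele_freq)
    p_case = 0.5 * dist.probs_cases[1] + dist.probs_cases[2]
    return p + 0.5 * (p_case - p)


class PanelGenotypeModel:
    """Vectorised genotype triples for every SNP of a panel.

    Rows follow panel order; ``population``, ``cases`` and ``controls`` are
    (n_snps, 3) arrays, ``log_lr`` the per-genotype log likelihood ratios,
    ``fh`` the Hardy-Weinberg triples at the family-history-conditioned
    allele frequencies.
    """

    def __init__(self, panel: SnpPanel, prevalence: float = 0.05):
        self.panel = panel
        self.prevalence = _check_prevalence(prevalence)
        dists = [genotype_dist(snp, self.prevalence) for snp in panel]
        self.dists: list[GenotypeDistribution] = dists
        self.population = np.vstack([d.probs_population for d in dists])
        self.cases = np.vstack([d.probs_cases for d in dists])
        self.controls = np.vstack([d.probs_controls for d in dists])
        self.log_lr = np.log(self.cases) - np.log(self.controls)
        self.fh_freqs = np.array([fh_conditioned_freq(s, self.prevalence) for s in panel])
        self.fh = np.vstack([hwe_genotype_freqs(p) for p in self.fh_freqs])

    def triples(self, status: str) -> np.ndarray:
        if status == "population":
            return self.population
        if status == "case":
            return self.cases
        if status == "control":
            return self.controls
        if status == "fh":
            return self.fh
        raise ValueError(f"unknown status {status!r}; expected one of {_STATUSES + ('fh',)}")

    def draw(self, status: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an (n, n_snps) matrix of risk-allele counts, SNPs independent."""
        if n < 1:
            raise ValueError("n must be >= 1")
        triples = self.triples(status)
        cum0 = triples[:, 0]
        cum1 = triples[:, 0] + triples[:, 1]
        u = rng.random((n, len(self.panel)))
        return ((u > cum0).astype(np.uint8) + (u > cum1).astype(np.uint8))

    def score(self, genotypes: np.ndarray) -> np.ndarray:
        """Sum of per-SNP log LRs for each row of a genotype matrix."""
        genotypes = np.asarray(genotypes)
        if genotypes.ndim == 1:
            genotypes = genotypes[None, :]
        if genotypes.shape[1] != len(self.panel):
            raise ValueError(
                f"genotype vectors of length {genotypes.shape[1]} do not match "
                f"panel of size {len(self.panel)}"
            )
        snp_idx = np.arange(len(self.panel))
        return self.log_lr[snp_idx[None, :], genotypes.astype(np.intp)].sum(axis=1)


def simulate_genotypes(
    panel: SnpPanel,
    status: str,
    n: int,
    prevalence: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate ``n`` genotype vectors (rows) for a panel.

    Each SNP is drawn independently from its population, case or control
    triple according to ``status``.  Returns an (n, n_snps) uint8 matrix of
    risk-allele counts; deterministic given ``seed``.
    """
    if status not in _STATUSES:
        raise ValueError(f"unknown status {status!r}; expected one of {_STATUSES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return PanelGenotypeModel(panel, prevalence).draw(status, n, rng)
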