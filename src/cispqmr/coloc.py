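"""Approximate-Bayes-factor colocalization over a cis region.

Given summary statistics for two traits across the same set of variants,
the method assumes at most one causal variant per trait within the region
and compares five hypotheses: H0 no causal variant for either trait;
H1/H2 a causal variant for one trait only; H3 distinct causal variants;
H4 one shared causal variant.  Per-variant evidence enters through
Wakefield's approximate Bayes factor, and configuration sums weighted by
per-variant priors give posterior probabilities PP.H0..PP.H4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .summary_stats import RegionDataset, harmonize


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities and the effect-size prior SD.

    p1/p2: prior that a variant is causal for trait A / trait B alone;
    p12: prior that it is causal for both.  The effect prior SD of 0.15
    is the conventional choice for a standardized quantitative trait.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_effect_sd_quant: float = 0.15

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be below 1")
        if self.prior_effect_sd_quant <= 0:
            raise ValueError("prior effect SD must be positive")


HYPOTHESES = ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities for H0..H4 and the evidence tier."""

    pp: tuple[float, float, float, float, float]
    tier: str  # strong | weak | none
    n_snps: int

    @property
    def pp_h4(self) -> float:
        return self.pp[4]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(HYPOTHESES, self.pp))


def classify_tier(pp_h4: float, strong: float = 0.80,
                  weak: float = 0.50) -> str:
    if pp_h4 >= strong:
        return "strong"
    if pp_h4 >= weak:
        return "weak"
    return "none"


def wakefield_labf(beta: float | np.ndarray, se: float | np.ndarray,
                   prior_sd: float) -> float | np.ndarray:
    """Log approximate Bayes factor for one variant-trait association.

    With V = se^2, W = prior_sd^2 and z = beta/se:

        log ABF = 0.5 [ ln(V/(V+W)) + z^2 W/(V+W) ].

    Positive when the data support an effect against the point null.
    """
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se ** 2
    w = prior_sd ** 2
    z = np.asarray(beta, dtype=float) / se
    labf = 0.5 * (np.log(v / (v + w)) + z ** 2 * w / (v + w))
    return labf if labf.ndim else float(labf)


def coloc_from_arrays(labf_a: np.ndarray, labf_b: np.ndarray,
                      priors: ColocPriors = ColocPriors()) -> ColocResult:
    """Posterior probabilities from per-variant log Bayes factors.

    All arithmetic is in log space: with S1 = sum_j BF1_j,
    S2 = sum_j BF2_j and S12 = sum_j BF1_j BF2_j, the unnormalized
    hypothesis weights are (1, p1 S1, p2 S2, p1 p2 (S1 S2 - S12),
    p12 S12).  The H3 term sums over ordered pairs of distinct variants,
    hence the subtraction; with a single variant it vanishes exactly.
    """
    labf_a = np.asarray(labf_a, dtype=float)
    labf_b = np.asarray(labf_b, dtype=float)
    if labf_a.shape != labf_b.shape or labf_a.ndim != 1 or labf_a.size == 0:
        raise ValueError("labf arrays must be equal-length 1-D and non-empty")
    m = labf_a.size
    l_s1 = float(logsumexp(labf_a))
    l_s2 = float(logsumexp(labf_b))
    l_s12 = float(logsumexp(labf_a + labf_b))

    lw = np.empty(5)
    lw[0] = 0.0
    lw[1] = math.log(priors.p1) + l_s1
    lw[2] = math.log(priors.p2) + l_s2
    # log(S1 S2 - S12) via a stable log-diff-exp; exact zero for m == 1
    l_cross = l_s1 + l_s2
    diff = -math.expm1(min(l_s12 - l_cross, 0.0))  # 1 - S12/(S1 S2) >= 0
    if m == 1 or diff <= 0.0:
        lw[3] = -np.inf
    else:
        lw[3] = math.log(priors.p1) + math.log(priors.p2) + l_cross \
            + math.log(diff)
    lw[4] = math.log(priors.p12) + l_s12

    lw -= logsumexp(lw)
    pp = np.exp(lw)
    pp /= pp.sum()
    return ColocResult(pp=tuple(float(x) for x in pp),
                       tier=classify_tier(float(pp[4])), n_snps=m)


def coloc_abf(region_a: RegionDataset, region_b: RegionDataset,
              priors: ColocPriors = ColocPriors()) -> ColocResult:
    """Colocalization of two traits over their shared region variants.

    Variants are intersected by snp_id after allele harmonization (effect
    orientation does not change the Bayes factors, which are even in z,
    but strand-ambiguous variants are excluded the same way as in the MR
    steps).  Raises when no variant is shared.
    """
    pairs = [p for p in harmonize(region_a, region_b) if p.usable]
    if not pairs:
        raise ValueError(
            f"no shared SNPs between {region_a.trait_id} and "
            f"{region_b.trait_id} after harmonization")
    labf_a = np.array([wakefield_labf(p.exposure.beta, p.exposure.se,
                                      priors.prior_effect_sd_quant)
                       for p in pairs])
    labf_b = np.array([wakefield_labf(p.outcome.beta, p.outcome.se,
                                      priors.prior_effect_sd_quant)
                       for p in pairs])
    return coloc_from_arrays(labf_a, labf_b, priors)
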