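"""Summary-data-based MR on the top cis variant, and the HEIDI test.

The SMR statistic combines the exposure and outcome z-scores of the single
most strongly associated cis variant,

    T_SMR = z_X^2 z_Y^2 / (z_X^2 + z_Y^2)  ~  chi-square(1),

so evidence requires both associations to be strong.  A significant SMR
test is compatible with two genetic architectures: one variant affecting
both traits (causality or pleiotropy) or two distinct variants in linkage
disequilibrium.  The HEIDI test separates them by asking whether the
Wald ratios at surrounding cis variants are homogeneous with the top
variant's ratio — under a single shared causal variant they estimate the
same quantity, under linkage they do not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .summary_stats import (HarmonizedPair, LDMatrix, RegionDataset,
                            harmonize)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeidiConfig:
    """Candidate-SNP selection knobs for the HEIDI test.

    Defaults follow common SMR-software practice: candidates must show a
    cis association at p < 1.57e-3 (chi-square(1) > 10), sit in
    intermediate LD with the top SNP (0.05 <= r^2 <= 0.9 — tight LD makes
    the ratio difference degenerate, weak LD carries no information), and
    at most the 20 strongest are used.
    """

    pval_threshold: float = 1.57e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20
    min_snps: int = 3


@dataclass(frozen=True)
class SMRResult:
    protein_id: str
    top_snp: str
    beta_smr: float
    se_smr: float
    pval_smr: float
    heidi_pval: float | None = None
    n_heidi_snps: int = 0


def _pairs_or_harmonize(region_exposure: RegionDataset,
                        region_outcome: RegionDataset,
                        ) -> list[HarmonizedPair]:
    return [p for p in harmonize(region_exposure, region_outcome)
            if p.usable]


def smr_from_pair(pair: HarmonizedPair, protein_id: str) -> SMRResult:
    """SMR statistic for a chosen top variant."""
    zx = pair.exposure.zscore()
    zy = pair.outcome.zscore()
    beta_smr = pair.outcome.beta / pair.exposure.beta
    denom = zx * zx + zy * zy
    t_smr = (zx * zx * zy * zy / denom) if denom > 0 else 0.0
    pval = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    se = abs(beta_smr) / math.sqrt(t_smr) if t_smr > 0 else math.inf
    return SMRResult(protein_id=protein_id, top_snp=pair.snp_id,
                     beta_smr=beta_smr, se_smr=se, pval_smr=pval)


def smr_test(region_exposure: RegionDataset, region_outcome: RegionDataset,
             qtl_pval_threshold: float = 5e-8) -> SMRResult | None:
    """SMR on the top cis variant (smallest exposure p-value).

    Returns None when no harmonized variant reaches ``qtl_pval_threshold``
    for the exposure.
    """
    pairs = _pairs_or_harmonize(region_exposure, region_outcome)
    eligible = [p for p in pairs
                if p.exposure.pvalue() < qtl_pval_threshold]
    if not eligible:
        return None
    top = min(eligible, key=lambda p: (p.exposure.pvalue(), p.snp_id))
    return smr_from_pair(top, region_exposure.trait_id)


def imhof_tail(q: float, lam: np.ndarray) -> float:
    """P(sum_k lam_k chi2_1 > q) by Imhof's numeric inversion.

    Integrates sin(theta(u)) / (u rho(u)) over u in (0, inf) with
    theta(u) = (sum_k atan(lam_k u) - q u)/2 and
    rho(u) = prod_k (1 + lam_k^2 u^2)^(1/4).  Clipped to [0, 1].
    """
    lam = np.asarray([l for l in np.atleast_1d(lam) if abs(l) > 1e-12],
                     dtype=float)
    if lam.size == 0:
        return 1.0 if q <= 0 else 0.0
    if q <= 0:
        return 1.0

    def integrand(u: float) -> float:
        if u == 0.0:
            return 0.5 * (float(np.sum(lam)) - q)  # limit of sin(theta)/u
        theta = 0.5 * (np.sum(np.arctan(lam * u)) - q * u)
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return math.sin(theta) / (u * rho)

    # The integrand oscillates with asymptotic half-period 2*pi/q and its
    # envelope decays like u^-(1 + k/2).  Integrate half-period by
    # half-period: consecutive segments alternate in sign, so the slowly
    # converging tail is accelerated by repeated averaging of partial sums.
    period = 2.0 * math.pi / q
    total = 0.0
    partials: list[float] = []
    lo = 0.0
    for _ in range(300):
        hi = lo + period
        seg, _ = integrate.quad(integrand, lo, hi, epsabs=1e-13,
                                epsrel=1e-11, limit=200)
        total += seg
        partials.append(total)
        lo = hi
        if abs(seg) < 1e-13 and len(partials) > 5:
            break
    tail = partials[-12:]
    while len(tail) > 1:
        tail = [0.5 * (a + b) for a, b in zip(tail, tail[1:])]
    # Imhof: F(q) = 1/2 - (1/pi) * integral, so the tail is 1/2 + it
    return float(min(max(0.5 + tail[0] / math.pi, 0.0), 1.0))


def _wald_ratio_cov(bx: np.ndarray, sx: np.ndarray, by: np.ndarray,
                    sy: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Delta-method covariance of per-SNP Wald ratios b_i = by_i/bx_i.

    With two-sample (independent) exposure and outcome GWAS whose per-SNP
    effect estimates are correlated across SNPs through the LD matrix r:

        cov(b_i, b_j) = r_ij sy_i sy_j / (bx_i bx_j)
                      + r_ij by_i by_j sx_i sx_j / (bx_i^2 bx_j^2).
    """
    inv_bx = 1.0 / bx
    t1 = r * np.outer(sy * inv_bx, sy * inv_bx)
    t2 = r * np.outer(by * sx * inv_bx ** 2, by * sx * inv_bx ** 2)
    return t1 + t2


def heidi_test(region_exposure: RegionDataset, region_outcome: RegionDataset,
               ld: LDMatrix, config: HeidiConfig = HeidiConfig(),
               qtl_pval_threshold: float = 5e-8,
               ) -> tuple[float | None, int]:
    """Heterogeneity-in-dependent-instruments test around the top SNP.

    Candidate SNPs are cis variants with exposure p below the candidate
    threshold, excluding the top SNP, pruned to intermediate LD with it and
    capped at the strongest ``max_snps``.  For each candidate the
    difference d_i between its Wald ratio and the top SNP's is formed; the
    statistic Q = sum_i (d_i / SD(d_i))^2 is referred to the distribution
    of the corresponding quadratic form (weighted chi-square over the
    eigenvalues of the correlation matrix of the standardized d).

    Returns (heidi_pval, n_candidates_used); the p-value is None when
    fewer than ``min_snps`` usable candidates remain.
    """
    pairs = _pairs_or_harmonize(region_exposure, region_outcome)
    sig = [p for p in pairs if p.exposure.pvalue() < qtl_pval_threshold]
    if not sig:
        return None, 0
    top = min(sig, key=lambda p: (p.exposure.pvalue(), p.snp_id))
    if top.snp_id not in ld:
        logger.info("heidi: top SNP %s missing from LD matrix", top.snp_id)
        return None, 0

    cands = []
    for p in pairs:
        if p.snp_id == top.snp_id or p.snp_id not in ld:
            continue
        if p.exposure.pvalue() >= config.pval_threshold:
            continue
        r2 = ld.r2(p.snp_id, top.snp_id)
        if config.r2_min <= r2 <= config.r2_max:
            cands.append(p)
    cands.sort(key=lambda p: (p.exposure.pvalue(), p.snp_id))
    cands = cands[:config.max_snps]
    if len(cands) < config.min_snps:
        return None, len(cands)

    sel = [top] + cands
    ids = [p.snp_id for p in sel]
    bx = np.array([p.exposure.beta for p in sel])
    sx = np.array([p.exposure.se for p in sel])
    by = np.array([p.outcome.beta for p in sel])
    sy = np.array([p.outcome.se for p in sel])
    r = ld.submatrix(ids).r

    cov_b = _wald_ratio_cov(bx, sx, by, sy, r)
    b = by / bx
    d = b[1:] - b[0]
    # cov(d_i, d_j) = cov(b_i,b_j) - cov(b_i,b_T) - cov(b_j,b_T) + var(b_T)
    cov_d = (cov_b[1:, 1:] - cov_b[1:, :1] - cov_b[:1, 1:] + cov_b[0, 0])
    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    q = float(np.sum(z_d ** 2))
    corr_d = cov_d / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(0.5 * (corr_d + corr_d.T))
    return imhof_tail(q, lam), len(cands)
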