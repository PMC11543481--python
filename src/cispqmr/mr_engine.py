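"""Causal-effect estimation from harmonized summary statistics.

Implements the Wald ratio for single-instrument proteins, fixed-effect
inverse-variance-weighted (IVW) meta-analysis for two or more instruments
(equivalent to weighted least squares through the origin), Bonferroni
threshold arithmetic, the Steiger directionality test, and reverse-direction
MR by exchanging trait roles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import (InstrumentCriteria, InstrumentSet, compute_pve,
                          select_instruments)
from .summary_stats import HarmonizedPair, RegionDataset, zscore_pval

#: 95% CI multiplier (two-sided normal).
Z95 = 1.959964


@dataclass(frozen=True)
class MRResult:
    """A causal estimate in SD-outcome-per-SD-exposure units."""

    exposure_id: str
    outcome_id: str
    method: str  # wald_ratio | ivw
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    direction_ok: bool | None = None
    steiger_pval: float | None = None


def _finish(exposure_id: str, outcome_id: str, method: str, beta: float,
            se: float, n_snps: int) -> MRResult:
    return MRResult(exposure_id=exposure_id, outcome_id=outcome_id,
                    method=method, beta=beta, se=se,
                    ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
                    pval=zscore_pval(beta / se) if se > 0 else 0.0,
                    n_snps=n_snps)


def wald_ratio(pair: HarmonizedPair, exposure_id: str = "exposure",
               outcome_id: str = "outcome",
               second_order: bool = False) -> MRResult:
    """Single-instrument causal estimate beta_GY / beta_GX.

    The default standard error is the first-order Delta approximation
    SE_GY/|beta_GX|; ``second_order`` adds the exposure-uncertainty term
    sqrt(SE_GY^2/beta_GX^2 + beta_GY^2 SE_GX^2/beta_GX^4).
    """
    bx, by = pair.exposure.beta, pair.outcome.beta
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_GX = 0")
    beta = by / bx
    if second_order:
        se = math.sqrt(pair.outcome.se ** 2 / bx ** 2
                       + by ** 2 * pair.exposure.se ** 2 / bx ** 4)
    else:
        se = pair.outcome.se / abs(bx)
    return _finish(exposure_id, outcome_id, "wald_ratio", beta, se, 1)


def ivw(pairs: Sequence[HarmonizedPair], exposure_id: str = "exposure",
        outcome_id: str = "outcome", random_effects: bool = False,
        _allow_single: bool = False) -> MRResult:
    """Fixed-effect IVW estimate over two or more instruments.

    With weights w_j = 1/SE_GY,j^2 this is weighted least squares of the
    outcome effects on the exposure effects through the origin:

        beta = sum w_j bx_j by_j / sum w_j bx_j^2,
        se   = sqrt(1 / sum w_j bx_j^2).

    ``random_effects`` applies a multiplicative overdispersion factor,
    scaling the SE by max(1, residual SD of the weighted regression).
    """
    if len(pairs) < 2 and not _allow_single:
        raise ValueError("IVW needs at least two instruments; "
                         "use wald_ratio for one")
    if not pairs:
        raise ValueError("no instruments")
    bx = np.array([p.exposure.beta for p in pairs])
    by = np.array([p.outcome.beta for p in pairs])
    sy = np.array([p.outcome.se for p in pairs])
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / denom
    se = math.sqrt(1.0 / denom)
    if random_effects and len(pairs) > 1:
        resid = by - beta * bx
        phi = float(np.sum(w * resid ** 2)) / (len(pairs) - 1)
        se *= max(1.0, math.sqrt(phi))
    return _finish(exposure_id, outcome_id, "ivw", beta, se, len(pairs))


def mr_estimate(pairs: Sequence[HarmonizedPair], exposure_id: str = "exposure",
                outcome_id: str = "outcome", random_effects: bool = False,
                second_order_wald: bool = False) -> MRResult:
    """Dispatch on instrument count: one SNP -> Wald ratio, two+ -> IVW."""
    if not pairs:
        raise ValueError("no instruments")
    if len(pairs) == 1:
        return wald_ratio(pairs[0], exposure_id, outcome_id,
                          second_order=second_order_wald)
    return ivw(pairs, exposure_id, outcome_id, random_effects=random_effects)


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m_tests < 1:
        raise ValueError("m_tests must be at least 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m_tests


def _pair_r2(side, fallback_eaf: float | None) -> float:
    eaf = side.eaf if side.eaf is not None else fallback_eaf
    if eaf is None:
        raise ValueError("variance explained needs an allele frequency")
    return compute_pve(side.beta, side.se, eaf, side.n)


def steiger_test(pair: HarmonizedPair) -> tuple[bool, float]:
    """Directionality check: does the SNP explain more exposure variance?

    Compares the instrument's correlation with exposure and outcome via
    Fisher's z: z = (atanh|r_X| - atanh|r_Y|) / sqrt(1/(n_X-3) + 1/(n_Y-3)),
    two-sided.  direction_ok is True iff r_X^2 > r_Y^2 strictly.
    """
    if pair.exposure.n <= 3 or pair.outcome.n <= 3:
        raise ValueError("Steiger test needs n > 3 on both sides")
    r2x = _pair_r2(pair.exposure, pair.outcome.eaf)
    r2y = _pair_r2(pair.outcome, pair.exposure.eaf)
    z = ((math.atanh(math.sqrt(r2x)) - math.atanh(math.sqrt(r2y)))
         / math.sqrt(1.0 / (pair.exposure.n - 3)
                     + 1.0 / (pair.outcome.n - 3)))
    return r2x > r2y, float(zscore_pval(z))


def steiger_test_set(pairs: Sequence[HarmonizedPair]) -> tuple[bool, float]:
    """Steiger test over a clumped instrument set.

    Clumped instruments are approximately independent, so their explained
    variances add; the summed R^2 on each side enters the same Fisher-z
    comparison, with the per-trait n taken from the first pair.
    """
    if not pairs:
        raise ValueError("no instruments")
    r2x = sum(_pair_r2(p.exposure, p.outcome.eaf) for p in pairs)
    r2y = sum(_pair_r2(p.outcome, p.exposure.eaf) for p in pairs)
    r2x, r2y = min(r2x, 1.0 - 1e-12), min(r2y, 1.0 - 1e-12)
    nx, ny = pairs[0].exposure.n, pairs[0].outcome.n
    if nx <= 3 or ny <= 3:
        raise ValueError("Steiger test needs n > 3 on both sides")
    z = ((math.atanh(math.sqrt(r2x)) - math.atanh(math.sqrt(r2y)))
         / math.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3)))
    return r2x > r2y, float(zscore_pval(z))


def reverse_mr(outcome_as_exposure: RegionDataset,
               protein_as_outcome: RegionDataset,
               criteria: InstrumentCriteria = InstrumentCriteria(),
               ) -> MRResult | None:
    """Forward machinery with trait roles exchanged.

    Instruments are selected for the outcome trait (genome-wide significant
    variants in the region; the cis filter only applies when the
    role-reversed exposure carries gene coordinates) and the protein is
    treated as the outcome.  Returns None when no instrument survives.
    """
    iset = select_instruments(outcome_as_exposure, protein_as_outcome,
                              criteria)
    if len(iset) == 0:
        return None
    res = mr_estimate(iset.members,
                      exposure_id=outcome_as_exposure.trait_id,
                      outcome_id=protein_as_outcome.trait_id)
    return replace(res, method=res.method + "_reverse")
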