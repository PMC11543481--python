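"""Two-step mediation MR and sex-stratified effect comparison.

Mediation decomposes a protein's total effect on the outcome into an
indirect path through a mediator (here, BMI) and the remainder: step 1
estimates protein -> mediator, step 2 mediator -> outcome, and the
indirect effect is their product, with a first-order Delta-method
standard error.  The sex-stratified comparison tests equality of the
female and male causal estimates with a bilateral Z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mr_engine import MRResult, Z95
from .summary_stats import zscore_pval


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients mediation decomposition for one protein."""

    protein_id: str
    beta_step1: float       # protein -> mediator
    se_step1: float
    beta_step2: float       # mediator -> outcome
    se_step2: float
    beta_total: float       # protein -> outcome (forward MR)
    indirect: float         # beta_step1 * beta_step2
    se_indirect: float      # first-order Delta method
    ci_indirect: tuple[float, float]
    pval_indirect: float
    proportion_mediated: float | None
    proportion_flag: str    # ok | undefined_total | outside_unit_interval


@dataclass(frozen=True)
class SubgroupComparison:
    """Bilateral Z-test for a sex difference in causal effect."""

    beta_f: float
    se_f: float
    beta_m: float
    se_m: float
    z_stat: float
    pval: float


def two_step_mediation(step1: MRResult, step2: MRResult,
                       total: MRResult,
                       protein_id: str | None = None) -> MediationResult:
    """Indirect effect by the coefficient-product method.

    indirect = beta_step1 * beta_step2;
    se = sqrt(beta_step1^2 se_step2^2 + beta_step2^2 se_step1^2)
    (first order, no cross-step covariance: the two steps come from
    non-overlapping two-sample fits).  The proportion mediated is
    indirect/total and is reported as-is with a warning flag when the
    total is zero or the signs disagree.
    """
    a, sa = step1.beta, step1.se
    b, sb = step2.beta, step2.se
    indirect = a * b
    se_ind = math.sqrt(a * a * sb * sb + b * b * sa * sa)
    ci = (indirect - Z95 * se_ind, indirect + Z95 * se_ind)
    pval = float(zscore_pval(indirect / se_ind)) if se_ind > 0 else 1.0
    if total.beta == 0:
        prop, flag = None, "undefined_total"
    else:
        prop = indirect / total.beta
        flag = "ok" if 0.0 <= prop <= 1.0 else "outside_unit_interval"
    return MediationResult(
        protein_id=protein_id or step1.exposure_id,
        beta_step1=a, se_step1=sa, beta_step2=b, se_step2=sb,
        beta_total=total.beta, indirect=indirect, se_indirect=se_ind,
        ci_indirect=ci, pval_indirect=pval,
        proportion_mediated=prop, proportion_flag=flag)


def subgroup_z_test(beta_f: float, se_f: float, beta_m: float,
                    se_m: float) -> SubgroupComparison:
    """Test beta_f == beta_m given independent subgroup estimates.

    z = (beta_f - beta_m) / sqrt(se_f^2 + se_m^2), two-sided normal p.
    """
    if se_f <= 0 or se_m <= 0:
        raise ValueError("subgroup standard errors must be positive")
    z = (beta_f - beta_m) / math.sqrt(se_f * se_f + se_m * se_m)
    return SubgroupComparison(beta_f=beta_f, se_f=se_f, beta_m=beta_m,
                              se_m=se_m, z_stat=z,
                              pval=float(zscore_pval(z)))
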