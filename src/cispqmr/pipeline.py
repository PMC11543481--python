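"""Orchestration of the full proteome-wide MR workflow.

Per protein: instrument selection -> Wald/IVW MR -> proteome-wide
Bonferroni -> SMR with its own Bonferroni -> ABF colocalization ->
Steiger directionality and reverse MR -> optional mediation and
sex-stratified comparison.  A protein earns the strong-evidence tier when
it passes the MR Bonferroni threshold, the SMR Bonferroni threshold,
shows PP.H4 >= 0.80, has the correct Steiger direction, and the HEIDI
test (when computable) does not reject homogeneity at 0.05.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coloc import ColocPriors, ColocResult, coloc_abf
from .instruments import (InstrumentCriteria, InstrumentSet, select_instruments,
                          write_attrition)
from .mediation_subgroup import (MediationResult, SubgroupComparison,
                                 subgroup_z_test, two_step_mediation)
from .mr_engine import (MRResult, bonferroni_threshold, mr_estimate,
                        reverse_mr, steiger_test_set)
from .smr import HeidiConfig, SMRResult, heidi_test, smr_test
from .synthetic_data import SimulatedProtein, StudyBundle, load_study

logger = logging.getLogger(__name__)

HEIDI_ALPHA = 0.05
COLOC_STRONG = 0.80


@dataclass
class PipelineSettings:
    """Analysis knobs shared by every protein in one run."""

    criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    priors: ColocPriors = field(default_factory=ColocPriors)
    heidi: HeidiConfig = field(default_factory=HeidiConfig)
    alpha: float = 0.05
    #: SMR Bonferroni divisor; None -> count of MR-significant proteins
    smr_alpha_m: int | None = None
    random_effects_ivw: bool = False
    second_order_wald: bool = False
    run_reverse: bool = True
    run_mediation: bool = True
    run_subgroup: bool = True
    seed: int = 0


@dataclass
class ProteinReport:
    """All per-protein results plus the derived evidence tier."""

    protein_id: str
    status: str = "ok"  # ok | no_instruments | no_shared_snps
    n_instruments: int = 0
    mr: MRResult | None = None
    pass_bonferroni: bool = False
    smr: SMRResult | None = None
    pass_smr_bonferroni: bool = False
    coloc: ColocResult | None = None
    direction_ok: bool | None = None
    steiger_pval: float | None = None
    reverse: MRResult | None = None
    reverse_null_ok: bool | None = None
    mediation: MediationResult | None = None
    subgroup: SubgroupComparison | None = None
    tier: str = "none"  # strong-evidence | none


def derive_tier(report: ProteinReport, alpha: float = 0.05) -> str:
    """Strong evidence requires every line of support to hold at once."""
    ok = (report.pass_bonferroni
          and report.pass_smr_bonferroni
          and report.coloc is not None
          and report.coloc.pp_h4 >= COLOC_STRONG
          and bool(report.direction_ok)
          and (report.smr is None or report.smr.heidi_pval is None
               or report.smr.heidi_pval >= HEIDI_ALPHA))
    return "strong-evidence" if ok else "none"


def analyse_protein(prot: SimulatedProtein,
                    settings: PipelineSettings) -> ProteinReport:
    """Run every per-protein stage except the cross-protein thresholds."""
    rep = ProteinReport(protein_id=prot.protein_id)
    exposure, outcome = prot.exposure, prot.outcome

    iset = select_instruments(exposure, outcome, settings.criteria)
    rep.n_instruments = len(iset)
    if len(iset) == 0:
        rep.status = "no_instruments"
        logger.info("%s: no surviving instruments", prot.protein_id)
        return rep

    rep.mr = mr_estimate(iset.members, exposure_id=prot.protein_id,
                         outcome_id=outcome.trait_id,
                         random_effects=settings.random_effects_ivw,
                         second_order_wald=settings.second_order_wald)

    smr_res = smr_test(exposure, outcome, settings.criteria.pval_threshold)
    if smr_res is not None and exposure.ld is not None:
        hp, nh = heidi_test(exposure, outcome, exposure.ld, settings.heidi,
                            settings.criteria.pval_threshold)
        smr_res = dataclasses.replace(smr_res, heidi_pval=hp,
                                      n_heidi_snps=nh)
    rep.smr = smr_res

    try:
        rep.coloc = coloc_abf(exposure, outcome, settings.priors)
    except ValueError:
        rep.status = "no_shared_snps"
        logger.info("%s: no shared SNPs for colocalization",
                    prot.protein_id)

    rep.direction_ok, rep.steiger_pval = steiger_test_set(iset.members)

    if settings.run_reverse:
        rev = reverse_mr(outcome, exposure, settings.criteria)
        rep.reverse = rev
        # no reverse signal counts as consistent with forward causality
        rep.reverse_null_ok = rev is None or rev.pval >= settings.alpha

    if settings.run_subgroup and "outcome_female" in prot.regions \
            and "outcome_male" in prot.regions:
        mr_f = _forward_mr(prot, "outcome_female", settings)
        mr_m = _forward_mr(prot, "outcome_male", settings)
        if mr_f is not None and mr_m is not None:
            rep.subgroup = subgroup_z_test(mr_f.beta, mr_f.se,
                                           mr_m.beta, mr_m.se)
    return rep


def _forward_mr(prot: SimulatedProtein, role: str,
                settings: PipelineSettings) -> MRResult | None:
    iset = select_instruments(prot.exposure, prot.regions[role],
                              settings.criteria)
    if len(iset) == 0:
        return None
    return mr_estimate(iset.members, exposure_id=prot.protein_id,
                       outcome_id=prot.regions[role].trait_id,
                       random_effects=settings.random_effects_ivw,
                       second_order_wald=settings.second_order_wald)


def run_study(bundle: StudyBundle,
              settings: PipelineSettings | None = None,
              ) -> list[ProteinReport]:
    """Run the full pipeline over a study bundle, in a deterministic order.

    The proteome-wide MR Bonferroni threshold divides alpha by the total
    number of retained instruments across proteins (falling back to the
    number of tested proteins when instrument counts are unavailable);
    the SMR threshold divides alpha by the number of MR-significant
    proteins, recomputed per run.
    """
    settings = settings or PipelineSettings()
    reports = [analyse_protein(p, settings) for p in bundle.proteins]

    n_instruments = sum(r.n_instruments for r in reports)
    tested = [r for r in reports if r.mr is not None]
    m_mr = n_instruments if n_instruments > 0 else max(len(tested), 1)
    mr_thresh = bonferroni_threshold(settings.alpha, m_mr)
    for r in tested:
        r.pass_bonferroni = r.mr.pval < mr_thresh

    m_smr = settings.smr_alpha_m
    if m_smr is None:
        m_smr = sum(1 for r in tested if r.pass_bonferroni)
    if m_smr > 0:
        smr_thresh = bonferroni_threshold(settings.alpha, m_smr)
        for r in reports:
            if r.smr is not None:
                r.pass_smr_bonferroni = r.smr.pval_smr < smr_thresh

    if settings.run_mediation and bundle.mediator_region is not None:
        step2 = _mediation_step2(bundle, settings)
        if step2 is not None:
            for r, prot in zip(reports, bundle.proteins):
                if "mediator" in prot.regions and r.mr is not None:
                    step1 = _forward_mr(prot, "mediator", settings)
                    if step1 is not None:
                        r.mediation = two_step_mediation(
                            step1, step2, r.mr, protein_id=r.protein_id)

    for r in reports:
        r.tier = derive_tier(r, settings.alpha)

    # deterministic ranking: descending PP.H4, then ascending MR p, then id
    reports.sort(key=lambda r: (
        -(r.coloc.pp_h4 if r.coloc else -1.0),
        r.mr.pval if r.mr else 2.0,
        r.protein_id))
    logger.info("run_study: %d proteins, %d tested, %d MR-significant, "
                "%d strong-evidence (MR threshold %.3g over %d tests)",
                len(reports), len(tested),
                sum(r.pass_bonferroni for r in reports),
                sum(r.tier == "strong-evidence" for r in reports),
                mr_thresh, m_mr)
    return reports


def _mediation_step2(bundle: StudyBundle,
                     settings: PipelineSettings) -> MRResult | None:
    med = bundle.mediator_region
    iset = select_instruments(med.exposure, med.outcome, settings.criteria)
    if len(iset) == 0:
        logger.warning("mediator region has no instruments; mediation skipped")
        return None
    return mr_estimate(iset.members, exposure_id="MEDIATOR",
                       outcome_id=med.outcome.trait_id,
                       random_effects=settings.random_effects_ivw,
                       second_order_wald=settings.second_order_wald)


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationRecord:
    protein_id: str
    status: str  # replicated | not_replicated | not_testable
    beta: float | None = None
    pval: float | None = None
    direction_concordant: bool | None = None


def external_validation_run(primary: Sequence[ProteinReport],
                            alternative: StudyBundle,
                            settings: PipelineSettings | None = None,
                            ) -> list[ValidationRecord]:
    """Re-run forward MR on alternative inputs and flag replication.

    Replication means nominal significance (p < alpha) with the same
    effect direction as the primary estimate.  A protein absent from the
    alternative bundle is recorded as not testable.
    """
    settings = settings or PipelineSettings()
    alt = {p.protein_id: p for p in alternative.proteins}
    out: list[ValidationRecord] = []
    for rep in primary:
        if rep.mr is None:
            continue
        prot = alt.get(rep.protein_id)
        if prot is None:
            out.append(ValidationRecord(rep.protein_id, "not_testable"))
            continue
        iset = select_instruments(prot.exposure, prot.outcome,
                                  settings.criteria)
        if len(iset) == 0:
            out.append(ValidationRecord(rep.protein_id, "not_testable"))
            continue
        mr = mr_estimate(iset.members, exposure_id=rep.protein_id,
                         outcome_id=prot.outcome.trait_id,
                         random_effects=settings.random_effects_ivw,
                         second_order_wald=settings.second_order_wald)
        concordant = (mr.beta * rep.mr.beta) > 0
        replicated = concordant and mr.pval < settings.alpha
        out.append(ValidationRecord(
            rep.protein_id,
            "replicated" if replicated else "not_replicated",
            beta=mr.beta, pval=mr.pval,
            direction_concordant=concordant))
    return out


# ---------------------------------------------------------------------------
# Output tables, logging, file-driven entry point
# ---------------------------------------------------------------------------

def reports_to_frame(reports: Sequence[ProteinReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row: dict = {"protein": r.protein_id, "status": r.status,
                     "tier": r.tier, "nsnp": r.n_instruments}
        if r.mr is not None:
            row.update(method=r.mr.method, beta=r.mr.beta, se=r.mr.se,
                       ci_low=r.mr.ci_low, ci_high=r.mr.ci_high,
                       pval=r.mr.pval, pass_bonferroni=r.pass_bonferroni)
        if r.smr is not None:
            row.update(top_snp=r.smr.top_snp, beta_smr=r.smr.beta_smr,
                       p_smr=r.smr.pval_smr,
                       pass_smr_bonferroni=r.pass_smr_bonferroni,
                       p_heidi=r.smr.heidi_pval,
                       n_heidi_snps=r.smr.n_heidi_snps)
        if r.coloc is not None:
            row.update(r.coloc.as_dict())
            row["coloc_tier"] = r.coloc.tier
        row.update(steiger_pval=r.steiger_pval, direction_ok=r.direction_ok)
        if r.reverse is not None:
            row.update(reverse_beta=r.reverse.beta, reverse_p=r.reverse.pval)
        if r.mediation is not None:
            m = r.mediation
            row.update(med_indirect=m.indirect, med_se=m.se_indirect,
                       med_prop=m.proportion_mediated,
                       med_flag=m.proportion_flag)
        if r.subgroup is not None:
            s = r.subgroup
            row.update(beta_female=s.beta_f, beta_male=s.beta_m,
                       subgroup_z=s.z_stat, subgroup_p=s.pval)
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(reports: Sequence[ProteinReport],
                  out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = reports_to_frame(reports)
    path = out / "report.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


def setup_logging(log_file: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def run_pipeline(study_dir: str | Path, out_dir: str | Path,
                 settings: PipelineSettings | None = None,
                 ) -> list[ProteinReport]:
    """File-driven pipeline: load a study directory, analyse, write TSVs."""
    settings = settings or PipelineSettings()
    bundle = load_study(study_dir)
    reports = run_study(bundle, settings)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_reports(reports, out)
    isets = []
    for prot in bundle.proteins:
        isets.append(select_instruments(prot.exposure, prot.outcome,
                                        settings.criteria))
    write_attrition(isets, out / "attrition.tsv")
    return reports
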