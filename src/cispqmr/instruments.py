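"""Selection of valid cis instruments per protein.

A variant qualifies as an instrument for a protein when it (1) reaches
genome-wide significance for the protein, (2) lies within a window of the
protein-coding gene (cis), (3) falls outside the MHC region, (4) survives
allele harmonization with the outcome, (5) is independent of stronger
instruments after greedy LD clumping, and (6) has a single-SNP F statistic
above the weak-instrument threshold.  The module also provides the
instrument-strength statistics (PVE/R-squared and F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .summary_stats import (HarmonizedPair, LDMatrix, RegionDataset,
                            VariantAssociation, harmonize)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstrumentCriteria:
    """Thresholds defining a valid cis instrument."""

    pval_threshold: float = 5e-8
    clump_r2: float = 0.001
    cis_window_bp: int = 1_000_000
    min_f_stat: float = 10.0
    mhc_chrom: str = "6"
    mhc_start_bp: int = 26_000_000
    mhc_end_bp: int = 34_000_000
    palindrome_af_window: float = 0.08

    def __post_init__(self) -> None:
        if min(self.pval_threshold, self.clump_r2, self.cis_window_bp,
               self.min_f_stat) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.mhc_start_bp >= self.mhc_end_bp:
            raise ValueError("mhc_start_bp must be below mhc_end_bp")


@dataclass
class InstrumentSet:
    """Clumped, harmonized instruments for one protein with strength stats."""

    protein_id: str
    members: list[HarmonizedPair]
    f_stats: list[float]
    pve: list[float]
    #: (stage, n_before, n_after) counts, in application order.
    attrition: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def compute_pve(beta: float, se: float, eaf: float, n: float) -> float:
    """Proportion of trait variance explained by one variant.

    Standard two-sample approximation for a standardized trait,

        R^2 = 2f(1-f) beta^2 / (2f(1-f) beta^2 + 2f(1-f) se^2 n),

    which reduces to z^2/(z^2 + n) with z = beta/se.  Clipped to [0, 1].
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"monomorphic variant (eaf={eaf})")
    if se <= 0:
        raise ValueError("se must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    het = 2.0 * eaf * (1.0 - eaf)
    num = het * beta * beta
    r2 = num / (num + het * se * se * n)
    return min(max(r2, 0.0), 1.0)


def compute_f_stat(r2: float, n: float, k_instruments: int = 1) -> float:
    """Instrument-strength F statistic from explained variance.

    F = (n - 1 - k)/k * r2/(1 - r2) for k instruments jointly explaining
    a fraction r2 of the exposure variance in a sample of size n.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2={r2} must lie in [0, 1)")
    if n <= k_instruments + 1:
        raise ValueError("n must exceed k_instruments + 1")
    return (n - 1 - k_instruments) / k_instruments * r2 / (1.0 - r2)


def ld_clump(candidates: Sequence[VariantAssociation], ld: LDMatrix | None,
             r2_threshold: float) -> list[str]:
    """Greedy LD clumping; returns retained snp_ids.

    Candidates are visited in ascending p-value order (ties broken by
    snp_id, so the result is deterministic); a SNP is accepted iff its
    r-squared with every previously accepted SNP is below ``r2_threshold``.
    With no LD matrix all candidates are treated as independent.  A SNP
    absent from the LD matrix is dropped and logged.
    """
    ordered = sorted(candidates, key=lambda v: (v.pval, v.snp_id))
    if ld is None:
        if len(ordered) > 1:
            logger.warning("ld_clump: no LD matrix; %d candidates kept as "
                           "independent", len(ordered))
        return [v.snp_id for v in ordered]
    kept: list[str] = []
    for v in ordered:
        if v.snp_id not in ld:
            logger.info("ld_clump: %s missing from LD matrix, dropped",
                        v.snp_id)
            continue
        if all(ld.r2(v.snp_id, k) < r2_threshold for k in kept):
            kept.append(v.snp_id)
    return kept


def _in_cis_window(rec: VariantAssociation, region: RegionDataset,
                   window: int) -> bool:
    # closed interval [gene_start - W, gene_end + W], positions 1-based
    return (rec.chrom == region.gene_chrom
            and region.gene_start - window <= rec.pos
            <= region.gene_end + window)


def _in_mhc(rec: VariantAssociation, crit: InstrumentCriteria) -> bool:
    return (rec.chrom == crit.mhc_chrom
            and crit.mhc_start_bp <= rec.pos <= crit.mhc_end_bp)


def select_instruments(protein: RegionDataset, outcome: RegionDataset,
                       criteria: InstrumentCriteria = InstrumentCriteria(),
                       ) -> InstrumentSet:
    """Apply all instrument criteria for one protein against one outcome.

    Stages, in order: genome-wide significance; cis window around the gene
    body (skipped, with a log message, when the region has no gene
    coordinates, as in reverse-direction runs); MHC exclusion; allele
    harmonization with the outcome; greedy LD clumping; single-SNP F
    filter.  Returns a possibly-empty set with per-stage attrition counts.
    """
    attrition: list[tuple[str, int, int]] = []

    def stage(name: str, before: int, after: int) -> None:
        attrition.append((name, before, after))

    cand = list(protein.records)
    sig = [r for r in cand if r.pval < criteria.pval_threshold]
    stage("pval", len(cand), len(sig))

    if protein.gene_chrom is not None and protein.gene_start is not None:
        cis = [r for r in sig
               if _in_cis_window(r, protein, criteria.cis_window_bp)]
    else:
        logger.info("select_instruments %s: no gene coordinates; cis filter "
                    "skipped", protein.trait_id)
        cis = sig
    stage("cis", len(sig), len(cis))

    non_mhc = [r for r in cis if not _in_mhc(r, criteria)]
    stage("mhc", len(cis), len(non_mhc))

    sub = RegionDataset(trait_id=protein.trait_id,
                        trait_kind=protein.trait_kind,
                        gene_chrom=protein.gene_chrom,
                        gene_start=protein.gene_start,
                        gene_end=protein.gene_end,
                        records=sorted(non_mhc,
                                       key=lambda r: (r.pval, r.snp_id)))
    pairs = harmonize(sub, outcome, criteria.palindrome_af_window)
    usable = {p.snp_id: p for p in pairs if p.usable}
    stage("harmonize", len(non_mhc), len(usable))

    clump_input = [r for r in sub.records if r.snp_id in usable]
    kept_ids = ld_clump(clump_input, protein.ld, criteria.clump_r2)
    stage("clump", len(usable), len(kept_ids))

    members: list[HarmonizedPair] = []
    f_stats: list[float] = []
    pves: list[float] = []
    rec_by_id = sub.by_snp()
    for sid in kept_ids:
        rec = rec_by_id[sid]
        if rec.eaf is None:
            logger.info("select_instruments %s: %s has no eaf, F "
                        "uncomputable, dropped", protein.trait_id, sid)
            continue
        r2 = compute_pve(rec.beta, rec.se, rec.eaf, rec.n)
        f = compute_f_stat(r2, rec.n, 1)
        if f > criteria.min_f_stat:
            members.append(usable[sid])
            f_stats.append(f)
            pves.append(r2)
    stage("f_stat", len(kept_ids), len(members))

    return InstrumentSet(protein_id=protein.trait_id, members=members,
                         f_stats=f_stats, pve=pves, attrition=attrition)


def write_attrition(sets: Sequence[InstrumentSet], path: str | Path) -> None:
    """Attrition report TSV: one row per (protein, stage)."""
    rows = [{"protein": s.protein_id, "stage": st, "n_before": b, "n_after": a}
            for s in sets for st, b, a in s.attrition]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
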