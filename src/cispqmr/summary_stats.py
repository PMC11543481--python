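"""Data model, file I/O and allele harmonization for GWAS summary statistics.

The atoms of every analysis in this package are per-variant marginal
associations (beta, SE, p, allele pair, frequency, sample size) for one
trait, grouped into cis regions around a protein-coding gene, optionally
with a matching LD correlation matrix.  Files are plain tab-separated
tables with configurable column names; LD matrices are square TSV tables
keyed by SNP id on both axes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: p-values below this are floored to avoid log-domain underflow.
PVAL_FLOOR = 1e-300

#: Relative tolerance for the consistency check between a stated p-value
#: and the two-sided normal tail implied by beta/se.
PVAL_REL_TOL = 0.10

#: Default column names for summary-statistic TSV files.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

REQUIRED_FIELDS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "pval", "n")


def zscore_pval(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal tail probability of a z-score, floored at PVAL_FLOOR."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, PVAL_FLOOR) if np.ndim(p) else max(float(p), PVAL_FLOOR)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's marginal association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float

    def zscore(self) -> float:
        return self.beta / self.se

    def problems(self) -> list[str]:
        """Invariant violations, empty when the record is valid."""
        out: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            out.append(f"effect allele {self.effect_allele!r} not in ACGT")
        if self.other_allele not in VALID_ALLELES:
            out.append(f"other allele {self.other_allele!r} not in ACGT")
        if self.effect_allele == self.other_allele:
            out.append("effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            out.append(f"se={self.se} not positive")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append(f"eaf={self.eaf} outside [0,1]")
        if not (0.0 < self.pval <= 1.0):
            out.append(f"pval={self.pval} outside (0,1]")
        if not (self.n > 0):
            out.append(f"n={self.n} not positive")
        if self.pos <= 0:
            out.append(f"pos={self.pos} not positive (1-based)")
        if not out and math.isfinite(self.beta):
            implied = zscore_pval(self.beta / self.se)
            stated = max(self.pval, PVAL_FLOOR)
            if abs(stated - implied) > PVAL_REL_TOL * implied:
                out.append(
                    f"pval {stated:.3g} inconsistent with |beta/se| tail {implied:.3g}")
        return out


@dataclass
class LDMatrix:
    """Square matrix of pairwise LD correlations r, labelled by SNP id.

    Symmetric with unit diagonal; positive semi-definite to an eigenvalue
    floor of -1e-8 (repaired on read).
    """

    snp_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = tuple(self.snp_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match "
                             f"{m} SNP ids")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != m:
            raise ValueError("duplicate SNP ids in LD matrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.corr(a, b) ** 2

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(tuple(snp_ids), self.r[np.ix_(idx, idx)])


@dataclass
class RegionDataset:
    """All variant associations for one trait in one cis region."""

    trait_id: str
    trait_kind: str = "protein"  # protein | outcome | mediator
    gene_chrom: str | None = None
    gene_start: int | None = None
    gene_end: int | None = None
    records: list[VariantAssociation] = field(default_factory=list)
    ld: LDMatrix | None = None

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate snp_ids in region {self.trait_id}")
        if self.ld is not None:
            missing = set(self.ld.snp_ids) - set(ids)
            if missing:
                raise ValueError(
                    f"LD labels absent from records: {sorted(missing)[:5]}")

    def by_snp(self) -> dict[str, VariantAssociation]:
        return {r.snp_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SideStats:
    """One side (exposure or outcome) of a harmonized pair."""

    beta: float
    se: float
    eaf: float | None
    n: float

    def zscore(self) -> float:
        return self.beta / self.se

    def pvalue(self) -> float:
        return float(zscore_pval(self.zscore()))


@dataclass(frozen=True)
class HarmonizedPair:
    """Allele-aligned exposure/outcome statistics for one SNP.

    When status is ``kept`` or ``flipped`` both sides refer to the same
    effect allele (the exposure's).
    """

    snp_id: str
    exposure: SideStats
    outcome: SideStats
    status: str  # kept | flipped | dropped_palindromic | dropped_incompatible

    @property
    def usable(self) -> bool:
        return self.status in ("kept", "flipped")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_summary_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       trait_id: str | None = None,
                       trait_kind: str = "protein",
                       gene_chrom: str | None = None,
                       gene_start: int | None = None,
                       gene_end: int | None = None) -> RegionDataset:
    """Read a tab-separated summary-statistics table into a RegionDataset.

    ``column_map`` maps field names (keys of DEFAULT_COLUMNS) to the column
    names used in the file; unmapped fields fall back to the defaults.
    Rows violating record invariants are dropped and counted in the log.
    A missing required column or an empty file is fatal.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cols["snp_id"]: str,
                                            cols["chrom"]: str},
                     float_precision="round_trip")
    for fld in REQUIRED_FIELDS:
        if cols[fld] not in df.columns:
            raise ValueError(f"{path}: required column {cols[fld]!r} "
                             f"(field {fld}) missing")
    if df.empty:
        raise ValueError(f"{path}: empty summary-statistics file")
    has_eaf = cols["eaf"] in df.columns
    records: list[VariantAssociation] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        eaf = row.get(cols["eaf"]) if has_eaf else None
        if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
            eaf = None
        rec = VariantAssociation(
            snp_id=str(row[cols["snp_id"]]),
            chrom=str(row[cols["chrom"]]),
            pos=int(row[cols["pos"]]),
            effect_allele=str(row[cols["effect_allele"]]).upper(),
            other_allele=str(row[cols["other_allele"]]).upper(),
            eaf=None if eaf is None else float(eaf),
            beta=float(row[cols["beta"]]),
            se=float(row[cols["se"]]),
            pval=max(float(row[cols["pval"]]), PVAL_FLOOR),
            n=float(row[cols["n"]]),
        )
        probs = rec.problems()
        if probs:
            n_dropped += 1
            logger.info("%s: dropped %s: %s", path.name, rec.snp_id,
                        "; ".join(probs))
        else:
            records.append(rec)
    if n_dropped:
        logger.warning("%s: dropped %d/%d rows failing invariants",
                       path.name, n_dropped, len(df))
    return RegionDataset(trait_id=trait_id or path.stem,
                         trait_kind=trait_kind,
                         gene_chrom=gene_chrom, gene_start=gene_start,
                         gene_end=gene_end, records=records)


def write_summary_table(dataset: RegionDataset, path: str | Path,
                        column_map: Mapping[str, str] | None = None) -> None:
    """Write a RegionDataset as a TSV readable by :func:`read_summary_table`.

    Floats are written with repr precision so a round trip preserves all
    fields exactly.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    rows = []
    for r in dataset.records:
        rows.append({cols["snp_id"]: r.snp_id, cols["chrom"]: r.chrom,
                     cols["pos"]: r.pos, cols["effect_allele"]: r.effect_allele,
                     cols["other_allele"]: r.other_allele,
                     cols["eaf"]: "" if r.eaf is None else repr(r.eaf),
                     cols["beta"]: repr(r.beta), cols["se"]: repr(r.se),
                     cols["pval"]: repr(r.pval), cols["n"]: repr(r.n)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square LD correlation table keyed by SNP id.

    The matrix is symmetrized as (M + M^T)/2, the diagonal forced to 1 and
    negative eigenvalues floored at 0 (PSD repair).  A non-square table is
    fatal.
    """
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: LD matrix not square {df.shape}")
    ids = tuple(str(s) for s in df.index)
    if tuple(str(s) for s in df.columns) != ids:
        raise ValueError(f"{path}: LD row and column labels differ")
    m = df.to_numpy(dtype=float)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    w, v = np.linalg.eigh(m)
    if w.min() < -1e-8:
        w = np.maximum(w, 0.0)
        m = (v * w) @ v.T
        m = 0.5 * (m + m.T)
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        np.fill_diagonal(m, 1.0)
    return LDMatrix(ids, np.clip(m, -1.0, 1.0))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t")


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def _ambiguous_freq(eaf: float | None, window: float) -> bool:
    """Ambiguity rule for palindromic SNPs: MAF within `window` of 0.5.

    Missing frequency cannot be resolved, so it counts as ambiguous
    (conservative drop).
    """
    if eaf is None:
        return True
    return min(eaf, 1.0 - eaf) > 0.5 - window


def _flip_outcome(out: SideStats) -> SideStats:
    return SideStats(beta=-out.beta, se=out.se,
                     eaf=None if out.eaf is None else 1.0 - out.eaf, n=out.n)


def harmonize(exposure: RegionDataset, outcome: RegionDataset,
              palindrome_af_window: float = 0.08) -> list[HarmonizedPair]:
    """Align outcome effect alleles to the exposure's, SNP by SNP.

    For every SNP id present in both datasets: same-orientation pairs are
    kept; swapped-allele pairs get the outcome beta negated and frequency
    reflected (status ``flipped``); strand flips (allele complements) are
    applied to non-palindromic mismatches before declaring a pair
    incompatible.  Palindromic SNPs (A/T or C/G) whose allele frequency is
    within ``palindrome_af_window`` of 0.5 are dropped as strand-ambiguous;
    unambiguous palindromic SNPs are oriented by frequency.  Drops are
    recorded in the returned pairs, never raised.
    """
    if not (0.0 <= palindrome_af_window < 0.5):
        raise ValueError("palindrome_af_window must be in [0, 0.5)")
    out_by_snp = outcome.by_snp()
    pairs: list[HarmonizedPair] = []
    for exp in exposure.records:
        out = out_by_snp.get(exp.snp_id)
        if out is None:
            continue
        e_side = SideStats(exp.beta, exp.se, exp.eaf, exp.n)
        o_side = SideStats(out.beta, out.se, out.eaf, out.n)
        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_y, oa_y = out.effect_allele, out.other_allele

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                status = "dropped_incompatible"
            elif (_ambiguous_freq(exp.eaf, palindrome_af_window)
                  or _ambiguous_freq(out.eaf, palindrome_af_window)):
                status = "dropped_palindromic"
            else:
                # orient by which side of 0.5 the frequencies fall on
                same_axis = (ea_y == ea_x)
                freq_agrees = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
                if same_axis == freq_agrees:
                    status = "kept" if same_axis else "flipped"
                else:
                    # label and frequency orientation disagree: the strand
                    # differs, so trust the frequency
                    status = "kept" if freq_agrees else "flipped"
                if status == "flipped":
                    o_side = _flip_outcome(o_side)
            pairs.append(HarmonizedPair(exp.snp_id, e_side, o_side, status))
            continue

        if (ea_y, oa_y) == (ea_x, oa_x):
            status = "kept"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            status = "flipped"
            o_side = _flip_outcome(o_side)
        else:
            # try a strand flip of the outcome alleles
            cy = (COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y))
            if cy == (ea_x, oa_x):
                status = "kept"
            elif cy == (oa_x, ea_x):
                status = "flipped"
                o_side = _flip_outcome(o_side)
            else:
                status = "dropped_incompatible"
        pairs.append(HarmonizedPair(exp.snp_id, e_side, o_side, status))
    n_drop = sum(not p.usable for p in pairs)
    if n_drop:
        logger.info("harmonize %s vs %s: %d/%d pairs dropped",
                    exposure.trait_id, outcome.trait_id, n_drop, len(pairs))
    return pairs


def write_harmonized(pairs: Iterable[HarmonizedPair],
                     path: str | Path) -> None:
    """Write harmonized pairs (all statuses) as a TSV."""
    rows = []
    for p in pairs:
        rows.append({
            "SNP": p.snp_id, "status": p.status,
            "beta_exposure": repr(p.exposure.beta),
            "se_exposure": repr(p.exposure.se),
            "eaf_exposure": "" if p.exposure.eaf is None else repr(p.exposure.eaf),
            "n_exposure": repr(p.exposure.n),
            "beta_outcome": repr(p.outcome.beta),
            "se_outcome": repr(p.outcome.se),
            "eaf_outcome": "" if p.outcome.eaf is None else repr(p.outcome.eaf),
            "n_outcome": repr(p.outcome.n),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
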