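"""Shared builders for summary-statistic test fixtures."""

from __future__ import annotations

import logging

import pytest

from cispqmr.summary_stats import (HarmonizedPair, RegionDataset, SideStats,
                                   VariantAssociation, zscore_pval)

logging.disable(logging.INFO)


def make_variant(snp_id: str = "rs1", chrom: str = "1", pos: int = 50_000_000,
                 ea: str = "A", oa: str = "G", eaf: float | None = 0.3,
                 beta: float = 0.1, se: float = 0.01,
                 pval: float | None = None,
                 n: float = 33_000.0) -> VariantAssociation:
    """A valid variant record; p-value derived from beta/se unless given."""
    if pval is None:
        pval = zscore_pval(beta / se) if se > 0 else 0.5
    return VariantAssociation(snp_id=snp_id, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa, eaf=eaf,
                              beta=beta, se=se, pval=pval, n=n)


def make_region(records, trait_id: str = "PROT", trait_kind: str = "protein",
                gene_chrom: str | None = "1",
                gene_start: int | None = 50_000_000,
                gene_end: int | None = 50_010_000,
                ld=None) -> RegionDataset:
    return RegionDataset(trait_id=trait_id, trait_kind=trait_kind,
                         gene_chrom=gene_chrom, gene_start=gene_start,
                         gene_end=gene_end, records=list(records), ld=ld)


def make_pair(bx: float, sx: float, by: float, sy: float,
              eaf: float = 0.3, nx: float = 33_000.0, ny: float = 426_824.0,
              snp_id: str = "rs1", status: str = "kept") -> HarmonizedPair:
    return HarmonizedPair(snp_id=snp_id,
                          exposure=SideStats(bx, sx, eaf, nx),
                          outcome=SideStats(by, sy, eaf, ny),
                          status=status)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def region_factory():
    return make_region


@pytest.fixture
def pair_factory():
    return make_pair
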