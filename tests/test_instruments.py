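"""Instrument strength statistics, LD clumping and the five IV criteria."""

import itertools
import random

import numpy as np
import pytest

from cispqmr.instruments import (InstrumentCriteria, compute_f_stat,
                                 compute_pve, ld_clump, select_instruments)
from cispqmr.summary_stats import LDMatrix
from cispqmr.synthetic_data import make_ld

from conftest import make_region, make_variant


class TestPVE:
    def test_zero_beta_explains_nothing(self):
        assert compute_pve(0.0, 0.01, 0.3, 1000) == 0.0

    def test_matches_z_squared_form(self):
        # direct evaluation, cross-checked against z^2/(z^2+n)
        beta, se, eaf, n = 0.1, 0.004472, 0.3, 50_000
        z = beta / se
        expected = z * z / (z * z + n)
        assert compute_pve(beta, se, eaf, n) == pytest.approx(expected,
                                                              rel=1e-12)
        assert compute_pve(beta, se, eaf, n) == pytest.approx(0.00990,
                                                              abs=5e-5)

    @pytest.mark.parametrize("eaf", [0.05, 0.2, 0.49])
    def test_symmetric_in_allele_frequency(self, eaf):
        assert compute_pve(0.08, 0.01, eaf, 5000) == pytest.approx(
            compute_pve(0.08, 0.01, 1 - eaf, 5000), rel=1e-12)

    def test_monomorphic_is_an_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_pve(0.1, 0.01, 0.0, 1000)


class TestFStat:
    def test_zero_r2_gives_zero(self):
        assert compute_f_stat(0.0, 1000, 1) == 0.0

    def test_direct_evaluation(self):
        assert compute_f_stat(0.0042, 50_000, 1) == pytest.approx(210.9,
                                                                  abs=0.1)

    def test_monotone_in_r2(self):
        grid = [compute_f_stat(r2, 10_000, 1)
                for r2 in np.linspace(0, 0.5, 20)]
        assert all(b > a for a, b in zip(grid, grid[1:]))

    def test_r2_of_one_is_an_error(self):
        with pytest.raises(ValueError):
            compute_f_stat(1.0, 1000, 1)


def _brute_force_clump_check(cands, ld, threshold, retained):
    """The greedy result must be valid, maximal, and p-dominant."""
    kept = set(retained)
    order = {v.snp_id: i for i, v in
             enumerate(sorted(cands, key=lambda v: (v.pval, v.snp_id)))}
    # valid: no retained pair conflicts
    for a, b in itertools.combinations(retained, 2):
        assert ld.r2(a, b) < threshold
    # maximal + p-dominant: every excluded SNP conflicts with a retained
    # SNP of strictly better rank
    for v in cands:
        if v.snp_id in kept:
            continue
        assert any(ld.r2(v.snp_id, k) >= threshold
                   and order[k] < order[v.snp_id] for k in retained)


class TestLDClump:
    def test_uncorrelated_candidates_all_retained(self):
        cands = [make_variant(snp_id=f"rs{i}", pos=1000 + i,
                              pval=10.0 ** -(8 + i)) for i in range(4)]
        ld = LDMatrix(tuple(f"rs{i}" for i in range(4)), np.eye(4))
        assert set(ld_clump(cands, ld, 0.001)) == {f"rs{i}"
                                                   for i in range(4)}

    def test_stronger_snp_dominates_its_ld_partner(self):
        cands = [make_variant(snp_id="rs_a", pval=1e-10),
                 make_variant(snp_id="rs_b", pos=50_000_100, pval=1e-8)]
        r = np.array([[1.0, 0.9487], [0.9487, 1.0]])  # r^2 ~ 0.9
        ld = LDMatrix(("rs_a", "rs_b"), r)
        assert ld_clump(cands, ld, 0.001) == ["rs_a"]

    def test_greedy_is_valid_maximal_and_p_minimal(self):
        pvals = (1e-12, 1e-9, 1e-7, 1e-6, 1e-5)
        cands = [make_variant(snp_id=f"rs{i+1}", pos=1000 + i, pval=p)
                 for i, p in enumerate(pvals)]
        ld = make_ld(5, 0.9, [f"rs{i+1}" for i in range(5)])
        for thr in (0.001, 0.5, 0.7):
            retained = ld_clump(cands, ld, thr)
            _brute_force_clump_check(cands, ld, thr, retained)

    def test_snp_missing_from_ld_is_dropped(self):
        cands = [make_variant(snp_id="rs_in", pval=1e-10),
                 make_variant(snp_id="rs_out", pos=50_000_100, pval=1e-9)]
        ld = LDMatrix(("rs_in",), np.eye(1))
        assert ld_clump(cands, ld, 0.001) == ["rs_in"]


class TestSelectInstruments:
    def _outcome_for(self, records):
        return make_region(
            [make_variant(snp_id=r.snp_id, chrom=r.chrom, pos=r.pos,
                          ea=r.effect_allele, oa=r.other_allele,
                          eaf=r.eaf, beta=0.01, se=0.005, n=400_000)
             for r in records],
            trait_id="OUT", trait_kind="outcome", gene_chrom=None,
            gene_start=None, gene_end=None)

    def test_single_strong_cis_snp_is_retained(self):
        rec = make_variant(pval=1e-9, beta=0.1, se=0.012)  # F ~ 69
        region = make_region([rec])
        iset = select_instruments(region, self._outcome_for([rec]))
        assert [p.snp_id for p in iset.members] == ["rs1"]
        assert iset.f_stats[0] > 10

    def test_mhc_snp_is_excluded(self):
        rec = make_variant(chrom="6", pos=30_000_000, pval=1e-9,
                           beta=0.1, se=0.012)
        region = make_region([rec], gene_chrom="6",
                             gene_start=30_000_000, gene_end=30_010_000)
        iset = select_instruments(region, self._outcome_for([rec]))
        assert len(iset) == 0
        assert ("mhc", 1, 0) in iset.attrition

    def test_weak_instrument_excluded_at_f_boundary(self):
        # z^2 = 9.9 * n/(n - 2 - 9.9)  =>  F = 9.9 < 10
        n = 33_000.0
        z2 = 9.9 * n / (n - 2 - 9.9)
        se = 0.01
        beta = np.sqrt(z2) * se
        rec = make_variant(beta=beta, se=se, n=n, pval=1e-9)
        region = make_region([rec])
        iset = select_instruments(region, self._outcome_for([rec]))
        assert len(iset) == 0
        assert ("f_stat", 1, 0) in iset.attrition

    def test_subthreshold_pvalue_excluded(self):
        rec = make_variant(beta=0.05, se=0.01)  # p ~ 5.7e-7 > 5e-8
        region = make_region([rec])
        iset = select_instruments(region, self._outcome_for([rec]))
        assert len(iset) == 0

    def test_cis_window_is_closed_around_gene_body(self):
        crit = InstrumentCriteria()
        inside = make_variant(snp_id="rs_in", pos=49_000_000,
                              beta=0.1, se=0.012, pval=1e-9)
        outside = make_variant(snp_id="rs_out", pos=48_999_999,
                               beta=0.1, se=0.012, pval=1e-9)
        region = make_region([inside, outside])
        iset = select_instruments(region,
                                  self._outcome_for([inside, outside]), crit)
        assert [p.snp_id for p in iset.members] == ["rs_in"]

    def test_output_invariant_under_row_shuffling(self):
        rng = random.Random(7)
        records = [make_variant(snp_id=f"rs{i}", pos=50_000_000 + 1000 * i,
                                beta=0.1 + 0.005 * i, se=0.012,
                                eaf=0.1 + 0.02 * i)
                   for i in range(8)]
        ld = make_ld(8, 0.2, [f"rs{i}" for i in range(8)])
        outcome = self._outcome_for(records)
        baseline = None
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            region = make_region(shuffled, ld=ld)
            got = [p.snp_id for p in
                   select_instruments(region, outcome).members]
            if baseline is None:
                baseline = got
            assert got == baseline

    def test_every_member_passes_pval_and_f(self):
        records = [make_variant(snp_id=f"rs{i}", pos=50_000_000 + 1000 * i,
                                beta=0.02 * i, se=0.012)
                   for i in range(10)]
        ld = make_ld(10, 0.0, [f"rs{i}" for i in range(10)])
        region = make_region(records, ld=ld)
        iset = select_instruments(region, self._outcome_for(records))
        by_id = region.by_snp()
        for p, f in zip(iset.members, iset.f_stats):
            assert by_id[p.snp_id].pval < 5e-8
            assert f > 10
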