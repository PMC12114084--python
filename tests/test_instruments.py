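"""Instrument selection, clumping, harmonization and strength formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr.exceptions import DomainError, MissingEAFError, NoOverlapError, ZeroInstrumentError
from tsmr.instruments import (
    ClumpConfig,
    HarmonizedInstrument,
    LDSource,
    clump,
    f_statistic,
    filter_weak,
    harmonize,
    select_by_pvalue,
    variance_explained,
)


class TestSelectByPvalue:
    def test_comparison_is_strict(self, record_factory, table_factory):
        table = table_factory(
            [
                record_factory(snp_id="a", pvalue=1e-7),
                record_factory(snp_id="b", pos=2, pvalue=4.9e-6),
                record_factory(snp_id="c", pos=3, pvalue=5e-6),
            ]
        )
        kept = select_by_pvalue(table, 5e-6)
        assert kept.snp_ids() == ["a", "b"]

    def test_threshold_one_keeps_all(self, record_factory, table_factory):
        table = table_factory([record_factory(snp_id=s, pvalue=p) for s, p in [("a", 0.5), ("b", 0.99)]])
        assert len(select_by_pvalue(table, 1.0 - 1e-12)) == 2

    def test_nothing_below_threshold_gives_empty_table(self, record_factory, table_factory):
        table = table_factory([record_factory(pvalue=0.1)])
        assert len(select_by_pvalue(table, 5e-6)) == 0


class TestClump:
    def test_single_snp_kept(self, record_factory, table_factory):
        table = table_factory([record_factory()])
        assert len(clump(table)) == 1

    def test_within_window_without_ld_source_keeps_best_p(self, record_factory, table_factory):
        table = table_factory(
            [
                record_factory(snp_id="best", pos=1_000_000, pvalue=1e-8),
                record_factory(snp_id="near", pos=6_000_000, pvalue=1e-7),  # 5,000 kb away
            ]
        )
        assert clump(table).snp_ids() == ["best"]

    def test_outside_window_both_kept(self, record_factory, table_factory):
        table = table_factory(
            [
                record_factory(snp_id="a", pos=1_000_000, pvalue=1e-8),
                record_factory(snp_id="b", pos=21_000_000, pvalue=1e-7),  # 20,000 kb away
            ]
        )
        assert clump(table).snp_ids() == ["a", "b"]

    def test_ld_source_spares_uncorrelated_neighbours(self, record_factory, table_factory):
        table = table_factory(
            [
                record_factory(snp_id="a", pos=1_000_000, pvalue=1e-8),
                record_factory(snp_id="b", pos=2_000_000, pvalue=1e-7),
            ]
        )
        loose = ClumpConfig(ld_source=LDSource({("a", "b"): 0.0005}))
        tight = ClumpConfig(ld_source=LDSource({("a", "b"): 0.5}))
        assert clump(table, loose).snp_ids() == ["a", "b"]
        assert clump(table, tight).snp_ids() == ["a"]

    def test_accepted_set_is_independent_brute_force(self, record_factory, table_factory):
        rng = np.random.default_rng(3)
        records = [
            record_factory(
                snp_id=f"rs{k}",
                chrom=str(rng.integers(1, 4)),
                pos=int(rng.integers(1, 60_000_000)),
                pvalue=float(rng.uniform(1e-10, 1e-6)),
            )
            for k in range(40)
        ]
        table = table_factory(records)
        config = ClumpConfig()
        kept = clump(table, config)
        by_id = {r.snp_id: r for r in records}
        for i, a in enumerate(kept.snp_ids()):
            for b in kept.snp_ids()[i + 1 :]:
                ra, rb = by_id[a], by_id[b]
                same_clump = (
                    ra.chrom == rb.chrom
                    and abs(ra.pos - rb.pos) <= config.window_kb * 1000
                )
                assert not same_clump, f"{a} and {b} violate the clumping rule"


def _pair(exposure_alleles, outcome_alleles, table_factory, record_factory, **kw):
    e = record_factory(
        effect_allele=exposure_alleles[0], other_allele=exposure_alleles[1],
        beta=0.10, eaf=kw.get("eaf_exp", 0.3),
    )
    o = record_factory(
        effect_allele=outcome_alleles[0], other_allele=outcome_alleles[1],
        beta=kw.get("beta_out", 0.05), se=0.02, eaf=kw.get("eaf_out", 0.3), pvalue=0.2,
    )
    return (
        table_factory([e], trait_id="exp"),
        table_factory([o], trait_id="out", trait_type="binary"),
    )


class TestHarmonize:
    def test_swapped_alleles_flip_the_outcome_sign(self, table_factory, record_factory):
        exp, out = _pair(("A", "G"), ("G", "A"), table_factory, record_factory)
        (inst,) = harmonize(exp, out)
        assert inst.beta_out == pytest.approx(-0.05)
        assert "flipped" in inst.flags and inst.kept

    def test_strand_complement_pair_is_corrected(self, table_factory, record_factory):
        exp, out = _pair(("A", "G"), ("T", "C"), table_factory, record_factory)
        (inst,) = harmonize(exp, out)
        assert inst.beta_out == pytest.approx(0.05)
        assert "strand_corrected" in inst.flags and inst.kept

    def test_palindrome_with_concordant_rare_frequencies_kept(self, table_factory, record_factory):
        exp, out = _pair(("A", "T"), ("A", "T"), table_factory, record_factory, eaf_exp=0.10, eaf_out=0.12)
        (inst,) = harmonize(exp, out, palindrome_eaf_limit=0.42)
        assert inst.kept and "palindromic" in inst.flags
        assert inst.beta_out == pytest.approx(0.05)

    def test_palindrome_with_discordant_frequencies_is_strand_corrected(self, table_factory, record_factory):
        exp, out = _pair(("C", "G"), ("C", "G"), table_factory, record_factory, eaf_exp=0.10, eaf_out=0.88)
        (inst,) = harmonize(exp, out)
        assert inst.kept and "strand_corrected" in inst.flags
        assert inst.beta_out == pytest.approx(-0.05)
        assert inst.eaf_out == pytest.approx(0.12)

    def test_ambiguous_palindrome_dropped(self, table_factory, record_factory):
        exp, out = _pair(("C", "G"), ("C", "G"), table_factory, record_factory, eaf_exp=0.10, eaf_out=0.50)
        (inst,) = harmonize(exp, out)
        assert inst.dropped_reason == "ambiguous palindrome"

    def test_incompatible_alleles_dropped_with_reason(self, table_factory, record_factory):
        exp, out = _pair(("A", "G"), ("A", "C"), table_factory, record_factory)
        (inst,) = harmonize(exp, out)
        assert inst.dropped_reason == "incompatible alleles"

    def test_empty_intersection_raises(self, table_factory, record_factory):
        exp = table_factory([record_factory(snp_id="rs1")], trait_id="exp")
        out = table_factory([record_factory(snp_id="rs2")], trait_id="out")
        with pytest.raises(NoOverlapError):
            harmonize(exp, out)

    @given(
        beta_out=st.floats(-1, 1, allow_nan=False),
        swap=st.booleans(),
    )
    @settings(deadline=None, max_examples=50)
    def test_double_flip_is_identity_and_harmonization_idempotent(self, beta_out, swap):
        from tests._helpers import make_record, make_table

        e = make_record(effect_allele="A", other_allele="G", beta=0.1)
        alleles = ("G", "A") if swap else ("A", "G")
        o = make_record(
            effect_allele=alleles[0], other_allele=alleles[1], beta=beta_out, eaf=0.3, pvalue=0.5
        )
        exp = make_table([e], trait_id="e")
        out = make_table([o], trait_id="o", trait_type="binary")
        (inst,) = harmonize(exp, out)
        # feed the harmonized orientation back in: nothing should change
        o2 = make_record(
            effect_allele="A", other_allele="G", beta=inst.beta_out, eaf=inst.eaf_out, pvalue=0.5
        )
        (inst2,) = harmonize(exp, make_table([o2], trait_id="o2", trait_type="binary"))
        assert inst2.beta_out == inst.beta_out
        assert inst2.flags == set()
        # double textual swap restores the original effect
        expected = -beta_out if swap else beta_out
        assert inst.beta_out == expected or inst.beta_out == pytest.approx(expected)


class TestStrengthFormulas:
    def test_zero_beta_explains_nothing(self, record_factory):
        assert variance_explained(record_factory(beta=0.0)) == 0.0

    def test_variance_explained_hand_computed(self, record_factory):
        """Term-by-term evaluation of the published variance-explained formula."""
        rec = record_factory(beta=0.1, eaf=0.5, se=0.01, n=10_000)
        num = 2 * 0.1**2 * 0.5 * 0.5
        den = num + 2 * 0.01**2 * 10_000 * 0.5 * 0.5
        assert variance_explained(rec) == pytest.approx(num / den, rel=1e-12)
        assert variance_explained(rec) == pytest.approx(0.009901, abs=5e-7)

    @given(
        eaf=st.floats(0.01, 0.99),
        beta=st.floats(-0.5, 0.5),
        se=st.floats(1e-4, 0.1),
    )
    @settings(deadline=None, max_examples=100)
    def test_eaf_cancels_and_r2_in_unit_interval(self, eaf, beta, se):
        from tests._helpers import make_record

        a = variance_explained(make_record(beta=beta, se=se, eaf=eaf))
        b = variance_explained(make_record(beta=beta, se=se, eaf=1 - eaf))
        assert a == pytest.approx(b, rel=1e-12, abs=1e-15)
        assert 0 <= a < 1

    def test_missing_eaf_raises_declared_error(self, record_factory):
        with pytest.raises(MissingEAFError):
            variance_explained(record_factory(eaf=None))

    def test_f_statistic_hand_computed(self):
        assert f_statistic(0.0, 100) == 0.0
        assert f_statistic(0.01, 102) == pytest.approx(0.01 * 100 / 0.99, rel=1e-14)

    def test_f_statistic_monotone_in_r2(self):
        values = [f_statistic(r2, 500) for r2 in np.linspace(0, 0.9, 20)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_f_statistic_domain_error(self):
        with pytest.raises(DomainError):
            f_statistic(1.0, 100)

    def test_f_approximates_squared_z_for_strong_samples(self, record_factory):
        """When se^2*N dominates beta^2, F tracks (beta/se)^2 within 1%."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            beta = rng.uniform(-0.1, 0.1)
            se = rng.uniform(0.005, 0.02)
            n = int(rng.integers(50_000, 200_000))
            rec = record_factory(beta=beta, se=se, n=n, eaf=rng.uniform(0.05, 0.95))
            f = f_statistic(variance_explained(rec), n)
            assert f == pytest.approx((beta / se) ** 2, rel=0.01)


class TestFilterWeak:
    def _inst(self, snp_id, f):
        return HarmonizedInstrument(
            snp_id=snp_id, beta_exp=0.1, se_exp=0.01, beta_out=0.05, se_out=0.02,
            n_exp=10_000, f_stat=f, r2=f / (f + 10_000),
        )

    def test_f_below_ten_removed_strong_retained(self):
        weak_one = self._inst("rs7117576", 2.153)
        strong = [self._inst("rs_a", 23.919), self._inst("rs_b", 1244.270)]
        retained, weak = filter_weak([weak_one] + strong, f_min=10.0)
        assert [i.snp_id for i in retained] == ["rs_a", "rs_b"]
        assert weak == [weak_one]
        assert weak_one.dropped_reason == "weak" and "weak" in weak_one.flags

    def test_f_min_zero_is_identity(self):
        instruments = [self._inst(f"rs{k}", f) for k, f in enumerate([0.5, 3, 100])]
        retained, weak = filter_weak(instruments, f_min=0.0)
        assert retained == instruments and weak == []

    def test_all_weak_raises(self):
        with pytest.raises(ZeroInstrumentError):
            filter_weak([self._inst("rs1", 1.0)], f_min=10.0)
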