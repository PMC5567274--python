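import math

import numpy as np
import pytest

from brcaloh import (
    ASCNSegment,
    BiallelicGroup,
    FisherVerdict,
    GermlineLocusObservation,
    LOHStatus,
    Mechanism,
    TumorProfile,
    assign_biallelic_group,
    call_locus_loh,
    classify_ascn_state,
    fisher_allele_test,
    purity_corrected_af,
)
from brcaloh.filters import SomaticVariant
from brcaloh.simulate import simulate_locus_observation

from oracles import binom_two_sided_oracle, fisher_p_oracle


def obs(nr, na, tr, ta, **kw):
    kw.setdefault("sample_id", "s")
    kw.setdefault("gene", "BRCA1")
    kw.setdefault("locus", ("1", 68_000_000))
    kw.setdefault("classification", "D")
    return GermlineLocusObservation(
        normal_ref=nr, normal_alt=na, tumor_ref=tr, tumor_alt=ta, **kw
    )


def one_segment_profile(genome, state, purity=0.6, ploidy=2.0, chrom="1"):
    a, b = max(state), min(state)
    seg = ASCNSegment(chrom, 1, genome.length(chrom), a + b, a, b)
    return TumorProfile("s", purity, ploidy, [seg], genome)


class TestFisherAlleleTest:
    def test_tumor_enrichment_positive(self):
        p_diff, p_het, verdict = fisher_allele_test(obs(30, 30, 5, 55))
        assert verdict is FisherVerdict.POSITIVE
        assert p_diff == pytest.approx(fisher_p_oracle(30, 30, 5, 55), rel=1e-9)
        assert p_het == pytest.approx(binom_two_sided_oracle(55, 60), rel=1e-9)
        assert p_diff < 1e-6

    def test_identical_tables_negative(self):
        p_diff, _, verdict = fisher_allele_test(obs(30, 30, 30, 30))
        assert p_diff == 1.0
        assert verdict is FisherVerdict.NEGATIVE

    def test_tumor_depletion_is_wildtype_retained(self):
        _, _, verdict = fisher_allele_test(obs(30, 30, 55, 5))
        assert verdict is FisherVerdict.WILDTYPE_RETAINED

    def test_zero_tumor_depth_indeterminate(self):
        p_diff, p_het, verdict = fisher_allele_test(obs(30, 30, 0, 0))
        assert verdict is FisherVerdict.INDETERMINATE
        assert math.isnan(p_diff) and math.isnan(p_het)

    def test_matches_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            nr, na, tr, ta = (int(x) for x in rng.integers(0, 20, 4))
            if nr + na == 0 or tr + ta == 0:
                continue
            p_diff, _, _ = fisher_allele_test(obs(nr, na, tr, ta))
            assert p_diff == pytest.approx(
                fisher_p_oracle(nr, na, tr, ta), rel=1e-8
            )


class TestPurityCorrection:
    def test_exact_algebra(self):
        m, f, d = purity_corrected_af(0.75, 0.5, 2, blood_af=0.5)
        assert (m, f, d) == (2.0, 1.0, 0.5)

    def test_heterozygous_fixed_point(self):
        for p in (0.1, 0.4, 0.9, 1.0):
            m, _, d = purity_corrected_af(0.5, p, 2, blood_af=0.5)
            assert m == pytest.approx(1.0)
            assert d == pytest.approx(0.0)

    def test_inverse_of_generative_formula(self):
        m, f, _ = purity_corrected_af(2 / 3, 0.5, 1, blood_af=0.5)
        assert m == pytest.approx(1.0)
        assert f == pytest.approx(1.0)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            purity_corrected_af(0.5, 0.0, 2, 0.5)

    def test_clamped_to_copy_number(self):
        m, f, _ = purity_corrected_af(0.999, 0.2, 1, 0.5)
        assert 0.0 <= m <= 1.0


class TestAscnTaxonomy:
    @pytest.mark.parametrize(
        "cn,m,expect",
        [
            (1, 1, Mechanism.LOH_DELETION),
            (2, 2, Mechanism.CN_LOH),
            (3, 3, Mechanism.LOH_GAIN),
            (5, 5, Mechanism.LOH_GAIN),
            (2, 1, Mechanism.ABSENT),
            (4, 2, Mechanism.ABSENT),
            (3, 1, Mechanism.ABSENT),
            (1, 0, Mechanism.WILDTYPE_RETAINED_LOH),
            (4, 0, Mechanism.WILDTYPE_RETAINED_LOH),
        ],
    )
    def test_state_mapping(self, cn, m, expect):
        assert classify_ascn_state(cn, m) is expect

    def test_mutant_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            classify_ascn_state(2, 3)


class TestCallLocusLoh:
    def test_concordant_cnloh_positive(self, mini_genome, rng):
        sim = simulate_locus_observation(Mechanism.CN_LOH, 0.7, rng=rng)
        profile = one_segment_profile(mini_genome, (2, 0), purity=0.7)
        call = call_locus_loh(
            obs(sim.normal_ref, sim.normal_alt, sim.tumor_ref, sim.tumor_alt),
            profile,
        )
        assert call.status is LOHStatus.LOH_POSITIVE
        assert call.mechanism is Mechanism.CN_LOH
        assert call.evidence.rule_path == "concordant"

    def test_absent_concordant_negative(self, mini_genome):
        profile = one_segment_profile(mini_genome, (1, 1), purity=0.6)
        call = call_locus_loh(obs(78, 77, 70, 71), profile)
        assert call.status is LOHStatus.LOH_NEGATIVE
        assert call.mechanism is Mechanism.ABSENT
        assert call.evidence.rule_path == "concordant"

    def test_delta_af_breaks_discordance(self, mini_genome):
        # shallow tumor coverage: the exact test cannot reach significance,
        # but the ASCN segment says gain-with-LOH and dAF clears 0.20
        profile = one_segment_profile(mini_genome, (3, 0), purity=0.35)
        call = call_locus_loh(obs(50, 50, 3, 9), profile)
        assert call.evidence.p_diff >= 0.05
        assert call.mechanism is Mechanism.LOH_GAIN
        assert call.evidence.rule_path == "discordant:delta_af"
        assert call.evidence.delta_af > 0.20
        assert call.status is LOHStatus.LOH_POSITIVE

    def test_delta_af_threshold_is_strict(self, mini_genome):
        # p=1, cn=4 segment, tumor 75/100 alt: m_cont = 3.0 -> ASCN absent,
        # exact test positive -> discordant; delta_af = 0.25 exactly
        profile = one_segment_profile(mini_genome, (2, 2), purity=1.0)
        o = obs(50, 50, 25, 75)
        call = call_locus_loh(o, profile)
        assert call.evidence.rule_path == "discordant:delta_af"
        d = call.evidence.delta_af
        assert d == 0.25
        # at a threshold equal to the observed dAF the call must be
        # negative (strict >); infinitesimally below, positive
        at = call_locus_loh(o, profile, delta_af_threshold=d)
        below = call_locus_loh(o, profile, delta_af_threshold=d - 1e-9)
        assert at.status is LOHStatus.LOH_NEGATIVE
        assert below.status is LOHStatus.LOH_POSITIVE

    def test_gap_reports_indeterminate(self, mini_genome):
        seg = ASCNSegment("2", 1, 10_000_000, 2, 1, 1)
        profile = TumorProfile("s", 0.6, 2.0, [seg], mini_genome)
        call = call_locus_loh(obs(50, 50, 40, 60), profile)
        assert call.status is LOHStatus.INDETERMINATE
        assert call.mechanism is None
        assert call.evidence.rule_path.startswith("gap")

    def test_tumor_only_normal_branch(self, mini_genome):
        profile = one_segment_profile(mini_genome, (2, 0), purity=0.9)
        call = call_locus_loh(obs(60, 60, 0, 0), profile)
        assert call.evidence.rule_path == "mutect_normal:ascn+delta_af"
        # zero observed tumor alt fraction cannot clear dAF > 0.20
        assert call.status is LOHStatus.LOH_NEGATIVE

    def test_nonpathogenic_classification_warns(self, mini_genome):
        profile = one_segment_profile(mini_genome, (1, 1))
        with pytest.warns(UserWarning, match="pathogenic"):
            call_locus_loh(obs(50, 50, 50, 50, classification="VUS"), profile)


class TestBiallelicGrouping:
    def _negative_call(self, mini_genome, gene="BRCA2"):
        profile = one_segment_profile(mini_genome, (1, 1), purity=0.6)
        return call_locus_loh(obs(78, 77, 70, 71, gene=gene), profile)

    def test_somatic_second_hit_moves_to_biallelic(self, mini_genome):
        call = self._negative_call(mini_genome)
        hit = SomaticVariant("s", "BRCA2", "truncating", "D", af=0.35)
        out = assign_biallelic_group(call, [hit])
        assert out.mechanism is Mechanism.ABSENT_PLUS_SOMATIC
        assert out.group_for_genomics is BiallelicGroup.BIALLELIC

    def test_other_gene_somatic_hit_ignored(self, mini_genome):
        call = self._negative_call(mini_genome)
        hit = SomaticVariant("s", "BRCA1", "truncating", "D", af=0.35)
        out = assign_biallelic_group(call, [hit])
        assert out.group_for_genomics is BiallelicGroup.NON_BIALLELIC

    def test_methylation_does_not_regroup(self, mini_genome):
        call = self._negative_call(mini_genome)
        out = assign_biallelic_group(call, [], methylation_flag=True)
        assert out.group_for_genomics is BiallelicGroup.NON_BIALLELIC

    def test_positive_call_is_biallelic(self, mini_genome, rng):
        sim = simulate_locus_observation(Mechanism.CN_LOH, 0.8, rng=rng)
        profile = one_segment_profile(mini_genome, (2, 0), purity=0.8)
        call = call_locus_loh(
            obs(sim.normal_ref, sim.normal_alt, sim.tumor_ref, sim.tumor_alt),
            profile,
        )
        out = assign_biallelic_group(call, [])
        assert out.group_for_genomics is BiallelicGroup.BIALLELIC
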