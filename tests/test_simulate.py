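import numpy as np
import pandas as pd
import pytest

from brcaloh import (
    Mechanism,
    call_locus_loh,
    load_genome_build,
    read_segments,
    score_all,
    write_segments,
)
from brcaloh.genome import ASCNSegment, TumorProfile
from brcaloh.loh import LOHStatus, expected_tumor_af
from brcaloh.simulate import (
    GENE_LOCI,
    ScarIntensity,
    SimulationParams,
    default_mechanism_probs,
    mechanism_state,
    simulate_cohort,
    simulate_locus_observation,
    simulate_profile,
    stamp_locus_state,
)


class TestSimulateProfile:
    def test_deterministic_given_seed(self, params):
        a, _ = simulate_profile(params, "biallelic", np.random.default_rng(7))
        b, _ = simulate_profile(params, "biallelic", np.random.default_rng(7))
        assert a.segments == b.segments
        assert a.purity == b.purity and a.ploidy == b.ploidy

    def test_zero_intensity_gives_clean_backbone(self, params):
        quiet = SimulationParams(
            seed=1,
            scar_intensity={"absent": ScarIntensity(0, 0, 0),
                            "biallelic": ScarIntensity(0, 0, 0)},
        )
        p, truth = simulate_profile(
            quiet, "absent", np.random.default_rng(3), ploidy=2.0
        )
        s = score_all(p)
        assert (s.ntai, s.lst, s.hrd_loh) == (0, 0, 0)
        assert sum(truth.values()) == 0

    def test_profiles_pass_genome_validation(self, params, mini_genome):
        # regenerating through the reader proves the conservation invariant
        for seed in range(5):
            p, _ = simulate_profile(
                params, "biallelic", np.random.default_rng(seed)
            )
            df = write_segments([p])
            meta = pd.DataFrame(
                {"sample": [p.sample_id], "purity": [p.purity],
                 "ploidy": [p.ploidy]}
            )
            (back,) = read_segments(df, meta, mini_genome)
            assert back.segments == p.segments

    def test_biallelic_preset_scores_higher(self, params):
        rng = np.random.default_rng(42)
        hi, _ = simulate_profile(params, "biallelic", rng, ploidy=2.0)
        rng = np.random.default_rng(42)
        lo, _ = simulate_profile(params, "absent", rng, ploidy=2.0)
        assert score_all(hi).hrd_mean > score_all(lo).hrd_mean


class TestLocusObservation:
    def test_expected_fraction_formula(self):
        # copy-neutral LOH at full purity: every tumor read is mutant
        assert expected_tumor_af(1.0, 2, 2) == 1.0
        # absent LOH matches the contamination exactly at any purity
        for p in (0.2, 0.5, 0.9):
            assert expected_tumor_af(p, 2, 1) == pytest.approx(0.5)
        # hemizygous deletion at half purity
        assert expected_tumor_af(0.5, 1, 1) == pytest.approx(2 / 3)

    def test_high_depth_concentrates_on_expectation(self, rng):
        sim = simulate_locus_observation(
            Mechanism.CN_LOH, 0.6, depth_tumor=1e6, depth_normal=1e6, rng=rng
        )
        f = expected_tumor_af(0.6, 2, 2)
        assert sim.tumor_alt / (sim.tumor_alt + sim.tumor_ref) == pytest.approx(
            f, abs=0.005
        )
        assert sim.normal_alt / (sim.normal_alt + sim.normal_ref) == pytest.approx(
            0.5, abs=0.005
        )

    def test_invalid_mechanism_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_locus_observation("NOT_A_MECHANISM", 0.5, rng=rng)

    def test_absent_plus_somatic_draws_af(self, rng):
        sim = simulate_locus_observation(
            Mechanism.ABSENT_PLUS_SOMATIC, 0.5, rng=rng
        )
        assert 0.1 <= sim.somatic_af <= 0.5
        assert (sim.cn, sim.m) == (2, 1)

    def test_mechanism_states(self):
        assert mechanism_state(Mechanism.LOH_DELETION) == (1, 1)
        assert mechanism_state(Mechanism.CN_LOH) == (2, 2)
        assert mechanism_state(Mechanism.LOH_GAIN, gain_cn=4) == (4, 4)
        assert mechanism_state(Mechanism.ABSENT) == (2, 1)


class TestSimulateCohort:
    def test_seeded_bundle_is_byte_identical(self, tmp_path):
        p = SimulationParams(seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(p).write(d1)
        simulate_cohort(SimulationParams(seed=5)).write(d2)
        for f in d1.iterdir():
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_group_sizes_and_truth_columns(self):
        bundle = simulate_cohort(SimulationParams(seed=2))
        assert len(bundle.truth) == 160
        by_gene = bundle.truth.groupby("gene").size()
        assert by_gene["BRCA1"] == 93 and by_gene["BRCA2"] == 67

    def test_mechanism_fractions_track_configuration(self):
        n = {("BRCA2", "breast"): 600}
        probs = {("BRCA2", "breast"): default_mechanism_probs()[("BRCA2", "breast")]}
        bundle = simulate_cohort(
            SimulationParams(seed=9, n_tumors=n, mechanism_probs=probs)
        )
        frac = (bundle.truth["mechanism"] == "ABSENT").mean()
        expect = probs[("BRCA2", "breast")]["ABSENT"]
        se = np.sqrt(expect * (1 - expect) / 600)
        assert abs(frac - expect) < 4 * se

    def test_burden_rate_recovered_from_generated_variants(self):
        from brcaloh import SomaticVariant, filter_somatic_variants, mutational_burden

        params = SimulationParams(
            seed=6, burden_rate={"BIALLELIC": 1.0, "NON_BIALLELIC": 1.0}
        )
        bundle = simulate_cohort(params)
        burdens = []
        for _, grp in bundle.somatic_variants.groupby("sample"):
            kept, _ = filter_somatic_variants(
                [
                    SomaticVariant(
                        sample_id=str(r["sample"]), gene=str(r["gene"]),
                        effect=str(r["effect"]),
                        pathogenicity=str(r["pathogenicity"]),
                        population_freq=float(r["population_freq"]),
                        segdup_frac=float(r["segdup_frac"]),
                        normal_alt_depth=int(r["normal_alt_depth"]),
                        tumor_alt_depth=int(r["tumor_alt_depth"]),
                    )
                    for _, r in grp.iterrows()
                ]
            )
            burdens.append(mutational_burden(kept, params.target_mb))
        # TP53 and second-hit extras add at most ~1/30 mutations per Mb
        se = np.sqrt(1.0 / params.target_mb / len(burdens))
        assert abs(np.mean(burdens) - 1.0) < 3 * se + 2 / params.target_mb

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationParams(n_tumors={("BRCA1", "breast"): 0}))

    def test_locus_stamp_matches_mechanism_truth(self, mini_genome):
        bundle = simulate_cohort(SimulationParams(seed=4))
        profiles = {
            p.sample_id: p
            for p in read_segments(
                bundle.segments, bundle.sample_meta, mini_genome
            )
        }
        from brcaloh.genome import segment_at

        for _, row in bundle.truth.head(40).iterrows():
            locus = GENE_LOCI["mini-test"][row["gene"]]
            seg = segment_at(profiles[row["sample"]], locus)
            assert seg is not None
            assert seg.cnt == row["cn"]

    def test_truth_recovered_at_ideal_purity_and_depth(self, mini_genome, rng):
        # p = 1 and effectively infinite depth: the caller must recover the
        # true mechanism for every non-degenerate state
        from brcaloh.loh import GermlineLocusObservation

        for mech in (
            Mechanism.LOH_DELETION, Mechanism.CN_LOH, Mechanism.LOH_GAIN,
            Mechanism.ABSENT,
        ):
            cn, m = mechanism_state(mech)
            a, b = max(m, cn - m), min(m, cn - m)
            seg = ASCNSegment("1", 1, 100_000_000, cn, a, b)
            profile = TumorProfile("s", 1.0, 2.0, [seg], mini_genome)
            for _ in range(10):
                sim = simulate_locus_observation(
                    mech, 1.0, depth_tumor=1e6, depth_normal=1e6, rng=rng
                )
                obs = GermlineLocusObservation(
                    "s", "BRCA1", ("1", 68_000_000), "D",
                    sim.normal_ref, sim.normal_alt, sim.tumor_ref, sim.tumor_alt,
                )
                call = call_locus_loh(obs, profile)
                assert call.mechanism is mech
                expect = (
                    LOHStatus.LOH_POSITIVE
                    if mech in (Mechanism.LOH_DELETION, Mechanism.CN_LOH,
                                Mechanism.LOH_GAIN)
                    else LOHStatus.LOH_NEGATIVE
                )
                assert call.status is expect
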