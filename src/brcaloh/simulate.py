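"""Synthetic tumor/normal cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes for a
cohort of germline BRCA1/BRCA2 carriers: per-sample allele-specific copy
number profiles whose scar-event load depends on biallelic status,
tumor/normal read counts at the carrier locus under a purity-aware
binomial model, somatic-variant tables with group-dependent burden,
mutational-signature proportion tables, and exponential survival with a
group hazard ratio.  Everything is deterministic given the seed, and
every file round-trips through the package readers.

The locus read-count model: tumor cells carry ``m`` mutant of ``cn``
copies, contaminating normal cells are germline-heterozygous, so the
expected tumor alt fraction at purity ``p`` is
``f = (p*m + (1-p)) / (p*cn + 2*(1-p))``; alt counts are binomial at
depths drawn Poisson around the configured mean coverages (141x tumor,
155x normal by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genome import ASCNSegment, GenomeBuild, TumorProfile, load_genome_build
from .loh import LOH_MECHANISMS, Mechanism

__all__ = [
    "ScarIntensity",
    "SCAR_PRESETS",
    "SimulationParams",
    "LocusSimulation",
    "CohortBundle",
    "SimulationError",
    "simulate_profile",
    "simulate_locus_observation",
    "simulate_cohort",
    "mechanism_state",
    "default_mechanism_probs",
]


class SimulationError(RuntimeError):
    """Event demands exceeded genome capacity after bounded retries."""


@dataclass(frozen=True)
class ScarIntensity:
    """Expected scar-event counts per Gb of simulated genome."""

    tai_per_gb: float  # telomeric allelic-imbalance segments (> 11 Mb)
    interstitial_loh_per_gb: float  # interstitial LOH segments (> 15 Mb)
    lst_pairs_per_gb: float  # adjacent >= 10 Mb alternating-state pairs


#: default presets by biallelic status of the BRCA locus
SCAR_PRESETS: dict[str, ScarIntensity] = {
    "biallelic": ScarIntensity(10.0, 8.0, 12.0),
    "absent": ScarIntensity(1.5, 1.0, 1.5),
}

_POSITIVE_LABELS = {
    "biallelic", "LOH_POSITIVE", "positive",
    *{m.value for m in LOH_MECHANISMS}, Mechanism.ABSENT_PLUS_SOMATIC.value,
}

#: carrier gene loci per genome build (chromosome, position)
GENE_LOCI: dict[str, dict[str, tuple[str, int]]] = {
    "hg19": {"BRCA1": ("17", 41_246_000), "BRCA2": ("13", 32_930_000)},
    "mini-test": {"BRCA1": ("1", 68_000_000), "BRCA2": ("2", 55_000_000)},
}


def default_mechanism_probs() -> dict[tuple[str, str], dict[str, float]]:
    """Mechanism distributions per gene x site.

    Absent-LOH totals follow the observed carrier rates (7% BRCA1 ovary,
    16% BRCA2 ovary, 10% BRCA1 breast, 46% BRCA2 breast); the LOH mass is
    split between deletion / copy-neutral / gain in the observed combined
    mechanism ratios per gene; a 2% absent-plus-somatic share is carved
    out of the absent mass in breast tumors.
    """
    loh_ratio = {
        "BRCA1": np.array([17.0, 36.0, 31.0]),  # deletion : cn-LOH : gain
        "BRCA2": np.array([14.0, 20.0, 11.0]),
    }
    absent_total = {
        ("BRCA1", "breast"): 0.10,
        ("BRCA1", "ovary"): 0.07,
        ("BRCA2", "breast"): 0.46,
        ("BRCA2", "ovary"): 0.16,
    }
    probs: dict[tuple[str, str], dict[str, float]] = {}
    for (gene, site), absent in absent_total.items():
        aps = 0.02 if site == "breast" else 0.0
        ratios = loh_ratio[gene] / loh_ratio[gene].sum()
        loh_mass = 1.0 - absent
        probs[(gene, site)] = {
            Mechanism.LOH_DELETION.value: loh_mass * ratios[0],
            Mechanism.CN_LOH.value: loh_mass * ratios[1],
            Mechanism.LOH_GAIN.value: loh_mass * ratios[2],
            Mechanism.ABSENT.value: absent - aps,
            Mechanism.ABSENT_PLUS_SOMATIC.value: aps,
        }
    return probs


@dataclass
class SimulationParams:
    """Cohort-level generator settings (defaults emulate the study design:
    160 carriers, 93 BRCA1 / 67 BRCA2, mean depths 141x/155x)."""

    genome: str = "mini-test"
    n_tumors: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("BRCA1", "breast"): 41,
            ("BRCA1", "ovary"): 52,
            ("BRCA2", "breast"): 35,
            ("BRCA2", "ovary"): 32,
        }
    )
    mechanism_probs: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=default_mechanism_probs
    )
    purity_alpha: float = 6.0  # Beta(6, 3): mean 0.67, bulk in [0.3, 0.9]
    purity_beta: float = 3.0
    ploidy_mean: float = 2.1
    ploidy_sd: float = 0.35
    depth_tumor: float = 141.0
    depth_normal: float = 155.0
    gain_cn: int = 3  # copy number used for the LOH-in-gain state
    scar_intensity: Mapping[str, ScarIntensity] = field(
        default_factory=lambda: dict(SCAR_PRESETS)
    )
    burden_rate: Mapping[str, float] = field(
        default_factory=lambda: {"BIALLELIC": 1.3, "NON_BIALLELIC": 0.6}
    )
    target_mb: float = 30.0
    tp53_prob: Mapping[str, float] = field(
        default_factory=lambda: {"BIALLELIC": 0.75, "NON_BIALLELIC": 0.35}
    )
    artifact_prob: float = 0.03
    on_saturation: str = "truncate"  # or "error": raise when genome is full
    baseline_median_months: float = 60.0
    hazard_ratio: float = 2.5  # non-biallelic vs biallelic overall mortality
    censor_low_months: float = 24.0
    censor_high_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, probs in self.mechanism_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mechanism probs for {key} sum to {total}")
        if self.depth_tumor <= 0 or self.depth_normal <= 0:
            raise ValueError("depths must be > 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")


def mechanism_state(mechanism: str | Mechanism, gain_cn: int = 3) -> tuple[int, int]:
    """(total copies, mutant copies) implied by a mechanism label."""
    mech = Mechanism(mechanism)
    return {
        Mechanism.LOH_DELETION: (1, 1),
        Mechanism.CN_LOH: (2, 2),
        Mechanism.LOH_GAIN: (gain_cn, gain_cn),
        Mechanism.ABSENT: (2, 1),
        Mechanism.ABSENT_PLUS_SOMATIC: (2, 1),
        Mechanism.WILDTYPE_RETAINED_LOH: (2, 0),
    }[mech]


# ---------------------------------------------------------------------------
# segment-profile simulation
# ---------------------------------------------------------------------------

_MAX_PLACEMENT_ATTEMPTS = 200


def _overlaps(placed: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s <= end and start <= e for s, e in placed)


def _event_chromosomes(genome: GenomeBuild) -> list[str]:
    return [c for c in genome.names if c != "X"]


def _resolve_intensity(loh_status: str, presets: Mapping[str, ScarIntensity]):
    if loh_status in presets:
        return presets[loh_status]
    key = "biallelic" if str(loh_status) in _POSITIVE_LABELS else "absent"
    return presets[key]


def simulate_profile(
    params: SimulationParams,
    loh_status: str,
    rng: np.random.Generator,
    sample_id: str = "sim",
    purity: Optional[float] = None,
    ploidy: Optional[float] = None,
) -> tuple[TumorProfile, dict[str, int]]:
    """Build one ASCN profile by placing scar events on a clean backbone.

    ``loh_status`` selects a scar-intensity preset ("biallelic"/"absent",
    or any status/mechanism label which is mapped accordingly).  Event
    counts are Poisson draws truncated at what the genome can hold;
    placement retries are bounded and exhaustion raises
    :class:`SimulationError`.  Returns the profile and the placed-event
    truth counts.
    """
    genome = load_genome_build(params.genome)
    intensity = _resolve_intensity(loh_status, params.scar_intensity)
    if purity is None:
        purity = float(
            np.clip(rng.beta(params.purity_alpha, params.purity_beta), 0.05, 1.0)
        )
    if ploidy is None:
        ploidy = float(
            np.clip(rng.normal(params.ploidy_mean, params.ploidy_sd), 1.5, 4.5)
        )
    backbone = (1, 1) if ploidy < 2.75 else (2, 2)
    chroms = _event_chromosomes(genome)
    gb = sum(genome.length(c) for c in chroms) / 1e9
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    events: list[tuple[str, str, int, int, tuple[int, int]]] = []

    def place(chrom: str, start: int, end: int, state: tuple[int, int], kind: str):
        placed[chrom].append((start, end))
        events.append((kind, chrom, start, end, state))

    # telomeric allelic-imbalance events: one per free terminus at most
    termini = [(c, arm) for c in chroms for arm in ("p", "q")]
    termini = [termini[j] for j in rng.permutation(len(termini))]
    k_tai = min(rng.poisson(intensity.tai_per_gb * gb), len(termini))
    n_tai = 0
    for chrom, arm in termini:
        if n_tai >= k_tai:
            break
        cen = genome.centromere(chrom)
        clen = genome.length(chrom)
        arm_len = cen[0] - 1 if arm == "p" else clen - cen[1]
        max_len = min(22_000_000, arm_len - 2_000_000)
        if max_len < 12_000_000:
            continue
        length = int(rng.uniform(12_000_000, max_len))
        if arm == "p":
            start, end = 1, length
        else:
            start, end = clen - length + 1, clen
        if _overlaps(placed[chrom], start, end):
            continue
        ai_state = (2, 1) if backbone == (1, 1) else (3, 1)
        place(chrom, start, end, ai_state, "tai")
        n_tai += 1

    def free_gaps() -> list[tuple[str, int, int]]:
        # free intervals, keeping a 2 Mb margin from the chromosome ends so
        # interstitial events never masquerade as telomeric ones
        gaps: list[tuple[str, int, int]] = []
        for chrom in chroms:
            clen = genome.length(chrom)
            cursor = 2_000_001
            for s, e in sorted(placed[chrom]):
                if s > cursor:
                    gaps.append((chrom, cursor, min(s - 1, clen - 2_000_000)))
                cursor = max(cursor, e + 1)
            if cursor <= clen - 2_000_000:
                gaps.append((chrom, cursor, clen - 2_000_000))
        return [g for g in gaps if g[2] >= g[1]]

    def place_interstitial(length: int, state: tuple[int, int], kind: str) -> bool:
        fitting = [g for g in free_gaps() if g[2] - g[1] + 1 >= length]
        if not fitting:
            return False
        weights = np.array(
            [g[2] - g[1] + 2 - length for g in fitting], dtype=float
        )
        chrom, lo, hi = fitting[int(rng.choice(len(fitting), p=weights / weights.sum()))]
        start = int(rng.integers(lo, hi - length + 2))
        place(chrom, start, start + length - 1, state, kind)
        return True

    def free_mb() -> float:
        return gb * 1000 - sum(
            (e - s + 1) / 1e6 for c in chroms for s, e in placed[c]
        )

    # capacity-truncated draws: never demand more than ~half the free
    # genome per event class, so bounded-retry placement stays feasible
    k_loh = min(
        rng.poisson(intensity.interstitial_loh_per_gb * gb),
        max(int(free_mb() * 0.45 / 21), 0),
    )
    n_loh = 0
    for _ in range(k_loh):
        length = int(rng.uniform(16_000_000, 25_000_000))
        loh_state = (1, 0) if rng.random() < 0.5 else (2, 0)
        if not (
            place_interstitial(length, loh_state, "iloh")
            or place_interstitial(16_000_000, loh_state, "iloh")
        ):
            if params.on_saturation == "error":
                raise SimulationError(
                    f"no room left for an interstitial LOH event in {sample_id}"
                )
            break  # genome saturated: truncate the draw here
        n_loh += 1

    k_lst = min(
        rng.poisson(intensity.lst_pairs_per_gb * gb),
        max(int(free_mb() * 0.55 / 24), 0),
    )
    lst_pool = [(2, 1), (3, 1), (1, 0), (2, 2)]
    lst_pool = [s for s in lst_pool if s != backbone]
    n_lst = 0
    for _ in range(k_lst):
        l1 = int(rng.uniform(10_000_000, 14_000_000))
        l2 = int(rng.uniform(10_000_000, 14_000_000))
        i, j = rng.choice(len(lst_pool), size=2, replace=False)
        s1, s2 = lst_pool[int(i)], lst_pool[int(j)]
        # place as one block, then split
        if not place_interstitial(l1 + l2, s1, "_lst_block"):
            l1 = l2 = 10_000_000
            if not place_interstitial(l1 + l2, s1, "_lst_block"):
                if params.on_saturation == "error":
                    raise SimulationError(
                        f"no room left for an LST segment pair in {sample_id}"
                    )
                break
        kind, chrom, start, end, _ = events.pop()
        placed[chrom].pop()
        place(chrom, start, start + l1 - 1, s1, "lst")
        place(chrom, start + l1, end, s2, "lst")
        n_lst += 1

    # fill everything else with the backbone state
    segments: list[ASCNSegment] = []
    for chrom in genome.names:
        clen = genome.length(chrom)
        placed_here = sorted(
            [
                (s, e, st)
                for k, c, s, e, st in events
                if c == chrom
            ]
        )
        cursor = 1
        for s, e, st in placed_here:
            if s > cursor:
                segments.append(
                    ASCNSegment(chrom, cursor, s - 1, sum(backbone), *backbone)
                )
            segments.append(ASCNSegment(chrom, s, e, sum(st), *st))
            cursor = e + 1
        if cursor <= clen:
            segments.append(
                ASCNSegment(chrom, cursor, clen, sum(backbone), *backbone)
            )

    profile = TumorProfile(
        sample_id=sample_id,
        purity=purity,
        ploidy=ploidy,
        segments=segments,
        genome=genome,
    )
    truth = {
        "n_tai_events": n_tai,
        "n_interstitial_loh_events": n_loh,
        "n_lst_pair_events": n_lst,
    }
    return profile, truth


def stamp_locus_state(
    profile: TumorProfile,
    locus: tuple[str, int],
    state: tuple[int, int],
    half_width: tuple[int, int] = (5_000_000, 5_000_000),
) -> TumorProfile:
    """Overwrite the region around ``locus`` with an (A, B) ASCN state."""
    chrom, pos = locus
    clen = profile.genome.length(chrom)
    start = max(1, pos - half_width[0])
    end = min(clen, pos + half_width[1])
    a, b = max(state), min(state)
    new_seg = ASCNSegment(chrom, start, end, a + b, a, b)
    out: list[ASCNSegment] = []
    for seg in profile.segments:
        if seg.chromosome != chrom or seg.end < start or seg.start > end:
            out.append(seg)
            continue
        if seg.start < start:
            out.append(replace(seg, end=start - 1))
        if seg.end > end:
            out.append(replace(seg, start=end + 1))
    out.append(new_seg)
    return TumorProfile(
        sample_id=profile.sample_id,
        purity=profile.purity,
        ploidy=profile.ploidy,
        segments=out,
        genome=profile.genome,
    )


# ---------------------------------------------------------------------------
# locus observation simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusSimulation:
    """Simulated tumor/normal counts at the carrier locus plus truth."""

    normal_ref: int
    normal_alt: int
    tumor_ref: int
    tumor_alt: int
    mechanism: str
    cn: int
    m: int
    f_expected: float
    purity: float
    somatic_af: Optional[float] = None


def simulate_locus_observation(
    mechanism: str | Mechanism,
    purity: float,
    depth_tumor: float = 141.0,
    depth_normal: float = 155.0,
    rng: Optional[np.random.Generator] = None,
    gain_cn: int = 3,
) -> LocusSimulation:
    """Draw tumor/normal allele counts for a mechanism at given purity."""
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    mech = Mechanism(mechanism)
    rng = rng if rng is not None else np.random.default_rng()
    cn, m = mechanism_state(mech, gain_cn)
    f = (purity * m + (1 - purity)) / (purity * cn + 2 * (1 - purity))
    dt = max(1, int(rng.poisson(depth_tumor)))
    dn = max(1, int(rng.poisson(depth_normal)))
    tumor_alt = int(rng.binomial(dt, f))
    normal_alt = int(rng.binomial(dn, 0.5))
    somatic_af = None
    if mech is Mechanism.ABSENT_PLUS_SOMATIC:
        somatic_af = float(rng.uniform(0.1, 0.5))
    return LocusSimulation(
        normal_ref=dn - normal_alt,
        normal_alt=normal_alt,
        tumor_ref=dt - tumor_alt,
        tumor_alt=tumor_alt,
        mechanism=mech.value,
        cn=cn,
        m=m,
        f_expected=f,
        purity=purity,
        somatic_af=somatic_af,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    """All generated tables for one synthetic cohort."""

    segments: pd.DataFrame
    sample_meta: pd.DataFrame
    locus_counts: pd.DataFrame
    somatic_variants: pd.DataFrame
    signatures: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame

    _FILES = {
        "segments": "segments.tsv",
        "sample_meta": "sample_meta.tsv",
        "locus_counts": "locus_counts.tsv",
        "somatic_variants": "somatic_variants.tsv",
        "signatures": "signatures.tsv",
        "clinical": "clinical.tsv",
        "truth": "truth.tsv",
    }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_csv(outdir / fname, sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "CohortBundle":
        indir = Path(indir)
        return cls(
            **{
                attr: pd.read_csv(indir / fname, sep="\t")
                for attr, fname in cls._FILES.items()
            }
        )


_SIGNATURE_COLUMNS = ["Sig1", "Sig3", "Sig5", "R1", "U1"]
_SOMATIC_EFFECTS = ["missense", "truncating", "indel"]


def simulate_cohort(params: SimulationParams) -> CohortBundle:
    """Generate the full synthetic cohort as a set of tidy tables."""
    if sum(params.n_tumors.values()) == 0:
        raise ValueError("zero samples requested")
    rng = np.random.default_rng(params.seed)
    genome = load_genome_build(params.genome)
    loci = GENE_LOCI[genome.name]
    log_haz_base = math.log(2) / params.baseline_median_months

    seg_rows, meta_rows, locus_rows = [], [], []
    somatic_rows, sig_rows, clin_rows, truth_rows = [], [], [], []
    i = 0
    for (gene, site), n in sorted(params.n_tumors.items()):
        probs = params.mechanism_probs[(gene, site)]
        labels = sorted(probs)
        pvec = np.array([probs[l] for l in labels])
        for _ in range(n):
            i += 1
            sample = f"S{i:04d}"
            mech = Mechanism(str(rng.choice(labels, p=pvec)))
            loh_positive = mech in LOH_MECHANISMS
            biallelic = loh_positive or mech is Mechanism.ABSENT_PLUS_SOMATIC
            group = "BIALLELIC" if biallelic else "NON_BIALLELIC"
            preset = "biallelic" if biallelic else "absent"

            profile, scar_truth = simulate_profile(
                params, preset, rng, sample_id=sample
            )
            cn, m = mechanism_state(mech, params.gain_cn)
            locus = loci[gene]
            half = (
                int(rng.uniform(2_000_000, 15_000_000)),
                int(rng.uniform(2_000_000, 15_000_000)),
            )
            profile = stamp_locus_state(
                profile, locus, (max(m, cn - m), min(m, cn - m)), half
            )
            for seg in profile.segments:
                seg_rows.append(
                    (sample, seg.chromosome, seg.start, seg.end,
                     seg.cnt, seg.a, seg.b)
                )
            meta_rows.append(
                (sample, round(profile.purity, 6), round(profile.ploidy, 6))
            )

            sim = simulate_locus_observation(
                mech, profile.purity, params.depth_tumor, params.depth_normal,
                rng, params.gain_cn,
            )
            locus_rows.append(
                (sample, gene, locus[0], locus[1], "A", "T", "D",
                 sim.normal_ref, sim.normal_alt, sim.tumor_ref, sim.tumor_alt)
            )

            # somatic variants: kept-nonsynonymous count is the burden draw
            n_nonsyn = int(
                rng.poisson(params.burden_rate[group] * params.target_mb)
            )
            tp53 = bool(rng.random() < params.tp53_prob[group])
            for v in range(n_nonsyn):
                effect = str(
                    rng.choice(_SOMATIC_EFFECTS, p=[0.65, 0.2, 0.15])
                )
                patho = str(rng.choice(["D", "LD", "VUS"], p=[0.15, 0.15, 0.7]))
                somatic_rows.append(
                    (sample, f"GENE{int(rng.integers(1, 400)):03d}", effect,
                     patho, 0.0, 0.0, int(rng.integers(0, 3)),
                     11 + int(rng.poisson(30)),
                     round(float(rng.uniform(0.1, 0.6)), 4))
                )
            for _ in range(int(rng.poisson(0.3 * n_nonsyn))):
                # synonymous chaff exercising the variant filter
                somatic_rows.append(
                    (sample, f"GENE{int(rng.integers(1, 400)):03d}",
                     "synonymous", "B", 0.0, 0.0, 0,
                     11 + int(rng.poisson(30)),
                     round(float(rng.uniform(0.1, 0.6)), 4))
                )
            if tp53:
                somatic_rows.append(
                    (sample, "TP53",
                     str(rng.choice(["missense", "truncating"])), "D",
                     0.0, 0.0, 0, 11 + int(rng.poisson(30)),
                     round(float(rng.uniform(0.2, 0.7)), 4))
                )
            if mech is Mechanism.ABSENT_PLUS_SOMATIC:
                somatic_rows.append(
                    (sample, gene, "truncating", "D", 0.0, 0.0, 0,
                     11 + int(rng.poisson(30)), round(sim.somatic_af, 4))
                )

            # mutational-signature proportions
            artifact = bool(rng.random() < params.artifact_prob)
            art = float(rng.uniform(0.35, 0.55)) if artifact else float(
                rng.uniform(0.0, 0.04)
            )
            sig3 = float(
                rng.uniform(0.3, 0.6) if biallelic else rng.uniform(0.0, 0.15)
            )
            sig3 = min(sig3, 1.0 - art)
            rest = 1.0 - art - sig3
            sig_rows.append(
                (sample, round(0.6 * rest, 6), round(sig3, 6),
                 round(0.4 * rest, 6), round(0.6 * art, 6), round(0.4 * art, 6))
            )

            # survival: exponential with group hazard, independent censoring
            hr = params.hazard_ratio if group == "NON_BIALLELIC" else 1.0
            t_death = float(rng.exponential(1.0 / (log_haz_base * hr)))
            t_censor = float(
                rng.uniform(params.censor_low_months, params.censor_high_months)
            )
            os_months = round(min(t_death, t_censor), 3)
            os_event = int(t_death <= t_censor)
            stage = int(rng.choice([1, 2, 3, 4], p=[0.15, 0.35, 0.35, 0.15]))
            receptor = (
                str(rng.choice(["TNBC", "ER+", "HER2+"], p=[0.45, 0.45, 0.10]))
                if site == "breast"
                else "NA"
            )
            clin_rows.append(
                (sample, site, gene, site, stage, receptor, os_months,
                 os_event, "LOHpos" if loh_positive else "LOHneg")
            )

            truth_rows.append(
                (sample, gene, site, mech.value,
                 "LOH_POSITIVE" if loh_positive else "LOH_NEGATIVE", group,
                 cn, m, round(profile.purity, 6), round(profile.ploidy, 6),
                 scar_truth["n_tai_events"],
                 scar_truth["n_interstitial_loh_events"],
                 scar_truth["n_lst_pair_events"],
                 hr, int(artifact), int(tp53), n_nonsyn)
            )

    return CohortBundle(
        segments=pd.DataFrame(
            seg_rows,
            columns=["sample", "chromosome", "start.pos", "end.pos",
                     "CNt", "A", "B"],
        ),
        sample_meta=pd.DataFrame(
            meta_rows, columns=["sample", "purity", "ploidy"]
        ),
        locus_counts=pd.DataFrame(
            locus_rows,
            columns=["sample", "gene", "chromosome", "position", "ref", "alt",
                     "classification", "normal_ref", "normal_alt",
                     "tumor_ref", "tumor_alt"],
        ),
        somatic_variants=pd.DataFrame(
            somatic_rows,
            columns=["sample", "gene", "effect", "pathogenicity",
                     "population_freq", "segdup_frac", "normal_alt_depth",
                     "tumor_alt_depth", "af"],
        ),
        signatures=pd.DataFrame(
            sig_rows, columns=["sample"] + _SIGNATURE_COLUMNS
        ),
        clinical=pd.DataFrame(
            clin_rows,
            columns=["sample", "site", "gene", "tumor_type", "stage",
                     "receptor_status", "os_months", "os_event", "group"],
        ),
        truth=pd.DataFrame(
            truth_rows,
            columns=["sample", "gene", "site", "mechanism", "loh_status",
                     "group_for_genomics", "cn", "m", "purity", "ploidy",
                     "n_tai_events", "n_interstitial_loh_events",
                     "n_lst_pair_events", "hazard_multiplier", "artifact",
                     "tp53_mutant", "n_somatic_nonsyn"],
        ),
    )
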