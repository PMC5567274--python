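"""WES-based homologous-recombination-deficiency (HRD) genomic-scar scores.

Three established scar counts are computed from an allele-specific copy
number profile, plus their mean:

* **NtAI** — allelic-imbalance segments (A != B) longer than 11 Mb that
  reach a chromosome terminus without spanning the centromere.
* **LST** — large-scale state transitions: after smoothing away segments
  shorter than 3 Mb, breakpoints whose two flanking segments are each at
  least 10 Mb and differ in (A, B) state.  The ploidy-corrected variant is
  ``LSTm = LST - 15.5 * ploidy`` (may be negative; no floor).
* **HRD-LOH** — LOH segments (B = 0, CNt >= 1) longer than 15 Mb, with
  chromosome 17 excluded (the BRCA1 chromosome, whose locus LOH would
  otherwise leak into the genome-wide scar count).

``HRD-Mean`` averages NtAI, LSTm and HRD-LOH by default; a config switch
substitutes raw LST for LSTm.  Chromosome X is excluded from all three
scores by default since allele states on X are ill-defined in males.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .genome import ASCNSegment, GenomeBuild, TumorProfile

__all__ = [
    "ScoreConfig",
    "HRDScores",
    "score_ntai",
    "score_lst",
    "score_hrd_loh",
    "score_all",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Thresholds for the scar scores (bp unless noted)."""

    ntai_min_length: int = 11_000_000
    lst_smooth_below: int = 3_000_000
    lst_min_flank: int = 10_000_000
    lst_ploidy_factor: float = 15.5
    hrd_loh_min_length: int = 15_000_000
    hrd_loh_excluded_chromosomes: tuple[str, ...] = ("17",)
    telomere_tolerance: int = 1_000_000
    exclude_whole_chromosome_loh: bool = False
    exclude_x: bool = True
    hrd_mean_uses_lstm: bool = True


@dataclass(frozen=True)
class HRDScores:
    sample_id: str
    ntai: int
    lst: int
    lstm: float
    hrd_loh: int
    hrd_mean: float


def _scored_chromosomes(genome: GenomeBuild, config: ScoreConfig) -> list[str]:
    return [c for c in genome.names if not (config.exclude_x and c == "X")]


def _reaches_terminus(
    seg: ASCNSegment,
    chrom_segments: list[ASCNSegment],
    chrom_length: int,
    tol: int,
) -> bool:
    # A segment is telomeric if it is the first/last segment of its
    # chromosome AND lies within the tolerance of the chromosome end.
    first = chrom_segments[0] is seg and seg.start <= tol
    last = chrom_segments[-1] is seg and seg.end >= chrom_length - tol + 1
    return first or last


def _spans_centromere(seg: ASCNSegment, cen: tuple[int, int]) -> bool:
    # "On one arm" = does not extend strictly beyond both centromere edges.
    return seg.start < cen[0] and seg.end > cen[1]


def score_ntai(
    profile: TumorProfile,
    genome: GenomeBuild | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> int:
    """Count telomere-reaching allelic-imbalance segments > 11 Mb on one arm."""
    genome = genome or profile.genome
    count = 0
    for chrom in _scored_chromosomes(genome, config):
        segs = profile.segments_on(chrom)
        if not segs:
            continue
        cen = genome.centromere(chrom)
        chrom_len = genome.length(chrom)
        for seg in segs:
            if (
                seg.has_allelic_imbalance
                and seg.length > config.ntai_min_length
                and not _spans_centromere(seg, cen)
                and _reaches_terminus(seg, segs, chrom_len, config.telomere_tolerance)
            ):
                count += 1
    return count


def _split_at_centromere(
    segs: list[ASCNSegment], cen: tuple[int, int]
) -> tuple[list[ASCNSegment], list[ASCNSegment]]:
    """Clip segments to the p arm [1, cen.start-1] and q arm [cen.end+1, len]."""
    p_arm: list[ASCNSegment] = []
    q_arm: list[ASCNSegment] = []
    for seg in segs:
        if seg.start < cen[0]:
            p_arm.append(
                replace(seg, end=min(seg.end, cen[0] - 1))
                if seg.end >= cen[0]
                else seg
            )
        if seg.end > cen[1]:
            q_arm.append(
                replace(seg, start=max(seg.start, cen[1] + 1))
                if seg.start <= cen[1]
                else seg
            )
    return p_arm, q_arm


def _smooth_arm(segs: list[ASCNSegment], below: int) -> list[ASCNSegment]:
    """Iteratively drop sub-threshold segments (shortest first), merging
    equal-state neighbours across the hole, until stable."""
    segs = list(segs)
    while True:
        small = [s for s in segs if s.length < below]
        if not small:
            return segs
        victim = min(small, key=lambda s: (s.length, s.start))
        i = segs.index(victim)
        segs.pop(i)
        if 0 < i <= len(segs) - 1:
            left, right = segs[i - 1], segs[i]
            if left.state == right.state:
                segs[i - 1 : i + 1] = [replace(left, end=right.end, cnt=left.cnt)]


def score_lst(
    profile: TumorProfile,
    genome: GenomeBuild | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> tuple[int, float]:
    """Return (LST, LSTm).

    Per arm: smooth out segments < 3 Mb, then count breakpoints whose two
    flanking smoothed segments are each >= 10 Mb and differ in (A, B).
    """
    genome = genome or profile.genome
    lst = 0
    for chrom in _scored_chromosomes(genome, config):
        segs = profile.segments_on(chrom)
        if not segs:
            continue
        for arm in _split_at_centromere(segs, genome.centromere(chrom)):
            smoothed = _smooth_arm(arm, config.lst_smooth_below)
            for left, right in zip(smoothed, smoothed[1:]):
                if (
                    left.state != right.state
                    and left.length >= config.lst_min_flank
                    and right.length >= config.lst_min_flank
                ):
                    lst += 1
    lstm = lst - config.lst_ploidy_factor * profile.ploidy
    return lst, lstm


def score_hrd_loh(
    profile: TumorProfile,
    genome: GenomeBuild | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> int:
    """Count LOH segments > 15 Mb outside the excluded chromosomes."""
    genome = genome or profile.genome
    count = 0
    for chrom in _scored_chromosomes(genome, config):
        if chrom in config.hrd_loh_excluded_chromosomes:
            continue
        chrom_len = genome.length(chrom)
        for seg in profile.segments_on(chrom):
            if not (seg.is_loh and seg.length > config.hrd_loh_min_length):
                continue
            if (
                config.exclude_whole_chromosome_loh
                and seg.start == 1
                and seg.end == chrom_len
            ):
                continue
            count += 1
    return count


def score_all(
    profile: TumorProfile,
    genome: GenomeBuild | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> HRDScores:
    """Compute all scar scores and their mean for one profile."""
    genome = genome or profile.genome
    ntai = score_ntai(profile, genome, config)
    lst, lstm = score_lst(profile, genome, config)
    hrd_loh = score_hrd_loh(profile, genome, config)
    lst_component = lstm if config.hrd_mean_uses_lstm else lst
    hrd_mean = (ntai + lst_component + hrd_loh) / 3.0
    return HRDScores(
        sample_id=profile.sample_id,
        ntai=ntai,
        lst=lst,
        lstm=lstm,
        hrd_loh=hrd_loh,
        hrd_mean=hrd_mean,
    )


def score_profiles(
    profiles: Iterable[TumorProfile],
    config: ScoreConfig = ScoreConfig(),
):
    """Score many profiles into a tidy DataFrame (one row per sample)."""
    import pandas as pd

    return pd.DataFrame(
        [vars(score_all(p, p.genome, config)) for p in profiles]
    )
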