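"""Genome coordinate model and allele-specific copy number (ASCN) ingestion.

Coordinates are 1-based, fully closed intervals throughout (the Sequenza
segment-table convention): a segment ``start=1, end=10`` covers 10 bp.
Chromosome names are normalized by stripping a leading ``chr``; ``X`` is
kept, ``Y`` and ``MT`` are dropped with a warning (allele states there are
ill-defined for most samples and the scar scores are autosome-focused).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomeBuild",
    "ASCNSegment",
    "TumorProfile",
    "GenomeModelError",
    "load_genome_build",
    "read_segments",
    "write_segments",
    "segment_at",
]


class GenomeModelError(ValueError):
    """Invalid genome build, segment table, or sample metadata."""


# UCSC hg19 chromosome lengths and gap-track centromere intervals (acen),
# autosomes 1-22 plus X.  Shipped so the package needs no download.
_HG19_CHROMS: list[tuple[str, int]] = [
    ("1", 249250621), ("2", 243199373), ("3", 198022430), ("4", 191154276),
    ("5", 180915260), ("6", 171115067), ("7", 159138663), ("8", 146364022),
    ("9", 141213431), ("10", 135534747), ("11", 135006516), ("12", 133851895),
    ("13", 115169878), ("14", 107349540), ("15", 102531392), ("16", 90354753),
    ("17", 81195210), ("18", 78077248), ("19", 59128983), ("20", 63025520),
    ("21", 48129895), ("22", 51304566), ("X", 155270560),
]

_HG19_CENTROMERES: dict[str, tuple[int, int]] = {
    "1": (121535434, 124535434), "2": (92326171, 95326171),
    "3": (90504854, 93504854), "4": (49660117, 52660117),
    "5": (46405641, 49405641), "6": (58830166, 61830166),
    "7": (58054331, 61054331), "8": (43838887, 46838887),
    "9": (47367679, 50367679), "10": (39254935, 42254935),
    "11": (51644205, 54644205), "12": (34856694, 37856694),
    "13": (16000000, 19000000), "14": (16000000, 19000000),
    "15": (17000000, 20000000), "16": (35335801, 38335801),
    "17": (22263006, 25263006), "18": (15460898, 18460898),
    "19": (24681782, 27681782), "20": (26369569, 29369569),
    "21": (11288129, 14288129), "22": (13000000, 16000000),
    "X": (58632012, 61632012),
}

# Deterministic three-chromosome genome for tests and fast simulation.
_MINI_CHROMS: list[tuple[str, int]] = [
    ("1", 100_000_000), ("2", 80_000_000), ("3", 60_000_000),
]
_MINI_CENTROMERES: dict[str, tuple[int, int]] = {
    "1": (40_000_000, 42_000_000),
    "2": (30_000_000, 32_000_000),
    "3": (25_000_000, 27_000_000),
}


def normalize_chromosome(name: object) -> str:
    """Strip a leading 'chr' prefix and return the bare chromosome label."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosomes with lengths and centromere intervals.

    ``centromeres`` maps chromosome name to a closed (start, end) interval
    that must lie strictly inside the chromosome.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        lengths = dict(self.chromosomes)
        for chrom, length in self.chromosomes:
            if chrom in seen:
                raise GenomeModelError(f"duplicate chromosome {chrom!r}")
            seen.add(chrom)
            if length <= 0:
                raise GenomeModelError(f"chromosome {chrom!r} length must be > 0")
            if chrom != normalize_chromosome(chrom):
                raise GenomeModelError(
                    f"chromosome name {chrom!r} is not normalized (no 'chr' prefix)"
                )
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in lengths:
                raise GenomeModelError(f"centromere for unknown chromosome {chrom!r}")
            if not (1 < cs <= ce < lengths[chrom]):
                raise GenomeModelError(
                    f"centromere {cs}-{ce} not strictly inside chromosome "
                    f"{chrom!r} (length {lengths[chrom]})"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for c, n in self.chromosomes:
            if c == chrom:
                return n
        raise GenomeModelError(f"unknown chromosome {chrom!r} in build {self.name!r}")

    def centromere(self, chrom: str) -> tuple[int, int]:
        try:
            return self.centromeres[chrom]
        except KeyError:
            raise GenomeModelError(
                f"no centromere recorded for chromosome {chrom!r}"
            ) from None

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.chromosomes)


def load_genome_build(
    source: str | Mapping[str, object],
) -> GenomeBuild:
    """Return a validated :class:`GenomeBuild`.

    ``source`` is either a packaged build name (``"hg19"``, ``"mini-test"``)
    or a mapping with keys ``name``, ``chromosomes`` (list of (name, length))
    and ``centromeres`` (chromosome -> (start, end)).
    """
    if isinstance(source, str):
        if source == "hg19":
            return GenomeBuild("hg19", tuple(_HG19_CHROMS), dict(_HG19_CENTROMERES))
        if source == "mini-test":
            return GenomeBuild(
                "mini-test", tuple(_MINI_CHROMS), dict(_MINI_CENTROMERES)
            )
        raise GenomeModelError(f"unknown genome build {source!r}")
    chroms = tuple(
        (normalize_chromosome(c), int(n)) for c, n in source["chromosomes"]
    )
    cents = {
        normalize_chromosome(c): (int(s), int(e))
        for c, (s, e) in dict(source.get("centromeres", {})).items()
    }
    return GenomeBuild(str(source.get("name", "custom")), chroms, cents)


@dataclass(frozen=True)
class ASCNSegment:
    """One allele-specific copy number segment (1-based closed interval).

    ``cnt`` is the total copy number, ``a``/``b`` the major/minor allele
    copies with ``a + b == cnt`` and ``a >= b >= 0``.
    """

    chromosome: str
    start: int
    end: int
    cnt: int
    a: int
    b: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeModelError(
                f"segment start {self.start} > end {self.end} on {self.chromosome}"
            )
        if self.b < 0 or self.a < self.b:
            raise GenomeModelError(
                f"allele copies must satisfy a >= b >= 0, got a={self.a} b={self.b}"
            )
        if self.a + self.b != self.cnt:
            raise GenomeModelError(
                f"A+B != CNt ({self.a}+{self.b} != {self.cnt}) on "
                f"{self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        """Loss of heterozygosity: minor allele absent, locus not deleted."""
        return self.b == 0 and self.cnt >= 1

    @property
    def has_allelic_imbalance(self) -> bool:
        return self.a != self.b

    @property
    def state(self) -> tuple[int, int]:
        return (self.a, self.b)


@dataclass
class TumorProfile:
    """One sample's purity, ploidy and ordered ASCN segments."""

    sample_id: str
    purity: float
    ploidy: float
    segments: list[ASCNSegment]
    genome: GenomeBuild
    _starts: dict[str, list[int]] = field(init=False, repr=False, default_factory=dict)
    _by_chrom: dict[str, list[ASCNSegment]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise GenomeModelError(
                f"purity must be in (0, 1], got {self.purity} for {self.sample_id}"
            )
        if self.ploidy <= 0:
            raise GenomeModelError(f"ploidy must be > 0, got {self.ploidy}")
        self.segments = sorted(
            self.segments, key=lambda s: (self.genome.names.index(s.chromosome), s.start)
        )
        by_chrom: dict[str, list[ASCNSegment]] = {}
        for seg in self.segments:
            if seg.chromosome not in self.genome:
                raise GenomeModelError(
                    f"segment chromosome {seg.chromosome!r} not in build "
                    f"{self.genome.name!r}"
                )
            if seg.end > self.genome.length(seg.chromosome):
                raise GenomeModelError(
                    f"segment end {seg.end} exceeds chromosome {seg.chromosome} "
                    f"length {self.genome.length(seg.chromosome)}"
                )
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in by_chrom.items():
            for prev, cur in zip(segs, segs[1:]):
                if cur.start <= prev.end:
                    raise GenomeModelError(
                        f"overlapping segments on {chrom}: "
                        f"{prev.start}-{prev.end} and {cur.start}-{cur.end} "
                        f"in sample {self.sample_id}"
                    )
        self._by_chrom = by_chrom
        self._starts = {c: [s.start for s in segs] for c, segs in by_chrom.items()}

    def segments_on(self, chrom: str) -> list[ASCNSegment]:
        return self._by_chrom.get(chrom, [])


def segment_at(
    profile: TumorProfile, locus: tuple[str, int]
) -> ASCNSegment | None:
    """Return the unique segment covering ``locus`` or ``None`` for a gap."""
    chrom, pos = normalize_chromosome(locus[0]), int(locus[1])
    if chrom not in profile.genome:
        raise GenomeModelError(
            f"locus chromosome {chrom!r} not in build {profile.genome.name!r}"
        )
    starts = profile._starts.get(chrom)
    if not starts:
        return None
    i = bisect_right(starts, pos) - 1
    if i < 0:
        return None
    seg = profile._by_chrom[chrom][i]
    return seg if seg.start <= pos <= seg.end else None


_SEGMENT_COLUMNS = ["chromosome", "start.pos", "end.pos", "CNt", "A", "B"]


def _require_integer(value: object, column: str, row: int) -> int:
    f = float(value)
    if f != int(f):
        raise GenomeModelError(
            f"non-integer {column}={value!r} at row {row}; discretization is "
            "the caller's responsibility"
        )
    return int(f)


def read_segments(
    segment_table: str | Path | pd.DataFrame,
    meta: str | Path | pd.DataFrame,
    genome: GenomeBuild,
) -> list[TumorProfile]:
    """Load Sequenza-dialect segment tables into validated profiles.

    ``segment_table`` needs columns ``chromosome, start.pos, end.pos, CNt,
    A, B`` plus ``sample`` in multi-sample mode; ``meta`` needs ``sample,
    purity, ploidy``.  Rows whose allele copies do not sum to CNt are
    dropped with a diagnostic warning; Y/MT rows are dropped with a
    warning; every sample listed in ``meta`` must have segments.
    """
    seg_df = (
        pd.read_csv(segment_table, sep="\t", dtype=str)
        if not isinstance(segment_table, pd.DataFrame)
        else segment_table.copy()
    )
    meta_df = (
        pd.read_csv(meta, sep="\t")
        if not isinstance(meta, pd.DataFrame)
        else meta.copy()
    )
    missing = [c for c in _SEGMENT_COLUMNS if c not in seg_df.columns]
    if missing:
        raise GenomeModelError(f"segment table missing columns: {missing}")
    for col in ("sample", "purity", "ploidy"):
        if col not in meta_df.columns:
            raise GenomeModelError(f"metadata table missing column {col!r}")
    if "sample" not in seg_df.columns:
        if len(meta_df) != 1:
            raise GenomeModelError(
                "segment table has no 'sample' column but metadata lists "
                f"{len(meta_df)} samples"
            )
        seg_df = seg_df.assign(sample=str(meta_df["sample"].iloc[0]))

    profiles: list[TumorProfile] = []
    grouped = {str(k): g for k, g in seg_df.groupby("sample", sort=False)}
    for _, mrow in meta_df.iterrows():
        sample = str(mrow["sample"])
        purity, ploidy = float(mrow["purity"]), float(mrow["ploidy"])
        if sample not in grouped:
            raise GenomeModelError(
                f"sample {sample!r} in metadata has no rows in the segment table"
            )
        segments: list[ASCNSegment] = []
        for idx, row in grouped[sample].iterrows():
            chrom = normalize_chromosome(row["chromosome"])
            if chrom in ("Y", "MT", "M"):
                warnings.warn(
                    f"dropping {chrom} segment at row {idx} (sample {sample}); "
                    "Y/MT are not analyzed",
                    stacklevel=2,
                )
                continue
            cnt = _require_integer(row["CNt"], "CNt", idx)
            a = _require_integer(row["A"], "A", idx)
            b = _require_integer(row["B"], "B", idx)
            if a + b != cnt:
                warnings.warn(
                    f"rejecting row {idx} (sample {sample}): A+B != CNt "
                    f"({a}+{b} != {cnt})",
                    stacklevel=2,
                )
                continue
            segments.append(
                ASCNSegment(
                    chromosome=chrom,
                    start=int(float(row["start.pos"])),
                    end=int(float(row["end.pos"])),
                    cnt=cnt,
                    a=a,
                    b=b,
                )
            )
        profiles.append(
            TumorProfile(
                sample_id=sample,
                purity=purity,
                ploidy=ploidy,
                segments=segments,
                genome=genome,
            )
        )
    unknown = set(grouped) - {str(s) for s in meta_df["sample"]}
    if unknown:
        raise GenomeModelError(
            f"segment table contains samples absent from metadata: {sorted(unknown)}"
        )
    return profiles


def write_segments(
    profiles: Iterable[TumorProfile], path: str | Path | None = None
) -> pd.DataFrame:
    """Serialize profiles back to the Sequenza-dialect TSV (round-trips)."""
    rows = [
        {
            "sample": p.sample_id,
            "chromosome": s.chromosome,
            "start.pos": s.start,
            "end.pos": s.end,
            "CNt": s.cnt,
            "A": s.a,
            "B": s.b,
        }
        for p in profiles
        for s in p.segments
    ]
    df = pd.DataFrame(rows, columns=["sample"] + _SEGMENT_COLUMNS)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def write_sample_meta(
    profiles: Iterable[TumorProfile], path: str | Path | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"sample": p.sample_id, "purity": p.purity, "ploidy": p.ploidy}
            for p in profiles
        ]
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
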