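"""Locus-specific loss-of-heterozygosity calling at a germline carrier locus.

Three evidence sources are combined for each tumor/normal pair:

1. An exact test of tumor vs. normal allele counts at the germline
   mutation (2x2 independence test on ref/alt counts, plus an exact
   binomial test of the tumor alt fraction against 0.5).
2. The allele-specific copy number (ASCN) state of the segment covering
   the locus, converted to a mutant-copy estimate via purity correction.
3. The purity-corrected allele-fraction difference dAF = f_corr - blood
   AF, used as the tie-break when 1 and 2 disagree (LOH-positive iff
   dAF > 0.20, strict).

The mutant-copy model: in a specimen of purity ``p``, tumor cells carry
``m`` mutant of ``cn`` total copies while contaminating normal cells are
germline-heterozygous (1 mutant of 2 copies), so the expected tumor alt
fraction is ``f = (p*m + (1-p)) / (p*cn + 2*(1-p))``.  Inverting for the
observed fraction gives the continuous mutant-copy estimate ``m_cont``;
rounding yields the ASCN mechanism via the state taxonomy:

=====================  ===========================
(cn, m)                mechanism
=====================  ===========================
(1, 1)                 LOH with deletion
(2, 2)                 copy-neutral LOH
(>=3, m = cn)          LOH in gain
(>=2, 1 <= m < cn)     absent LOH (wildtype kept)
m = 0                  wildtype-retained LOH
=====================  ===========================

Any retained wildtype copy means absent locus-specific LOH, including
gains with 1 < m < cn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

from scipy import stats

from .genome import TumorProfile, segment_at

__all__ = [
    "LOHStatus",
    "Mechanism",
    "BiallelicGroup",
    "FisherVerdict",
    "GermlineLocusObservation",
    "LOHCall",
    "fisher_allele_test",
    "purity_corrected_af",
    "classify_ascn_state",
    "call_locus_loh",
    "assign_biallelic_group",
]

DELTA_AF_THRESHOLD = 0.20
DEFAULT_ALPHA = 0.05


class LOHStatus(str, Enum):
    LOH_POSITIVE = "LOH_POSITIVE"
    LOH_NEGATIVE = "LOH_NEGATIVE"
    INDETERMINATE = "INDETERMINATE"


class Mechanism(str, Enum):
    LOH_DELETION = "LOH_DELETION"
    CN_LOH = "CN_LOH"
    LOH_GAIN = "LOH_GAIN"
    ABSENT = "ABSENT"
    ABSENT_PLUS_SOMATIC = "ABSENT_PLUS_SOMATIC"
    WILDTYPE_RETAINED_LOH = "WILDTYPE_RETAINED_LOH"


#: mechanisms that constitute loss of the wildtype allele
LOH_MECHANISMS = frozenset(
    {Mechanism.LOH_DELETION, Mechanism.CN_LOH, Mechanism.LOH_GAIN}
)


class BiallelicGroup(str, Enum):
    BIALLELIC = "BIALLELIC"
    NON_BIALLELIC = "NON_BIALLELIC"


class FisherVerdict(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    WILDTYPE_RETAINED = "WILDTYPE_RETAINED"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class GermlineLocusObservation:
    """Tumor/normal ref/alt read counts at the carrier mutation."""

    sample_id: str
    gene: str
    locus: tuple[str, int]
    classification: str  # pathogenicity label, e.g. "D", "LD", "VUS"
    normal_ref: int
    normal_alt: int
    tumor_ref: int
    tumor_alt: int

    def __post_init__(self) -> None:
        for name in ("normal_ref", "normal_alt", "tumor_ref", "tumor_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def normal_depth(self) -> int:
        return self.normal_ref + self.normal_alt

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def blood_af(self) -> float:
        if self.normal_depth == 0:
            return math.nan
        return self.normal_alt / self.normal_depth

    @property
    def tumor_af(self) -> float:
        if self.tumor_depth == 0:
            return math.nan
        return self.tumor_alt / self.tumor_depth


@dataclass(frozen=True)
class Evidence:
    """Complete numeric trail behind one LOH call."""

    p_diff: float
    p_het: float
    cn: Optional[int]
    m_cont: Optional[float]
    m_hat: Optional[int]
    f_corr: Optional[float]
    delta_af: Optional[float]
    tumor_af: float
    blood_af: float
    rule_path: str


@dataclass(frozen=True)
class LOHCall:
    sample_id: str
    gene: str
    status: LOHStatus
    mechanism: Optional[Mechanism]
    evidence: Evidence
    group_for_genomics: Optional[BiallelicGroup] = None


def fisher_allele_test(
    obs: GermlineLocusObservation, alpha: float = DEFAULT_ALPHA
) -> tuple[float, float, FisherVerdict]:
    """Exact tumor-vs-normal allele count comparison.

    ``p_diff`` is the two-sided exact test of independence on the 2x2
    table (normal_ref, normal_alt; tumor_ref, tumor_alt); ``p_het`` the
    two-sided exact binomial of the tumor alt count against rate 0.5.
    The verdict is POSITIVE when the counts differ significantly with the
    tumor AF above blood AF, WILDTYPE_RETAINED when significantly below,
    NEGATIVE otherwise, and INDETERMINATE at zero tumor depth (mutation
    seen only in the normal; resolved by the ASCN+dAF branch upstream).
    """
    if obs.normal_depth == 0:
        raise ValueError("normal depth is zero; no germline evidence at locus")
    if obs.tumor_depth == 0:
        return math.nan, math.nan, FisherVerdict.INDETERMINATE
    _, p_diff = stats.fisher_exact(
        [[obs.normal_ref, obs.normal_alt], [obs.tumor_ref, obs.tumor_alt]],
        alternative="two-sided",
    )
    p_het = stats.binomtest(obs.tumor_alt, obs.tumor_depth, 0.5).pvalue
    if p_diff < alpha:
        if obs.tumor_af > obs.blood_af:
            verdict = FisherVerdict.POSITIVE
        elif obs.tumor_af < obs.blood_af:
            verdict = FisherVerdict.WILDTYPE_RETAINED
        else:
            verdict = FisherVerdict.NEGATIVE
    else:
        verdict = FisherVerdict.NEGATIVE
    return p_diff, p_het, verdict


def purity_corrected_af(
    f_obs: float, p: float, cn: int, blood_af: float
) -> tuple[float, float, float]:
    """Invert the contamination model for (m_cont, f_corr, delta_af).

    Solves ``f_obs = (p*m + (1-p)) / (p*cn + 2*(1-p))`` for the mutant
    copy number ``m``, clamps to [0, cn], and returns the corrected
    fraction ``f_corr = m_cont / cn`` and ``delta_af = f_corr - blood_af``.
    """
    if not (0 < p <= 1):
        raise ValueError(f"purity must be in (0, 1], got {p}")
    if cn < 1:
        raise ValueError(f"copy number must be >= 1 for correction, got {cn}")
    m_cont = (f_obs * (p * cn + 2 * (1 - p)) - (1 - p)) / p
    m_cont = min(max(m_cont, 0.0), float(cn))
    f_corr = m_cont / cn
    return m_cont, f_corr, f_corr - blood_af


def expected_tumor_af(p: float, cn: int, m: int) -> float:
    """Forward model: expected tumor alt fraction for purity p, state (cn, m)."""
    return (p * m + (1 - p)) / (p * cn + 2 * (1 - p))


def classify_ascn_state(cn: int, m_hat: int) -> Mechanism:
    """Map a (total copies, mutant copies) state to its mechanism label."""
    if m_hat > cn:
        raise ValueError(f"mutant copies {m_hat} exceed total copies {cn}")
    if m_hat < 0 or cn < 0:
        raise ValueError("copy numbers must be non-negative")
    if m_hat == 0:
        return Mechanism.WILDTYPE_RETAINED_LOH
    if cn == 1 and m_hat == 1:
        return Mechanism.LOH_DELETION
    if cn == 2 and m_hat == 2:
        return Mechanism.CN_LOH
    if cn >= 3 and m_hat == cn:
        return Mechanism.LOH_GAIN
    # cn >= 2 with at least one wildtype copy
    return Mechanism.ABSENT


def _round_away_from_het(m_cont: float, cn: int) -> int:
    """Round with .5 ties pushed away from the heterozygous midpoint cn/2."""
    frac = m_cont - math.floor(m_cont)
    if abs(frac - 0.5) < 1e-12:
        m_hat = math.floor(m_cont) if m_cont < cn / 2 else math.ceil(m_cont)
    else:
        m_hat = round(m_cont)
    return min(max(int(m_hat), 0), cn)


def call_locus_loh(
    obs: GermlineLocusObservation,
    profile: TumorProfile,
    alpha: float = DEFAULT_ALPHA,
    delta_af_threshold: float = DELTA_AF_THRESHOLD,
) -> LOHCall:
    """Full decision ladder for one carrier locus.

    (i) run the exact allele test and classify the ASCN state;
    (ii) if concordant, that is the status;
    (iii) if discordant, LOH-positive iff dAF > threshold (strict);
    (iv) if the tumor has no reads at the locus, LOH-positive iff the
    ASCN state is an LOH mechanism AND dAF > threshold.
    The mechanism is always reported from the ASCN state.
    """
    if profile.purity is None or math.isnan(profile.purity):
        raise ValueError(f"purity missing for sample {obs.sample_id}")
    if obs.classification not in ("D", "LD", "pathogenic", "P"):
        warnings.warn(
            f"{obs.sample_id}: classification {obs.classification!r} is not "
            "pathogenic; LOH call produced anyway",
            stacklevel=2,
        )
    seg = segment_at(profile, obs.locus)
    blood_af = obs.blood_af
    tumor_af = obs.tumor_af
    if seg is None:
        return LOHCall(
            obs.sample_id,
            obs.gene,
            LOHStatus.INDETERMINATE,
            None,
            Evidence(
                math.nan, math.nan, None, None, None, None, None,
                tumor_af, blood_af, "gap:no_segment_at_locus",
            ),
        )
    cn = seg.cnt
    p_diff, p_het, verdict = fisher_allele_test(obs, alpha)
    if cn == 0:
        # homozygous deletion of the locus: wildtype and mutant both lost
        return LOHCall(
            obs.sample_id,
            obs.gene,
            LOHStatus.LOH_NEGATIVE,
            Mechanism.WILDTYPE_RETAINED_LOH,
            Evidence(
                p_diff, p_het, 0, 0.0, 0, 0.0, -blood_af,
                tumor_af, blood_af, "ascn:homozygous_deletion",
            ),
        )
    m_cont, f_corr, delta_af = purity_corrected_af(
        0.0 if math.isnan(tumor_af) else tumor_af, profile.purity, cn, blood_af
    )
    m_hat = _round_away_from_het(m_cont, cn)
    mechanism = classify_ascn_state(cn, m_hat)
    ascn_positive = mechanism in LOH_MECHANISMS

    if verdict is FisherVerdict.INDETERMINATE:
        positive = ascn_positive and delta_af > delta_af_threshold
        rule = "mutect_normal:ascn+delta_af"
    else:
        fisher_positive = verdict is FisherVerdict.POSITIVE
        if fisher_positive == ascn_positive:
            positive = ascn_positive
            rule = "concordant"
        else:
            positive = delta_af > delta_af_threshold
            rule = "discordant:delta_af"
    status = LOHStatus.LOH_POSITIVE if positive else LOHStatus.LOH_NEGATIVE
    return LOHCall(
        obs.sample_id,
        obs.gene,
        status,
        mechanism,
        Evidence(
            p_diff, p_het, cn, m_cont, m_hat, f_corr, delta_af,
            tumor_af, blood_af, rule,
        ),
    )


def assign_biallelic_group(
    call: LOHCall,
    somatic_variants: Sequence[object] = (),
    methylation_flag: Optional[bool] = None,
) -> LOHCall:
    """Assign the group used for genomic comparisons.

    An LOH-negative tumor with a pathogenic somatic variant in the same
    gene is reclassified ABSENT_PLUS_SOMATIC and grouped biallelic (the
    somatic hit is the second hit); promoter methylation does NOT move an
    LOH-negative tumor into the biallelic group.  Everything else is
    biallelic iff LOH-positive.
    """
    has_somatic_hit = any(
        getattr(v, "gene", None) == call.gene
        and getattr(v, "pathogenicity", getattr(v, "classification", None))
        in ("D", "LD", "pathogenic", "P")
        for v in somatic_variants
    )
    if call.status is LOHStatus.LOH_NEGATIVE and has_somatic_hit:
        return replace(
            call,
            mechanism=Mechanism.ABSENT_PLUS_SOMATIC,
            group_for_genomics=BiallelicGroup.BIALLELIC,
        )
    group = (
        BiallelicGroup.BIALLELIC
        if call.status is LOHStatus.LOH_POSITIVE
        else BiallelicGroup.NON_BIALLELIC
    )
    return replace(call, group_for_genomics=group)
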