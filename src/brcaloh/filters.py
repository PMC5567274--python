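"""Sample and variant eligibility rules, mutational burden, and PTEN status.

All thresholds are strict or non-strict exactly as the pipeline defines
them; the somatic-variant filter attributes each rejected variant to the
first failing rule so the tallies partition the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "SomaticVariant",
    "SignatureProfile",
    "PTENStatus",
    "is_germline_carrier",
    "filter_somatic_variants",
    "mutational_burden",
    "nonbrca_eligible",
    "artifact_fraction_excluded",
    "extrapolate_pten",
]

ARTIFACT_SIGNATURES = ("R1", "R2", "R3", "U1", "U2")
DEFAULT_TARGET_MB = 30.0  # exome footprint used for burden (config-exposed)

PATHOGENIC_LABELS = frozenset({"D", "LD"})
BENIGN_LABELS = frozenset({"LB", "B"})


@dataclass(frozen=True)
class SomaticVariant:
    sample_id: str
    gene: str
    effect: str  # synonymous | missense | truncating | indel
    pathogenicity: str  # D | LD | VUS | LB | B
    population_freq: float = 0.0
    segdup_frac: float = 0.0
    normal_alt_depth: int = 0
    tumor_alt_depth: int = 0
    af: float = math.nan


@dataclass(frozen=True)
class SignatureProfile:
    sample_id: str
    proportions: Mapping[str, float]


def is_germline_carrier(
    classification: str,
    germline_af: float,
    normal_depth: int,
    tumor_depth: int,
) -> bool:
    """Carrier criteria: pathogenic mutation, germline AF > 0.30 (strict),
    and total depth > 30 (strict) in both germline and tumor."""
    return (
        classification in PATHOGENIC_LABELS
        and germline_af > 0.30
        and normal_depth > 30
        and tumor_depth > 30
    )


# Evaluation order fixed so rejection tallies are deterministic.
_FILTER_RULES = (
    "germline_alt_depth",
    "population_frequency",
    "segmental_duplication",
    "synonymous",
    "tumor_alt_depth",
    "pathogenicity",
)


def _first_failing_rule(v: SomaticVariant) -> Optional[str]:
    try:
        if not (v.normal_alt_depth < 5):
            return "germline_alt_depth"
        if not (v.population_freq < 0.01):
            return "population_frequency"
        if not (v.segdup_frac <= 0.89):
            return "segmental_duplication"
        if v.effect == "synonymous":
            return "synonymous"
        if not (v.tumor_alt_depth > 10):
            return "tumor_alt_depth"
        if v.pathogenicity in PATHOGENIC_LABELS:
            return None
        if v.pathogenicity == "VUS":
            # rare VUS only: population allele frequency < 0.1%
            return None if v.population_freq < 0.001 else "pathogenicity"
        return "pathogenicity"
    except TypeError:
        return "missing_field"


def filter_somatic_variants(
    variants: Sequence[SomaticVariant],
) -> tuple[list[SomaticVariant], dict[str, int]]:
    """Apply the somatic-variant filter ladder.

    Kept iff germline alt depth < 5, population frequency < 1%, segmental
    duplication fraction <= 0.89, non-synonymous, tumor alt reads > 10
    (strict), and pathogenic/likely pathogenic or rare (< 0.1%) VUS.
    Returns (kept, per-rule rejection counts); kept + rejections
    partition the input by first failing rule.
    """
    kept: list[SomaticVariant] = []
    rejections = {rule: 0 for rule in _FILTER_RULES}
    rejections["missing_field"] = 0
    for v in variants:
        rule = _first_failing_rule(v)
        if rule is None:
            kept.append(v)
        else:
            rejections[rule] += 1
    return kept, rejections


def mutational_burden(
    kept_variants: Sequence[SomaticVariant] | int,
    target_mb: float = DEFAULT_TARGET_MB,
) -> float:
    """Somatic nonsynonymous mutations per megabase of callable exome."""
    if target_mb <= 0:
        raise ValueError(f"target_mb must be > 0, got {target_mb}")
    if isinstance(kept_variants, int):
        n = kept_variants
    else:
        n = sum(1 for v in kept_variants if v.effect != "synonymous")
    return n / target_mb


def nonbrca_eligible(
    somatic_brca_pathogenic: bool,
    brca_homozygous_deletion: bool,
    brca1_expression_z: float,
    brca1_methylation_beta: float,
    brca2_expression_z: float,
    neoadjuvant_chemo: bool,
) -> tuple[bool, str]:
    """Eligibility of a tumor for the non-BRCA comparison set.

    Excluded (with the first matching reason) for: a pathogenic somatic
    BRCA1/2 mutation; homozygous BRCA1/2 deletion; BRCA1 silencing
    (expression z < -1.5 with methylation beta > 0.5); low BRCA2
    expression (z < -1.5); neoadjuvant chemotherapy.
    """
    if somatic_brca_pathogenic:
        return False, "somatic BRCA"
    if brca_homozygous_deletion:
        return False, "homozygous BRCA deletion"
    if brca1_expression_z < -1.5 and brca1_methylation_beta > 0.5:
        return False, "BRCA1 silenced"
    if brca2_expression_z < -1.5:
        return False, "BRCA2 low expression"
    if neoadjuvant_chemo:
        return False, "neoadjuvant chemotherapy"
    return True, "eligible"


def artifact_fraction_excluded(
    profile: SignatureProfile, threshold: float = 0.30
) -> bool:
    """True iff the summed artifact-signature fraction (R1-R3, U1-U2)
    strictly exceeds the threshold (default 30%)."""
    total = sum(profile.proportions.get(sig, 0.0) for sig in ARTIFACT_SIGNATURES)
    return total > threshold


class PTENStatus(str, Enum):
    LOSS = "LOSS"
    RETAINED = "RETAINED"
    INDETERMINATE = "INDETERMINATE"


def extrapolate_pten(
    cn_state: tuple[int, int], pten_mutation: Optional[str] = None
) -> PTENStatus:
    """Extrapolate PTEN protein status from its ASCN state.

    LOSS for copy number below two, or a truncating mutation with loss of
    the other allele; RETAINED for wildtype at copy number two or more
    with a minor allele present; copy-neutral LOH without a mutation is
    INDETERMINATE (excluded downstream).
    """
    cn, b = cn_state
    if cn < 0 or b < 0:
        raise ValueError("copy numbers must be non-negative")
    if cn < 2:
        return PTENStatus.LOSS
    if pten_mutation == "truncating" and b == 0:
        return PTENStatus.LOSS
    if pten_mutation is None:
        return PTENStatus.RETAINED if b >= 1 else PTENStatus.INDETERMINATE
    # non-truncating mutation or truncating with retained allele: keep the
    # copy-number reading
    return PTENStatus.RETAINED if b >= 1 else PTENStatus.INDETERMINATE
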