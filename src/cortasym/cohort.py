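"""Domain types for an ADAD cohort: thickness profiles and participant records.

A cohort couples clinical/biomarker metadata (one :class:`ParticipantRecord`
per participant-visit) with regional mean cortical thickness (one left and
one right :class:`RegionalThicknessProfile` per participant-visit, 34
Desikan-Killiany regions each).

Group semantics follow the ADAD literature: CTR are mutation-negative family
members (CDR 0), AMC are asymptomatic mutation carriers (CDR 0), SMC are
symptomatic carriers (CDR >= 0.5), subdivided into SMC-MCI (CDR = 0.5) and
SMC-AD (CDR >= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .atlas import DESIKAN_KILLIANY_REGIONS, N_REGIONS


class ValidationError(ValueError):
    """Raised when input data violate a cohort invariant."""


GROUPS = ("CTR", "AMC", "SMC")
SMC_SUBGROUPS = ("none", "SMC_MCI", "SMC_AD")
MUTATION_GENES = ("none", "PSEN1", "PSEN2", "APP")
APOE_GENOTYPES = ("2/2", "2/3", "2/4", "3/3", "3/4", "4/4")
SEXES = ("female", "male")  # female first: reference level in covariate models
COHORT_TEMPLATES = ("barcelona_like", "dian_like")
VALID_CDR = (0.0, 0.5, 1.0, 2.0, 3.0)


def compute_eyo(age_years: float, parent_onset_age_years: float) -> float:
    """Estimated years from symptom onset.

    The participant's age at the visit minus the age at which the affected
    parent first developed symptoms; negative before the expected onset.
    Symptom-onset age is highly heritable within ADAD families, which is what
    makes this a usable disease clock.
    """
    if not (age_years > 0 and parent_onset_age_years > 0):
        raise ValueError(
            "age_years and parent_onset_age_years must both be positive; got "
            f"{age_years!r}, {parent_onset_age_years!r}"
        )
    return float(age_years) - float(parent_onset_age_years)


def smc_subgroup_from_cdr(group: str, cdr: float) -> str:
    """Derive the symptomatic subgroup label from CDR (SMC only)."""
    if group != "SMC":
        return "none"
    return "SMC_MCI" if cdr == 0.5 else "SMC_AD"


def apoe_e4_carrier_from_genotype(genotype: Optional[str]) -> Optional[bool]:
    if genotype is None:
        return None
    return "4" in genotype


@dataclass(frozen=True)
class RegionalThicknessProfile:
    """One hemisphere's 34 regional mean thicknesses for one participant-visit."""

    participant_id: str
    visit: int
    hemisphere: str  # "left" | "right"
    regions: tuple[str, ...]
    values_mm: np.ndarray  # shape (34,), strictly positive, region order = regions

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValidationError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.visit < 0:
            raise ValidationError(f"visit index must be non-negative, got {self.visit}")
        if len(self.regions) != N_REGIONS:
            raise ValidationError(
                f"expected {N_REGIONS} regions, got {len(self.regions)} "
                f"({self.participant_id}, visit {self.visit}, {self.hemisphere})"
            )
        unknown = set(self.regions) - set(DESIKAN_KILLIANY_REGIONS)
        if unknown:
            raise ValidationError(f"unknown Desikan-Killiany region(s): {sorted(unknown)}")
        vals = np.asarray(self.values_mm, dtype=float)
        object.__setattr__(self, "values_mm", vals)
        if vals.shape != (N_REGIONS,):
            raise ValidationError(f"values_mm must have shape ({N_REGIONS},), got {vals.shape}")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            bad = self.regions[int(np.argmin(np.isfinite(vals) & (vals > 0)))]
            raise ValidationError(
                f"thickness must be strictly positive and finite; offending region "
                f"{bad!r} ({self.participant_id}, visit {self.visit}, {self.hemisphere})"
            )

    @classmethod
    def from_mapping(
        cls, participant_id: str, visit: int, hemisphere: str, values: Mapping[str, float]
    ) -> "RegionalThicknessProfile":
        """Build a profile from a region->thickness mapping, normalizing to atlas order."""
        missing = [r for r in DESIKAN_KILLIANY_REGIONS if r not in values]
        if missing:
            raise ValidationError(
                f"missing region(s) {missing} for {participant_id} visit {visit} {hemisphere}"
            )
        extra = set(values) - set(DESIKAN_KILLIANY_REGIONS)
        if extra:
            raise ValidationError(f"unrecognized region(s): {sorted(extra)}")
        vals = np.array([float(values[r]) for r in DESIKAN_KILLIANY_REGIONS])
        return cls(participant_id, visit, hemisphere, DESIKAN_KILLIANY_REGIONS, vals)


@dataclass
class ParticipantRecord:
    """Clinical and biomarker metadata for one participant-visit."""

    participant_id: str
    group: str  # CTR | AMC | SMC
    sex: str  # female | male
    age_years: float
    visit: int = 0
    cohort: str = "barcelona_like"
    smc_subgroup: Optional[str] = None  # derived from cdr when None
    mutation_gene: str = "none"
    apoe_genotype: Optional[str] = None
    apoe_e4_carrier: Optional[bool] = None
    parent_onset_age_years: Optional[float] = None
    eyo_years: Optional[float] = None
    cdr: float = 0.0
    mmse: Optional[int] = None
    csf_nfl_pg_ml: Optional[float] = None
    plasma_nfl_pg_ml: Optional[float] = None
    hippocampal_volume_mm3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group label {self.group!r} (expected one of {GROUPS})")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.cohort not in COHORT_TEMPLATES:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.mutation_gene not in MUTATION_GENES:
            raise ValidationError(f"unknown mutation gene {self.mutation_gene!r}")
        if not (self.age_years > 0):
            raise ValidationError(f"age_years must be positive, got {self.age_years}")
        if self.visit < 0:
            raise ValidationError("visit index must be non-negative")
        if self.cdr not in VALID_CDR:
            raise ValidationError(f"cdr must be one of {VALID_CDR}, got {self.cdr}")
        # CDR/group coherence: the group labels are *defined* by CDR in carriers
        if self.group in ("CTR", "AMC") and self.cdr != 0:
            raise ValidationError(
                f"group {self.group} requires CDR 0 but got {self.cdr} "
                f"({self.participant_id}, visit {self.visit})"
            )
        if self.group == "SMC" and self.cdr < 0.5:
            raise ValidationError(
                f"group SMC requires CDR >= 0.5 but got {self.cdr} ({self.participant_id})"
            )
        derived_sub = smc_subgroup_from_cdr(self.group, self.cdr)
        if self.smc_subgroup is None:
            self.smc_subgroup = derived_sub
        elif self.smc_subgroup != derived_sub:
            raise ValidationError(
                f"smc_subgroup {self.smc_subgroup!r} inconsistent with group={self.group}, "
                f"cdr={self.cdr} (expected {derived_sub!r})"
            )
        if self.apoe_genotype is not None and self.apoe_genotype not in APOE_GENOTYPES:
            raise ValidationError(f"unknown APOE genotype {self.apoe_genotype!r}")
        derived_e4 = apoe_e4_carrier_from_genotype(self.apoe_genotype)
        if self.apoe_e4_carrier is None:
            self.apoe_e4_carrier = derived_e4
        elif derived_e4 is not None and self.apoe_e4_carrier != derived_e4:
            raise ValidationError(
                f"apoe_e4_carrier={self.apoe_e4_carrier} inconsistent with genotype "
                f"{self.apoe_genotype!r}"
            )
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValidationError(f"MMSE must lie in [0, 30], got {self.mmse}")
        for name in ("csf_nfl_pg_ml", "plasma_nfl_pg_ml", "hippocampal_volume_mm3",
                     "parent_onset_age_years"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValidationError(f"{name} must be positive and finite, got {v}")
        if self.eyo_years is None and self.parent_onset_age_years is not None:
            self.eyo_years = compute_eyo(self.age_years, self.parent_onset_age_years)

    @property
    def is_carrier(self) -> bool:
        return self.group in ("AMC", "SMC")

    @property
    def fine_group(self) -> str:
        """CTR / AMC / SMC_MCI / SMC_AD."""
        return self.smc_subgroup if self.group == "SMC" else self.group


@dataclass
class CohortTable:
    """A validated cohort: participant records plus paired hemispheric profiles."""

    records: list[ParticipantRecord] = field(default_factory=list)
    profiles: list[RegionalThicknessProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        keys = [(r.participant_id, r.visit) for r in self.records]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (participant_id, visit) in records: {dup[:5]}")
        by_key: dict[tuple[str, int], dict[str, RegionalThicknessProfile]] = {}
        for p in self.profiles:
            slot = by_key.setdefault((p.participant_id, p.visit), {})
            if p.hemisphere in slot:
                raise ValidationError(
                    f"duplicate {p.hemisphere} profile for {p.participant_id} visit {p.visit}"
                )
            slot[p.hemisphere] = p
        for k in keys:
            have = by_key.get(k, {})
            if set(have) != {"left", "right"}:
                raise ValidationError(
                    f"participant-visit {k} needs exactly one left and one right profile, "
                    f"found {sorted(have)}"
                )
            if have["left"].regions != have["right"].regions:
                raise ValidationError(f"left/right region order differs for {k}")
        baseline = {pid for pid, v in keys if v == 0}
        all_ids = {pid for pid, _ in keys}
        if all_ids - baseline:
            raise ValidationError(
                f"participants without a baseline (visit 0) record: {sorted(all_ids - baseline)[:5]}"
            )

    def profile_pair(self, participant_id: str, visit: int):
        left = right = None
        for p in self.profiles:
            if p.participant_id == participant_id and p.visit == visit:
                if p.hemisphere == "left":
                    left = p
                else:
                    right = p
        if left is None or right is None:
            raise KeyError((participant_id, visit))
        return left, right

    def iter_pairs(self) -> Iterable[tuple[ParticipantRecord, RegionalThicknessProfile, RegionalThicknessProfile]]:
        by_key: dict[tuple[str, int], dict[str, RegionalThicknessProfile]] = {}
        for p in self.profiles:
            by_key.setdefault((p.participant_id, p.visit), {})[p.hemisphere] = p
        for r in self.records:
            pair = by_key[(r.participant_id, r.visit)]
            yield r, pair["left"], pair["right"]

    @property
    def n_participants(self) -> int:
        return len({r.participant_id for r in self.records})
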