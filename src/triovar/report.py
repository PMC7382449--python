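"""Cohort-level demographic and results summaries."""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Optional

import pandas as pd

from .io import AffectedStatus, FamilyPedigree, Role, Sex
from .prioritize import PrioritizedVariant

__all__ = ["DemographicSummary", "demographic_summary", "per_family_counts"]


@dataclass
class DemographicSummary:
    n_families: int
    n_probands_male: int
    n_probands_female: int
    sex_ratio: Optional[str]  # reduced M:F ratio, None when undefined
    mean_proband_age: Optional[float]
    mean_affected_age: Optional[float]  # probands + affected relatives with known age

    def rounded_proband_age(self) -> Optional[int]:
        return None if self.mean_proband_age is None else round(self.mean_proband_age)

    def rounded_affected_age(self) -> Optional[int]:
        return None if self.mean_affected_age is None else round(self.mean_affected_age)


def demographic_summary(
    pedigrees: list[FamilyPedigree], include_suspected: bool = False
) -> DemographicSummary:
    """Proband male:female ratio and mean ages over the enrolled cohort.

    The affected mean covers probands plus affected relatives with a known
    age; suspected-status individuals join only when ``include_suspected``
    is set.  The ratio is undefined (None) when either sex count is zero.
    """
    probands = [p.proband for p in pedigrees if p.proband is not None]
    n_m = sum(1 for p in probands if p.sex == Sex.MALE)
    n_f = sum(1 for p in probands if p.sex == Sex.FEMALE)
    ratio = None
    if n_m > 0 and n_f > 0:
        d = gcd(n_m, n_f)
        ratio = f"{n_m // d}:{n_f // d}"

    proband_ages = [p.age_years for p in probands if p.age_years is not None]
    affected_ages = list(proband_ages)
    for ped in pedigrees:
        for m in ped.affected_members(include_suspected=include_suspected):
            if m.role != Role.PROBAND and m.age_years is not None:
                affected_ages.append(m.age_years)

    return DemographicSummary(
        n_families=len(pedigrees),
        n_probands_male=n_m,
        n_probands_female=n_f,
        sex_ratio=ratio,
        mean_proband_age=(sum(proband_ages) / len(proband_ages)) if proband_ages else None,
        mean_affected_age=(sum(affected_ages) / len(affected_ages)) if affected_ages else None,
    )


def per_family_counts(results: list[PrioritizedVariant]) -> pd.DataFrame:
    """Number of prioritized variants per family (one row per family)."""
    if not results:
        return pd.DataFrame(columns=["family", "n_variants"])
    counts: dict[str, int] = {}
    for r in results:
        counts[r.family_id] = counts.get(r.family_id, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["family", "n_variants"]
    )
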