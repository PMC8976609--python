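"""Per-province founder-mutation carrier summaries with sample-size masking.

Provinces with few enrolled subjects cannot support frequency claims, so the
map-style summary carries a mask: sample size below 50 is masked dark, 50-99
light, and 100 or more unmasked (the two thresholds are nested; dark
overrides light).  Carrier counts are still reported for masked provinces —
masking is a display contract, not an exclusion — and a spot-size field
proportional to the carrier count is emitted for plotting.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import Gene, Subject, VariantCall

__all__ = ["Mask", "ProvinceSummary", "summarize_geography", "geography_frame"]

UNKNOWN_PROVINCE = "unknown"


class Mask(enum.Enum):
    NONE = "none"
    LIGHT = "light"  # sample size < 100
    DARK = "dark"  # sample size < 50


def mask_for(sample_size: int) -> Mask:
    if sample_size < 50:
        return Mask.DARK
    if sample_size < 100:
        return Mask.LIGHT
    return Mask.NONE


@dataclass(frozen=True)
class ProvinceSummary:
    province: str
    sample_size: int
    carrier_counts: dict[str, int]  # "GENE:c.x" -> distinct carriers
    mask: Mask


def summarize_geography(
    subjects: Sequence[Subject],
    variants: Sequence[VariantCall],
    mutations: Sequence[tuple[Gene | str, str]],
) -> list[ProvinceSummary]:
    """Carrier counts per province for each requested (gene, hgvs_c) mutation.

    Subjects without a province fall into the "unknown" bucket; masked
    provinces are flagged, never dropped, so national totals stay conserved.
    """
    mutations = [(Gene(g) if isinstance(g, str) else g, m) for g, m in mutations]
    province_of = {
        s.subject_id: (s.province or UNKNOWN_PROVINCE) for s in subjects
    }
    sample_sizes = Counter(province_of.values())
    keys = [f"{g.value}:{m}" for g, m in mutations]
    per_province: dict[str, dict[str, set]] = {
        p: {k: set() for k in keys} for p in sample_sizes
    }
    wanted = {(g, m): f"{g.value}:{m}" for g, m in mutations}
    for v in variants:
        key = wanted.get((v.gene, v.hgvs_c))
        if key is not None and v.deleterious and v.subject_id in province_of:
            per_province[province_of[v.subject_id]][key].add(v.subject_id)
    return [
        ProvinceSummary(
            province=p,
            sample_size=sample_sizes[p],
            carrier_counts={k: len(s) for k, s in per_province[p].items()},
            mask=mask_for(sample_sizes[p]),
        )
        for p in sorted(sample_sizes)
    ]


def geography_frame(summaries: Sequence[ProvinceSummary]) -> pd.DataFrame:
    """Long-format plotting-ready table: one row per province per mutation."""
    rows = []
    for s in summaries:
        for mut, n in s.carrier_counts.items():
            rows.append(
                {
                    "province": s.province,
                    "sample_size": s.sample_size,
                    "mutation": mut,
                    "carriers": n,
                    "spot_size": n,  # spot size unit = carrier count
                    "mask": s.mask.value,
                }
            )
    return pd.DataFrame(rows)
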