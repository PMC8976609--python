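"""STR marker association and core-haplotype sharing around a founder mutation.

A founder mutation descends from one ancestral chromosome, so its carriers
share flanking marker alleles far in excess of population frequencies, with
sharing decaying as recombination separates distant markers from the focal
locus.  Two summaries are provided: a per-marker Pearson chi-square test of
allele frequencies between carriers and controls, and a core-haplotype
sharing table (modal carrier allele per marker vs its control frequency)
with a founder-effect flag when carriers beat controls at >= k consecutive
markers.

Haplotype phasing is not performed here: the sharing summary consumes
externally phased chromosome vectors, or falls back to genotype-level
summaries labelled "unphased".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError

__all__ = [
    "DEFAULT_PANEL",
    "StrGenotype",
    "MarkerTestResult",
    "MarkerSharing",
    "SharingSummary",
    "allele_freq_test",
    "core_haplotype_sharing",
]

#: nine polymorphic STRs flanking BRCA1 (~5.8 Mbp), ordered along the chromosome
DEFAULT_PANEL = (
    "D17S800",
    "D17S1320",
    "D17S1321",
    "D17S855",
    "D17S1323",
    "D17S1327",
    "D17S1326",
    "D17S1325",
    "D17S791",
)


@dataclass(frozen=True)
class StrGenotype:
    subject_id: str
    marker: str
    alleles: tuple[str, str]  # unordered pair of repeat-length labels


@dataclass(frozen=True)
class MarkerTestResult:
    marker: str
    table: pd.DataFrame  # allele x group counts
    chi2: float | None
    df: int
    p: float | None
    note: str = ""


@dataclass(frozen=True)
class MarkerSharing:
    marker: str
    modal_allele: str
    carrier_frequency: float
    control_frequency: float


@dataclass(frozen=True)
class SharingSummary:
    markers: list[MarkerSharing]
    founder_flag: bool
    phased: bool


def _allele_counts(genotypes: Iterable[StrGenotype], marker: str) -> Counter:
    counts: Counter = Counter()
    for g in genotypes:
        if g.marker == marker:
            counts.update(a for a in g.alleles if a not in ("", None))
    return counts


def allele_freq_test(
    carrier_genotypes: Sequence[StrGenotype],
    control_genotypes: Sequence[StrGenotype],
    marker: str,
    panel: Sequence[str] = DEFAULT_PANEL,
    pool_rare: bool = False,
    rare_threshold: int = 5,
) -> MarkerTestResult:
    """Pearson chi-square comparing allele counts between carriers and controls.

    Each typed subject contributes two allele observations.  Alleles seen
    fewer than ``rare_threshold`` times overall can be pooled into an
    "other" class (``pool_rare=True``, off by default).  A monomorphic table
    (df = 0) is reported untested with a notice.
    """
    if marker not in panel:
        raise ConfigurationError(f"marker {marker!r} not in panel")
    carr = _allele_counts(carrier_genotypes, marker)
    ctrl = _allele_counts(control_genotypes, marker)
    if not carr or not ctrl:
        raise DomainError(f"marker {marker}: need typed subjects in both groups")
    alleles = sorted(set(carr) | set(ctrl))
    if pool_rare:
        total = carr + ctrl
        rare = [a for a in alleles if total[a] < rare_threshold]
        if len(rare) > 1:
            alleles = [a for a in alleles if a not in rare] + ["other"]
            carr["other"] = sum(carr.pop(a, 0) for a in rare)
            ctrl["other"] = sum(ctrl.pop(a, 0) for a in rare)
    table = pd.DataFrame(
        {"carriers": [carr.get(a, 0) for a in alleles], "controls": [ctrl.get(a, 0) for a in alleles]},
        index=pd.Index(alleles, name="allele"),
    )
    df = (len(alleles) - 1) * (table.shape[1] - 1)
    if df == 0:
        return MarkerTestResult(
            marker=marker, table=table, chi2=None, df=0, p=None, note="monomorphic: test skipped"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table.values, correction=False)
    return MarkerTestResult(marker=marker, table=table, chi2=float(chi2), df=int(dof), p=float(p))


def _chromosome_vectors(
    phased: pd.DataFrame, panel: Sequence[str]
) -> dict[tuple[str, int], dict[str, str]]:
    required = {"subject_id", "chrom_index", "marker", "allele"}
    missing = required - set(phased.columns)
    if missing:
        raise ConfigurationError(
            "phased table missing column(s) "
            + ", ".join(sorted(missing))
            + " — supply externally phased haplotypes"
        )
    vectors: dict[tuple[str, int], dict[str, str]] = {}
    for rec in phased.to_dict("records"):
        key = (str(rec["subject_id"]), int(rec["chrom_index"]))
        vectors.setdefault(key, {})[str(rec["marker"])] = str(rec["allele"])
    return vectors


def core_haplotype_sharing(
    phased: pd.DataFrame,
    carrier_ids: set[str],
    panel: Sequence[str] = DEFAULT_PANEL,
    k_consecutive: int = 3,
) -> SharingSummary:
    """Per-marker modal carrier allele and its carrier vs control chromosome frequency.

    ``phased`` is a tidy table ``subject_id, chrom_index (1|2), marker,
    allele`` of externally reconstructed haplotypes.  The founder-effect flag
    is set when the carrier modal allele exceeds its control frequency at
    >= ``k_consecutive`` consecutive markers of the panel.
    """
    vectors = _chromosome_vectors(phased, panel)
    carrier_chroms = [v for (sid, _), v in vectors.items() if sid in carrier_ids]
    control_chroms = [v for (sid, _), v in vectors.items() if sid not in carrier_ids]
    if not carrier_chroms or not control_chroms:
        raise DomainError("need phased chromosomes for both carriers and controls")
    markers_out: list[MarkerSharing] = []
    exceeds = []
    for marker in panel:
        carr = Counter(v[marker] for v in carrier_chroms if marker in v)
        ctrl = Counter(v[marker] for v in control_chroms if marker in v)
        if not carr:
            continue
        modal, modal_n = carr.most_common(1)[0]
        f_carr = modal_n / sum(carr.values())
        f_ctrl = ctrl.get(modal, 0) / sum(ctrl.values()) if ctrl else float("nan")
        markers_out.append(
            MarkerSharing(
                marker=marker,
                modal_allele=modal,
                carrier_frequency=f_carr,
                control_frequency=f_ctrl,
            )
        )
        exceeds.append(f_carr > f_ctrl)
    flag = _has_run(exceeds, k_consecutive)
    return SharingSummary(markers=markers_out, founder_flag=flag, phased=True)


def _has_run(flags: Sequence[bool], k: int) -> bool:
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= k:
            return True
    return False
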