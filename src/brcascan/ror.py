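"""Per-bin odds ratios, the ratio-of-odds-ratios (ROR) statistic, and region calls.

For each bin along the coding sequence, carriers of a deleterious variant in
the bin are compared against gene-wide non-carriers in three phenotype arms:
breast cancer, ovarian cancer and cancer-free.  The bin's breast OR and
ovarian OR each use the cancer-free arm as reference, so their ratio

    ROR = OR_breast / OR_ovarian = (b_bin * O_nc) / (B_nc * o_bin)

algebraically cancels the control arm and reduces to the odds ratio of the
2x2 table (breast-in-bin, breast non-carrier; ovarian-in-bin, ovarian
non-carrier).  The confidence interval and p-value are computed on that
reduced table: Woolf (log) 95% CI, two-sided normal test on ln ROR, with an
exact conditional test available behind a flag.  Per-gene Benjamini-Hochberg
adjustment of the bin p-values then yields the cluster-region calls:
adjusted p < alpha with ROR < 1 is an ovarian cluster region (OCCR), with
ROR > 1 a breast cluster region (BCCR).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binning import Bin, build_bins
from .cohort import Gene, Status, Subject, VariantCall
from .errors import DomainError, UndefinedOddsRatioError

__all__ = [
    "RegionCall",
    "BinPhenotypeCounts",
    "OddsRatio",
    "BinStats",
    "odds_ratio",
    "ror_stats",
    "bh_adjust",
    "call_regions",
    "scan",
    "interval_counts",
]

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


class RegionCall(enum.Enum):
    OCCR = "OCCR"
    BCCR = "BCCR"
    NONE = "none"


@dataclass(frozen=True)
class BinPhenotypeCounts:
    """Carrier and non-carrier counts per phenotype arm for one bin."""

    b_bin: int  # breast-cancer subjects carrying a deleterious variant in the bin
    o_bin: int  # ovarian analogue
    c_bin: int  # cancer-free analogue
    B_nc: int  # breast-cancer gene-wide non-carriers
    O_nc: int
    C_nc: int

    def __post_init__(self):
        for name in ("b_bin", "o_bin", "c_bin", "B_nc", "O_nc", "C_nc"):
            if getattr(self, name) < 0:
                raise DomainError(f"count {name} must be >= 0")


@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    se_log: float
    corrected: bool  # whether the +0.5 zero-cell correction was applied


@dataclass
class BinStats:
    bin: Bin | None
    counts: BinPhenotypeCounts
    or_breast: float
    or_ovarian: float
    ror: float
    ci95: tuple[float, float]
    p_raw: float
    p_adj: float | None = None
    call: RegionCall = RegionCall.NONE
    se_log: float = field(default=float("nan"), repr=False)


def odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatio:
    """Cross-product odds ratio of the 2x2 table [[a, b], [c, d]] with Woolf 95% CI.

    If any cell is zero, 0.5 is added to all four cells (Haldane-Anscombe)
    so the estimate and CI stay finite.  An all-zero table is undefined.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise DomainError("contingency counts must be >= 0")
    if all(x == 0 for x in cells):
        raise UndefinedOddsRatioError("odds ratio undefined on an all-zero table")
    corrected = any(x == 0 for x in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(value)
    return OddsRatio(
        value=value,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        se_log=se,
        corrected=corrected,
    )


def ror_stats(
    counts: BinPhenotypeCounts, bin: Bin | None = None, exact: bool = False
) -> BinStats:
    """ROR, CI and raw p for one bin (no multiplicity adjustment).

    The cancer-free arm cancels exactly in the ratio, so ROR, CI and p are
    computed on the reduced table (b_bin, B_nc; o_bin, O_nc) and are invariant
    to the control counts.  ``exact=True`` replaces the normal test on ln ROR
    with Fisher's exact test on the reduced table.
    """
    or_breast = odds_ratio(counts.b_bin, counts.B_nc, counts.c_bin, counts.C_nc).value
    or_ovarian = odds_ratio(counts.o_bin, counts.O_nc, counts.c_bin, counts.C_nc).value
    reduced = odds_ratio(counts.b_bin, counts.B_nc, counts.o_bin, counts.O_nc)
    if exact:
        table = [[counts.b_bin, counts.B_nc], [counts.o_bin, counts.O_nc]]
        p_raw = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        z = math.log(reduced.value) / reduced.se_log
        p_raw = float(2 * stats.norm.sf(abs(z)))
    return BinStats(
        bin=bin,
        counts=counts,
        or_breast=or_breast,
        or_ovarian=or_ovarian,
        ror=reduced.value,
        ci95=(reduced.ci_low, reduced.ci_high),
        p_raw=p_raw,
        se_log=reduced.se_log,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order preserved on return."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def call_regions(stats_list: Sequence[BinStats], alpha: float = 0.05) -> list[BinStats]:
    """BH-adjust the bins' raw p-values (per gene) and set the OCCR/BCCR calls."""
    adj = bh_adjust([s.p_raw for s in stats_list])
    for s, pa in zip(stats_list, adj):
        s.p_adj = float(pa)
        if pa < alpha:
            s.call = RegionCall.OCCR if s.ror < 1 else RegionCall.BCCR
        else:
            s.call = RegionCall.NONE
    return list(stats_list)


def interval_counts(
    subjects: Sequence[Subject],
    variants: Sequence[VariantCall],
    gene: Gene | str,
    start: int,
    end: int,
    include_double_primary: bool = False,
) -> BinPhenotypeCounts:
    """Phenotype counts for one fixed CDS interval [start, end] (both inclusive).

    Exposure = carrying a deleterious variant of the gene whose representative
    coordinate base lies in the interval; reference = gene-wide non-carriers.
    Useful for evaluating a designed region directly, without binning.
    """
    gene = Gene(gene) if isinstance(gene, str) else gene
    carrier_pos: dict[str, list[int]] = {}
    for v in variants:
        if v.deleterious and v.gene == gene:
            if v.cds_coord is None:
                raise DomainError(f"variant {v.hgvs_c} has no parsed CDS coordinate")
            carrier_pos.setdefault(v.subject_id, []).append(v.cds_coord.base)
    counts = {"b_bin": 0, "o_bin": 0, "c_bin": 0, "B_nc": 0, "O_nc": 0, "C_nc": 0}
    arm_keys = {
        Status.BREAST: [("b_bin", "B_nc")],
        Status.OVARY: [("o_bin", "O_nc")],
        Status.CANCER_FREE: [("c_bin", "C_nc")],
    }
    if include_double_primary:
        arm_keys[Status.BREAST_AND_OVARY] = [("b_bin", "B_nc"), ("o_bin", "O_nc")]
    for s in subjects:
        keys = arm_keys.get(s.status)
        if not keys:
            continue
        pos = carrier_pos.get(s.subject_id)
        for in_key, nc_key in keys:
            if pos is None:
                counts[nc_key] += 1
            elif any(start <= p <= end for p in pos):
                counts[in_key] += 1
            # carriers outside the interval belong to neither arm of the table
    return BinPhenotypeCounts(**counts)


def scan(
    subjects: Sequence[Subject],
    variants: Sequence[VariantCall],
    gene: Gene | str,
    n_bins: int,
    alpha: float = 0.05,
    exact: bool = False,
    include_double_primary: bool = False,
) -> list[BinStats]:
    """Full cluster-region scan for one gene.

    Builds near-equal-carrier bins from the gene's deleterious variant
    positions, tabulates per-bin phenotype counts against gene-wide
    non-carriers, computes ROR statistics and calls OCCR/BCCR after per-gene
    BH adjustment.

    Subjects with both breast and ovarian primaries are excluded from both
    case arms unless ``include_double_primary`` (then they count in both).
    Subjects whose deleterious variants fall in more than one bin are
    excluded from the carrier counts with a logged warning.
    """
    gene = Gene(gene) if isinstance(gene, str) else gene
    by_subject: dict[str, Subject] = {s.subject_id: s for s in subjects}

    # per-subject positions of deleterious variants in this gene
    positions: dict[str, set] = {}
    for v in variants:
        if v.deleterious and v.gene == gene:
            if v.cds_coord is None:
                raise DomainError(f"variant {v.hgvs_c} has no parsed CDS coordinate")
            positions.setdefault(v.subject_id, set()).add(v.cds_coord)

    # binning uses each carrier once, anchored at the 5'-most of their variants
    rep_positions = [min(pos) for pos in positions.values()]
    bins = build_bins(rep_positions, n_bins, gene=gene.value)

    def bin_index(coord) -> int | None:
        for b in bins:
            if b.start <= coord <= b.end:
                return b.index
        return None

    def arms_for(subject: Subject) -> list[str]:
        if subject.status == Status.BREAST:
            return ["breast"]
        if subject.status == Status.OVARY:
            return ["ovarian"]
        if subject.status == Status.BREAST_AND_OVARY:
            return ["breast", "ovarian"] if include_double_primary else []
        if subject.status == Status.CANCER_FREE:
            return ["control"]
        return []

    carriers_in_bin: dict[int, dict[str, int]] = {
        b.index: {"breast": 0, "ovarian": 0, "control": 0} for b in bins
    }
    nc_totals = {"breast": 0, "ovarian": 0, "control": 0}
    n_multibin = 0
    for sid, subject in by_subject.items():
        arms = arms_for(subject)
        if sid in positions:
            idxs = {bin_index(c) for c in positions[sid]}
            if len(idxs) > 1:
                n_multibin += 1
                continue  # ambiguous exposure: dropped from the scan
            (idx,) = idxs
            for arm in arms:
                carriers_in_bin[idx][arm] += 1
        else:
            for arm in arms:
                nc_totals[arm] += 1
    if n_multibin:
        logger.warning(
            "%d subject(s) with deleterious %s variants in multiple bins excluded from scan",
            n_multibin,
            gene.value,
        )

    stats_list = [
        ror_stats(
            BinPhenotypeCounts(
                b_bin=carriers_in_bin[b.index]["breast"],
                o_bin=carriers_in_bin[b.index]["ovarian"],
                c_bin=carriers_in_bin[b.index]["control"],
                B_nc=nc_totals["breast"],
                O_nc=nc_totals["ovarian"],
                C_nc=nc_totals["control"],
            ),
            bin=b,
            exact=exact,
        )
        for b in bins
    ]
    return call_regions(stats_list, alpha=alpha)
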