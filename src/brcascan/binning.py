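"""Partition observed carrier positions into contiguous bins of near-equal carrier count.

The region scan needs segments of the coding sequence that each contain a
roughly equal number of deleterious-mutation carriers, so that every bin's
odds ratios rest on comparable information.  Bin boundaries are observed
variant positions: all carriers sharing a position (a founder hotspot) stay
together, and gaps between consecutive bins are expected — bins span observed
variants, not the full CDS.

Algorithm: cut the sorted carrier-position multiset at its empirical
quantiles, then make one repair pass moving each internal boundary one
observed position left or right whenever that reduces the max-min spread of
bin counts.  This is a heuristic; an exhaustive cut-point search is provided
for small instances as a test oracle.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InfeasibleBinningError
from .hgvs import CdsCoordinate

__all__ = ["Bin", "build_bins", "brute_force_bins", "count_spread", "n_bins_for_target"]


@dataclass(frozen=True)
class Bin:
    gene: str
    index: int  # 1-based
    start: CdsCoordinate
    end: CdsCoordinate
    carrier_count: int


def _grouped(positions: Iterable[CdsCoordinate]) -> tuple[list[CdsCoordinate], list[int]]:
    counter = Counter(positions)
    uniq = sorted(counter)
    return uniq, [counter[p] for p in uniq]


def count_spread(counts: Sequence[int]) -> int:
    return max(counts) - min(counts)


def _bins_from_cuts(
    uniq: list[CdsCoordinate], counts: list[int], cuts: Sequence[int], gene: str
) -> list[Bin]:
    """cuts are indices into uniq: bin k covers uniq[cuts[k-1]:cuts[k]]."""
    bounds = [0, *cuts, len(uniq)]
    bins = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        bins.append(
            Bin(
                gene=gene,
                index=k + 1,
                start=uniq[lo],
                end=uniq[hi - 1],
                carrier_count=sum(counts[lo:hi]),
            )
        )
    return bins


def _quantile_cuts(counts: list[int], n_bins: int) -> list[int]:
    """Greedy walk placing each cut where cumulative count best matches k*N/n_bins."""
    total = sum(counts)
    cuts: list[int] = []
    cum = 0
    idx = 0
    for k in range(1, n_bins):
        target = k * total / n_bins
        # advance while the next group brings us closer to (or not past) the target
        while idx < len(counts) - (n_bins - k) and abs(cum + counts[idx] - target) <= abs(
            cum - target
        ):
            cum += counts[idx]
            idx += 1
        # ensure at least one group per bin
        min_idx = (cuts[-1] if cuts else 0) + 1
        idx = max(idx, min_idx)
        cum = sum(counts[:idx])
        cuts.append(idx)
    return cuts


def _repair_pass(counts: list[int], cuts: list[int]) -> list[int]:
    """One left-to-right pass shifting each cut +/-1 group if it reduces the spread."""
    cuts = list(cuts)
    m = len(counts)
    for j in range(len(cuts)):
        best = cuts[j]
        lo = (cuts[j - 1] if j > 0 else 0) + 1
        hi = (cuts[j + 1] if j + 1 < len(cuts) else m) - 1
        current = _spread_for(counts, cuts)
        for cand in (cuts[j] - 1, cuts[j] + 1):
            if lo <= cand <= hi:
                trial = cuts[:j] + [cand] + cuts[j + 1 :]
                if _spread_for(counts, trial) < current:
                    best, current = cand, _spread_for(counts, trial)
        cuts[j] = best
    return cuts


def _spread_for(counts: Sequence[int], cuts: Sequence[int]) -> int:
    bounds = [0, *cuts, len(counts)]
    bin_counts = [sum(counts[bounds[k] : bounds[k + 1]]) for k in range(len(bounds) - 1)]
    return count_spread(bin_counts)


def build_bins(
    carrier_positions: Iterable[CdsCoordinate],
    n_bins: int,
    gene: str = "",
    repair: bool = True,
) -> list[Bin]:
    """Bin a multiset of carrier positions into ``n_bins`` near-equal-count bins.

    Raises :class:`~brcascan.errors.InfeasibleBinningError` when there are
    fewer distinct positions than requested bins.  Set ``repair=False`` for
    the plain quantile cut without the boundary-repair pass.
    """
    if n_bins < 1:
        raise InfeasibleBinningError(f"n_bins must be >= 1, got {n_bins}")
    uniq, counts = _grouped(carrier_positions)
    if len(uniq) < n_bins:
        raise InfeasibleBinningError(
            f"{n_bins} bins requested but only {len(uniq)} distinct carrier positions"
        )
    cuts = _quantile_cuts(counts, n_bins)
    if repair:
        cuts = _repair_pass(counts, cuts)
    return _bins_from_cuts(uniq, counts, cuts, gene)


def brute_force_bins(
    carrier_positions: Iterable[CdsCoordinate], n_bins: int, gene: str = ""
) -> list[Bin]:
    """Exhaustive cut-point search minimizing the max-min carrier-count spread.

    Exponential in the number of distinct positions; intended as an oracle on
    small instances.
    """
    uniq, counts = _grouped(carrier_positions)
    if len(uniq) < n_bins:
        raise InfeasibleBinningError(
            f"{n_bins} bins requested but only {len(uniq)} distinct carrier positions"
        )
    best_cuts = None
    best_spread = None
    for cuts in itertools.combinations(range(1, len(uniq)), n_bins - 1):
        s = _spread_for(counts, cuts)
        if best_spread is None or s < best_spread:
            best_spread, best_cuts = s, list(cuts)
    return _bins_from_cuts(uniq, counts, best_cuts, gene)


def n_bins_for_target(n_carriers: int, carriers_per_bin: int = 60) -> int:
    """Number of bins putting roughly ``carriers_per_bin`` carriers in each."""
    if carriers_per_bin < 1:
        raise ValueError("carriers_per_bin must be >= 1")
    return max(1, round(n_carriers / carriers_per_bin))
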