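"""Bayes allelic penetrance estimation for individual recurrent mutations.

Penetrance here is the lifetime probability that a carrier of a specific
deleterious mutation develops breast cancer.  Given the mutation's carrier
frequency among cases (f_case), among cancer-free controls (f_ctrl) and the
population lifetime risk K, Bayes' theorem inverts the case-control
frequencies:

    P(disease | carrier) = f_case * K / (f_case * K + f_ctrl * (1 - K))

The default K = 0.053 is the estimated mean lifetime breast-cancer risk for
Chinese women (Gail model); 0.35 is the approximate lower bound of published
carrier risks and serves as the minimum-expected-penetrance reference line.
A mutation never seen in controls yields penetrance 1.0 ("complete
penetrance") — the uncorrected estimator is deliberately the default, with
optional +0.5 count smoothing behind a flag.

Controls default to the cancer-free, family-history-negative subset: an
unselected healthy cohort member with a positive family history is not an
appropriate baseline for sporadic risk.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

from .cohort import FamilyHistory, Gene, Status, Subject, VariantCall
from .errors import DomainError, UndefinedPenetranceError

__all__ = [
    "DEFAULT_LIFETIME_RISK",
    "REFERENCE_PENETRANCE",
    "Stratum",
    "PenetranceInput",
    "PenetranceEstimate",
    "bayes_penetrance",
    "carrier_frequencies",
    "stratified_penetrance",
]

logger = logging.getLogger(__name__)

DEFAULT_LIFETIME_RISK = 0.053
REFERENCE_PENETRANCE = 0.35


class Stratum(enum.Enum):
    ALL = "all"
    FH_POSITIVE = "FH_positive"
    FH_NEGATIVE = "FH_negative"


@dataclass(frozen=True)
class PenetranceInput:
    f_case: float
    f_ctrl: float
    k: float = DEFAULT_LIFETIME_RISK
    n_case: int | None = None
    n_ctrl: int | None = None

    def __post_init__(self):
        if not (0 <= self.f_case <= 1 and 0 <= self.f_ctrl <= 1):
            raise DomainError("carrier frequencies must lie in [0, 1]")
        if not (0 < self.k < 1):
            raise DomainError("lifetime risk K must lie in (0, 1)")


@dataclass(frozen=True)
class PenetranceEstimate:
    penetrance: float
    above_reference: bool
    stratum: Stratum = Stratum.ALL
    input: PenetranceInput | None = None


def bayes_penetrance(
    inp: PenetranceInput, stratum: Stratum = Stratum.ALL
) -> PenetranceEstimate:
    """Evaluate the Bayes allelic penetrance formula on case/control carrier frequencies."""
    if inp.f_case == 0 and inp.f_ctrl == 0:
        raise UndefinedPenetranceError(
            "penetrance undefined: mutation absent from both cases and controls"
        )
    num = inp.f_case * inp.k
    pen = num / (num + inp.f_ctrl * (1 - inp.k))
    return PenetranceEstimate(
        penetrance=pen,
        above_reference=pen >= REFERENCE_PENETRANCE,
        stratum=stratum,
        input=inp,
    )


def carrier_frequencies(
    subjects: Sequence[Subject],
    variants: Sequence[VariantCall],
    gene: Gene | str,
    mutation: str,
    controls: str = "fh-negative",
    fh: FamilyHistory | None = None,
    k: float = DEFAULT_LIFETIME_RISK,
    smoothing: float = 0.0,
    allele_mode: bool = False,
) -> PenetranceInput:
    """Carrier frequencies of one mutation among breast-cancer cases and controls.

    ``controls`` is ``"fh-negative"`` (cancer-free with negative family
    history, the default baseline) or ``"all-cancer-free"``.  ``fh`` restricts
    both arms to one family-history stratum.  ``smoothing`` adds a
    pseudo-count to the carrier numerators and denominators (off by default:
    the uncorrected estimator is what yields complete penetrance when no
    control carrier is seen).  ``allele_mode`` divides by chromosomes (2N)
    instead of subjects; for rare heterozygous mutations the two conventions
    give identical penetrance because the factor 2 cancels.
    """
    gene = Gene(gene) if isinstance(gene, str) else gene
    mut_carriers = {
        v.subject_id
        for v in variants
        if v.deleterious and v.gene == gene and v.hgvs_c == mutation
    }
    cases = [s for s in subjects if s.status == Status.BREAST]
    if controls == "fh-negative":
        ctrls = [
            s
            for s in subjects
            if s.status == Status.CANCER_FREE and s.family_history == FamilyHistory.NEGATIVE
        ]
    elif controls == "all-cancer-free":
        ctrls = [s for s in subjects if s.status == Status.CANCER_FREE]
    else:
        raise DomainError(f"unknown control set {controls!r}")
    if fh is not None:
        cases = [s for s in cases if s.family_history == fh]
        ctrls = [s for s in ctrls if s.family_history == fh]
    n_case, n_ctrl = len(cases), len(ctrls)
    if n_case == 0 or n_ctrl == 0:
        raise DomainError("empty case or control arm")
    ploidy = 2 if allele_mode else 1
    x_case = sum(s.subject_id in mut_carriers for s in cases) + smoothing
    x_ctrl = sum(s.subject_id in mut_carriers for s in ctrls) + smoothing
    return PenetranceInput(
        f_case=x_case / (ploidy * n_case + 2 * smoothing),
        f_ctrl=x_ctrl / (ploidy * n_ctrl + 2 * smoothing),
        k=k,
        n_case=n_case,
        n_ctrl=n_ctrl,
    )


def stratified_penetrance(
    subjects: Sequence[Subject],
    variants: Sequence[VariantCall],
    gene: Gene | str,
    mutation: str,
    k: float = DEFAULT_LIFETIME_RISK,
    controls: str = "fh-negative",
) -> list[PenetranceEstimate]:
    """Penetrance pooled and per family-history stratum.

    Returns one estimate per non-empty stratum plus the pooled estimate;
    empty strata are skipped with a warning.  When strata sit on opposite
    sides of the 0.35 reference (penetrance "subject to family history"),
    the disagreement is logged.
    """
    out: list[PenetranceEstimate] = []
    for stratum, fh in (
        (Stratum.ALL, None),
        (Stratum.FH_POSITIVE, FamilyHistory.POSITIVE),
        (Stratum.FH_NEGATIVE, FamilyHistory.NEGATIVE),
    ):
        # within the FH-positive stratum the fh-negative control set is empty
        # by construction, so stratified runs compare against all cancer-free
        ctrl_set = "all-cancer-free" if fh is not None else controls
        try:
            inp = carrier_frequencies(
                subjects, variants, gene, mutation, controls=ctrl_set, fh=fh, k=k
            )
            out.append(bayes_penetrance(inp, stratum=stratum))
        except (DomainError, UndefinedPenetranceError) as exc:
            logger.warning("stratum %s skipped: %s", stratum.value, exc)
    flags = {e.above_reference for e in out if e.stratum != Stratum.ALL}
    if len(flags) > 1:
        logger.info(
            "family-history strata fall on opposite sides of the %.2f reference",
            REFERENCE_PENETRANCE,
        )
    return out
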