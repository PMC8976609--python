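"""Domain types and delimited-table I/O for case-control BRCA1/2 cohorts.

The cohort is a flat table of enrolled women (clinical status, age, family
history, province) plus a variant table of germline BRCA1/2 calls in HGVS
cDNA notation.  "Deleterious" means classified pathogenic or likely
pathogenic; a subject with at least one deleterious variant in a gene is a
carrier of that gene.  A subject carrying deleterious variants in both genes
counts once per gene but only once in the overall carrier total, which is how
the per-status carrier column of a clinical summary stays conserved while
per-gene counts may overlap.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, RecordError, UndefinedFractionError
from .hgvs import CdsCoordinate, parse_cdna

__all__ = [
    "Status",
    "FamilyHistory",
    "Gene",
    "Classification",
    "Subject",
    "VariantCall",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "summarize_carriers",
    "recurrent_fraction",
]


class Status(enum.Enum):
    BREAST = "breast"
    OVARY = "ovary"
    BREAST_AND_OVARY = "breast_and_ovary"
    BREAST_OR_OVARY_PLUS_OTHER = "breast_or_ovary_plus_other"
    OTHER_SITE = "other_site"
    CANCER_FREE = "cancer_free"


class FamilyHistory(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class Gene(enum.Enum):
    BRCA1 = "BRCA1"
    BRCA2 = "BRCA2"


class Classification(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    OTHER = "other"


#: common aliases accepted when reading status columns
STATUS_ALIASES: Mapping[str, Status] = {
    **{s.value: s for s in Status},
    "breast cancer": Status.BREAST,
    "ovarian": Status.OVARY,
    "ovary cancer": Status.OVARY,
    "ovarian cancer": Status.OVARY,
    "breast and ovary": Status.BREAST_AND_OVARY,
    "breast or ovary and other sites": Status.BREAST_OR_OVARY_PLUS_OTHER,
    "other sites": Status.OTHER_SITE,
    "other": Status.OTHER_SITE,
    "cancer-free": Status.CANCER_FREE,
    "healthy": Status.CANCER_FREE,
}

_FH_ALIASES: Mapping[str, FamilyHistory] = {
    **{f.value: f for f in FamilyHistory},
    "pos": FamilyHistory.POSITIVE,
    "neg": FamilyHistory.NEGATIVE,
    "yes": FamilyHistory.POSITIVE,
    "no": FamilyHistory.NEGATIVE,
    "": FamilyHistory.UNKNOWN,
    "na": FamilyHistory.UNKNOWN,
    "nan": FamilyHistory.UNKNOWN,
}

DELETERIOUS = frozenset({Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC})


@dataclass(frozen=True)
class Subject:
    subject_id: str
    status: Status
    age: float | None = None
    family_history: FamilyHistory = FamilyHistory.UNKNOWN
    province: str | None = None

    def __post_init__(self):
        if self.age is not None and self.age < 18:
            raise ValueError(f"subject {self.subject_id}: age {self.age} < 18")


@dataclass(frozen=True)
class VariantCall:
    subject_id: str
    gene: Gene
    hgvs_c: str
    classification: Classification
    cds_coord: CdsCoordinate | None = field(default=None, compare=False)

    @property
    def deleterious(self) -> bool:
        return self.classification in DELETERIOUS


@dataclass
class CohortSummary:
    """Per-status carrier/non-carrier counts plus per-gene and per-mutation tallies."""

    status_carriers: dict[Status, int]
    status_noncarriers: dict[Status, int]
    gene_carriers: dict[Gene, int]
    mutation_recurrence: dict[tuple[Gene, str], int]
    n_subjects: int

    @property
    def total_carriers(self) -> int:
        return sum(self.status_carriers.values())

    @property
    def total_noncarriers(self) -> int:
        return sum(self.status_noncarriers.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "status": s.value,
                "carriers": self.status_carriers.get(s, 0),
                "non_carriers": self.status_noncarriers.get(s, 0),
            }
            for s in Status
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_subjects": self.n_subjects,
                "total_carriers": self.total_carriers,
                "status_carriers": {s.value: c for s, c in self.status_carriers.items()},
                "status_noncarriers": {s.value: c for s, c in self.status_noncarriers.items()},
                "gene_carriers": {g.value: c for g, c in self.gene_carriers.items()},
                "mutation_recurrence": {
                    f"{g.value}:{m}": c for (g, m), c in self.mutation_recurrence.items()
                },
            },
            indent=2,
        )


_SUBJECT_COLUMNS = ("subject_id", "status")
_VARIANT_COLUMNS = ("subject_id", "gene", "hgvs_c", "classification")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    # sep=None auto-detects tab vs comma
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_cohort(
    subjects_path: str | Path,
    variants_path: str | Path,
    parse_coordinates: bool = True,
) -> tuple[list[Subject], list[VariantCall]]:
    """Read subject and variant tables (TSV or CSV, auto-detected).

    Every variant must reference an existing subject; unknown columns are
    preserved in the file but ignored here.  Raises
    :class:`~brcascan.errors.ConfigurationError` for missing columns and
    :class:`~brcascan.errors.RecordError` (with line number) for bad records.
    """
    sdf = _read_table(subjects_path)
    _require_columns(sdf, _SUBJECT_COLUMNS, subjects_path)
    subjects: list[Subject] = []
    for i, row in enumerate(sdf.itertuples(index=False), start=2):  # header is line 1
        raw_status = str(row.status).strip().lower()
        status = STATUS_ALIASES.get(raw_status)
        if status is None:
            raise RecordError(f"unmappable status {row.status!r}", line_no=i)
        age_raw = str(getattr(row, "age", "")).strip()
        age = float(age_raw) if age_raw not in ("", "NA", "nan") else None
        fh_raw = str(getattr(row, "family_history", "")).strip().lower()
        fh = _FH_ALIASES.get(fh_raw)
        if fh is None:
            raise RecordError(f"unmappable family history {fh_raw!r}", line_no=i)
        province = str(getattr(row, "province", "")).strip() or None
        try:
            subjects.append(
                Subject(str(row.subject_id), status, age=age, family_history=fh, province=province)
            )
        except ValueError as exc:
            raise RecordError(str(exc), line_no=i) from exc

    known_ids = {s.subject_id for s in subjects}
    vdf = _read_table(variants_path)
    _require_columns(vdf, _VARIANT_COLUMNS, variants_path)
    variants: list[VariantCall] = []
    for i, row in enumerate(vdf.itertuples(index=False), start=2):
        sid = str(row.subject_id)
        if sid not in known_ids:
            raise RecordError(f"variant references unknown subject {sid!r}", line_no=i)
        try:
            gene = Gene(str(row.gene).strip())
        except ValueError as exc:
            raise RecordError(f"unknown gene {row.gene!r}", line_no=i) from exc
        try:
            cls = Classification(str(row.classification).strip())
        except ValueError as exc:
            raise RecordError(f"unknown classification {row.classification!r}", line_no=i) from exc
        hgvs_c = str(row.hgvs_c).strip()
        coord = parse_cdna(hgvs_c) if parse_coordinates else None
        variants.append(VariantCall(sid, gene, hgvs_c, cls, cds_coord=coord))
    return subjects, variants


def write_cohort(
    subjects: Iterable[Subject],
    variants: Iterable[VariantCall],
    subjects_path: str | Path,
    variants_path: str | Path,
    sep: str = "\t",
) -> None:
    """Write subject and variant tables in the same schema :func:`read_cohort` accepts."""
    srows = [
        {
            "subject_id": s.subject_id,
            "status": s.status.value,
            "age": "" if s.age is None else (int(s.age) if float(s.age).is_integer() else s.age),
            "family_history": s.family_history.value,
            "province": s.province or "",
        }
        for s in subjects
    ]
    vrows = [
        {
            "subject_id": v.subject_id,
            "gene": v.gene.value,
            "hgvs_c": v.hgvs_c,
            "classification": v.classification.value,
        }
        for v in variants
    ]
    pd.DataFrame(srows).to_csv(subjects_path, sep=sep, index=False)
    pd.DataFrame(
        vrows, columns=["subject_id", "gene", "hgvs_c", "classification"]
    ).to_csv(variants_path, sep=sep, index=False)


def deleterious_carriers(variants: Iterable[VariantCall]) -> dict[str, set[Gene]]:
    """Map subject_id -> set of genes in which the subject carries a deleterious variant."""
    carriers: dict[str, set[Gene]] = {}
    for v in variants:
        if v.deleterious:
            carriers.setdefault(v.subject_id, set()).add(v.gene)
    return carriers


def summarize_carriers(
    subjects: Sequence[Subject], variants: Sequence[VariantCall]
) -> CohortSummary:
    """Tally carriers and non-carriers per clinical status, gene and mutation.

    A subject with several deleterious variants counts once overall and once
    per gene; mutation recurrence counts distinct subjects per (gene, hgvs_c).
    """
    carriers = deleterious_carriers(variants)
    status_carriers: Counter = Counter()
    status_noncarriers: Counter = Counter()
    for s in subjects:
        if s.subject_id in carriers:
            status_carriers[s.status] += 1
        else:
            status_noncarriers[s.status] += 1
    gene_carriers: Counter = Counter()
    for genes in carriers.values():
        for g in genes:
            gene_carriers[g] += 1
    mutation_subjects: dict[tuple[Gene, str], set[str]] = {}
    for v in variants:
        if v.deleterious:
            mutation_subjects.setdefault((v.gene, v.hgvs_c), set()).add(v.subject_id)
    return CohortSummary(
        status_carriers=dict(status_carriers),
        status_noncarriers=dict(status_noncarriers),
        gene_carriers=dict(gene_carriers),
        mutation_recurrence={k: len(v) for k, v in mutation_subjects.items()},
        n_subjects=len(subjects),
    )


def recurrent_fraction(
    variants: Sequence[VariantCall],
    gene: Gene | str,
    mutation: str,
    denominator: int | None = None,
) -> tuple[int, int, float, str]:
    """Fraction of a gene's deleterious carriers who carry a specific mutation.

    Returns ``(numerator, denominator, proportion, percent_string)`` with the
    percentage rounded to one decimal (e.g. 50/527 -> "9.5%").  ``denominator``
    overrides the carrier count derived from ``variants`` — published per-gene
    denominators differ between contexts (e.g. whether dual-gene carriers are
    included), so both conventions are accepted.
    """
    gene = Gene(gene) if isinstance(gene, str) else gene
    carriers_by_subject = deleterious_carriers(variants)
    gene_carriers = {sid for sid, genes in carriers_by_subject.items() if gene in genes}
    den = denominator if denominator is not None else len(gene_carriers)
    if den <= 0:
        raise UndefinedFractionError(f"no deleterious {gene.value} carriers to use as denominator")
    num = len(
        {
            v.subject_id
            for v in variants
            if v.deleterious and v.gene == gene and v.hgvs_c == mutation
        }
    )
    proportion = num / den
    return num, den, proportion, f"{round(100 * proportion, 1):.1f}%"
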