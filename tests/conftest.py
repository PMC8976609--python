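import pytest

from brcascan.cohort import (
    Classification,
    FamilyHistory,
    Gene,
    Status,
    Subject,
    VariantCall,
)
from brcascan.hgvs import parse_cdna


def make_subject(sid, status, fh=FamilyHistory.UNKNOWN, age=40.0, province=None):
    return Subject(sid, status, age=age, family_history=fh, province=province)


def make_variant(sid, hgvs, gene=Gene.BRCA1, cls=Classification.PATHOGENIC):
    return VariantCall(sid, gene, hgvs, cls, cds_coord=parse_cdna(hgvs))


@pytest.fixture
def small_cohort():
    """Three subjects, two deleterious variants, one VUS."""
    subjects = [
        make_subject("s1", Status.BREAST, FamilyHistory.POSITIVE, 45, "Guangdong"),
        make_subject("s2", Status.OVARY, FamilyHistory.NEGATIVE, 52, "Jiangsu"),
        make_subject("s3", Status.CANCER_FREE, FamilyHistory.NEGATIVE, 30, "Guangdong"),
    ]
    variants = [
        make_variant("s1", "c.5470_5477delATTGGGCA"),
        make_variant("s2", "c.100A>T", cls=Classification.LIKELY_PATHOGENIC),
        make_variant("s3", "c.200G>C", cls=Classification.VUS),
    ]
    return subjects, variants


def expand_clinical_counts(counts):
    """Expand per-status (carriers, non_carriers) counts into subject/variant lists.

    Carriers all receive the same deleterious BRCA1 variant; useful for
    reconstructing a cohort whose summary must reproduce published totals.
    """
    subjects, variants = [], []
    i = 0
    for status, (n_carr, n_nc) in counts.items():
        for k in range(n_carr + n_nc):
            i += 1
            sid = f"x{i:05d}"
            subjects.append(make_subject(sid, status))
            if k < n_carr:
                variants.append(make_variant(sid, "c.5470_5477delATTGGGCA"))
    return subjects, variants
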