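"""Synthetic case-control cohorts, variant tables and STR founder panels.

Everything downstream — binning, the ROR scan, penetrance, the STR sharing
summary — is exercised on data from this module, so the generators are
first-class, seed-deterministic code emitting exactly the delimited schemas
the readers consume.

Cohort model
------------
Subjects fall into three arms (breast cancer, ovarian cancer, cancer-free)
with sizes defaulting to the study scale (2,400 / 1,697 / 3,641 subjects;
15% of cases and 2.5% of controls are deleterious carriers).  Both case
arms share one baseline carrier fraction: a bin's ROR then equals 1 unless
a region tilt says otherwise, which is what makes the designed r an
absolute, recoverable ROR.  Carrier positions follow a base density (uniform
plus founder-hotspot point masses).  A region map assigns intervals a
breast:ovarian odds tilt r; within each arm a subject's carrier state is
drawn so that the *odds* of being a carrier at position p versus a
non-carrier are proportional to f(p) (ovarian, control arms) or f(p)·r(p)
(breast arm).  Because the ROR statistic is exactly a ratio of such odds,
the population ROR of any interval inside a region equals its designed r,
with no normalization error — phenotype assignment is multinomial
conditional on position, not a liability model.

STR model
---------
Founder chromosomes descend from a single ancestral haplotype through a
star genealogy: over g generations, marker j's ancestral allele survives
with probability (1 - c_j)^g (c_j = recombination fraction to the focal
locus) and is otherwise replaced by a population-frequency draw.  Expected
sharing at marker j is therefore (1-c_j)^g + (1-(1-c_j)^g)·p_j, which the
tests check in closed form.  Control chromosomes are population draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    Classification,
    FamilyHistory,
    Gene,
    Status,
    Subject,
    VariantCall,
    write_cohort,
)
from .errors import ConfigurationError
from .hgvs import parse_cdna
from .str_markers import DEFAULT_PANEL, StrGenotype

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_str_panel",
    "simulate_penetrance_study",
    "StrPanelSim",
    "write_str_tables",
]

#: canonical names for known founder-hotspot positions
_HOTSPOT_NAMES = {
    5470: "c.5470_5477delATTGGGCA",
    981: "c.981_982delAT",
    3770: "c.3770_3771delAG",
    5521: "c.5521delA",
    4801: "c.4801A>T",
    5722: "c.5722_5723delCT",
    3109: "c.3109C>T",
}

_PROVINCE_WEIGHTS = {
    "Guangdong": 0.14,
    "Jiangsu": 0.12,
    "Shandong": 0.11,
    "Henan": 0.10,
    "Sichuan": 0.10,
    "Zhejiang": 0.09,
    "Hunan": 0.08,
    "Hubei": 0.08,
    "Beijing": 0.07,
    "Shanghai": 0.06,
    "Yunnan": 0.035,
    "Gansu": 0.02,
    "Qinghai": 0.008,
    "Ningxia": 0.004,
    "Tibet": 0.003,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort and STR panel generators."""

    seed: int
    n_breast: int = 2400
    n_ovarian: int = 1697
    n_controls: int = 3641
    gene: str = "BRCA1"
    cds_length: int = 5592
    #: marginal deleterious-carrier fraction of the case arms when r = 1
    #: (pooled study scale: 617 carriers / 4,097 breast+ovarian cases);
    #: both case arms share this baseline so that a bin's ROR is 1 unless a
    #: region tilt says otherwise — r would not be identifiable as an
    #: absolute ROR if the arms had different baseline carrier odds
    carrier_freq_cases: float = 0.15
    carrier_freq_controls: float = 0.025
    #: list of (start, end, r): breast:ovarian odds tilt on [start, end]
    region_map: tuple[tuple[int, int, float], ...] = ()
    #: list of (position, mass): point masses of the carrier-position density
    founder_hotspots: tuple[tuple[int, float], ...] = ((5470, 0.095), (981, 0.04))
    lifetime_risk: float = 0.053
    fh_positive_rate_cases: float = 0.18
    fh_positive_rate_controls: float = 0.28
    # STR panel
    str_markers: tuple[str, ...] = DEFAULT_PANEL
    n_str_alleles: int = 6
    #: per-marker recombination fraction to the focal locus (per meiosis)
    recomb_fractions: tuple[float, ...] = (
        0.030,
        0.018,
        0.008,
        0.004,
        0.002,
        0.006,
        0.012,
        0.020,
        0.035,
    )
    founder_generations: int = 100
    n_str_carriers: int = 31
    n_str_controls: int = 50

    def __post_init__(self):
        spans = sorted((a, b) for a, b, _ in self.region_map)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ConfigurationError("region intervals must not overlap")
        for _, _, r in self.region_map:
            if r <= 0:
                raise ConfigurationError("region odds tilt r must be > 0")
        for q in (self.carrier_freq_cases, self.carrier_freq_controls):
            if not 0 < q < 1:
                raise ConfigurationError("carrier fractions must lie in (0, 1)")
        if sum(m for _, m in self.founder_hotspots) >= 1:
            raise ConfigurationError("hotspot masses must sum to < 1")
        if len(self.recomb_fractions) != len(self.str_markers):
            raise ConfigurationError("one recombination fraction per STR marker required")


def _position_density(config: SimConfig) -> np.ndarray:
    f = np.full(config.cds_length, 1.0 / config.cds_length)
    hot_mass = sum(m for _, m in config.founder_hotspots)
    f *= 1.0 - hot_mass
    for pos, mass in config.founder_hotspots:
        if not 1 <= pos <= config.cds_length:
            raise ConfigurationError(f"hotspot position {pos} outside CDS")
        f[pos - 1] += mass
    return f


def _region_tilt(config: SimConfig) -> np.ndarray:
    w = np.ones(config.cds_length)
    for start, end, r in config.region_map:
        w[start - 1 : end] = r
    return w


def _hgvs_for_position(pos: int, rng: np.random.Generator) -> str:
    if pos in _HOTSPOT_NAMES:
        return _HOTSPOT_NAMES[pos]
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    return f"c.{pos}{ref}>{alt}"


def simulate_cohort(config: SimConfig) -> tuple[list[Subject], list[VariantCall]]:
    """Draw a cohort (subjects + deleterious variant calls) under the config.

    Deterministic given ``config.seed``: the same config yields byte-identical
    written tables.
    """
    rng = np.random.default_rng(config.seed)
    f = _position_density(config)
    tilt = _region_tilt(config)
    grid = np.arange(1, config.cds_length + 1)
    provinces = list(_PROVINCE_WEIGHTS)
    pw = np.array(list(_PROVINCE_WEIGHTS.values()))
    pw = pw / pw.sum()

    arms = [
        (Status.BREAST, config.n_breast, config.carrier_freq_cases, tilt, 45.0, 8.0,
         config.fh_positive_rate_cases),
        (Status.OVARY, config.n_ovarian, config.carrier_freq_cases, np.ones_like(tilt), 52.0,
         8.0, config.fh_positive_rate_cases),
        (Status.CANCER_FREE, config.n_controls, config.carrier_freq_controls,
         np.ones_like(tilt), 36.0, 7.0, config.fh_positive_rate_controls),
    ]

    subjects: list[Subject] = []
    variants: list[VariantCall] = []
    sid = 0
    for status, n, q, w, age_mu, age_sd, fh_rate in arms:
        lam = q / (1.0 - q)
        mass = lam * f * w  # odds of carrier-at-position vs non-carrier
        total_mass = mass.sum()
        p_carrier = total_mass / (1.0 + total_mass)
        pos_p = mass / total_mass
        is_carrier = rng.random(n) < p_carrier
        positions = rng.choice(grid, size=int(is_carrier.sum()), p=pos_p)
        ages = np.clip(np.round(rng.normal(age_mu, age_sd, size=n)), 18, 95)
        fh_pos = rng.random(n) < fh_rate
        carrier_iter = iter(positions)
        for i in range(n):
            sid += 1
            subject_id = f"S{sid:05d}"
            subjects.append(
                Subject(
                    subject_id=subject_id,
                    status=status,
                    age=float(ages[i]),
                    family_history=FamilyHistory.POSITIVE if fh_pos[i] else FamilyHistory.NEGATIVE,
                    province=str(rng.choice(provinces, p=pw)),
                )
            )
            if is_carrier[i]:
                pos = int(next(carrier_iter))
                hgvs = _hgvs_for_position(pos, rng)
                variants.append(
                    VariantCall(
                        subject_id=subject_id,
                        gene=Gene(config.gene),
                        hgvs_c=hgvs,
                        classification=Classification.PATHOGENIC,
                        cds_coord=parse_cdna(hgvs),
                    )
                )
    return subjects, variants


@dataclass
class StrPanelSim:
    genotypes: list[StrGenotype]
    phased: pd.DataFrame  # subject_id, chrom_index, marker, allele
    carrier_ids: set[str]
    ancestral: dict[str, str]
    population_frequencies: dict[str, np.ndarray]
    allele_labels: list[str] = field(default_factory=list)


def _population_frequencies(n_alleles: int) -> np.ndarray:
    w = 0.8 ** np.arange(n_alleles)
    return w / w.sum()


def simulate_str_panel(config: SimConfig) -> StrPanelSim:
    """Generate genotype and phased haplotype tables under the star-genealogy model."""
    rng = np.random.default_rng(config.seed + 1)  # independent stream from the cohort
    labels = [str(10 + 2 * k) for k in range(config.n_str_alleles)]  # repeat lengths
    freqs = _population_frequencies(config.n_str_alleles)
    pop = {m: freqs for m in config.str_markers}
    ancestral = {
        m: labels[int(rng.choice(config.n_str_alleles, p=freqs))] for m in config.str_markers
    }
    survival = {
        m: (1.0 - c) ** config.founder_generations
        for m, c in zip(config.str_markers, config.recomb_fractions)
    }

    def population_draw() -> dict[str, str]:
        return {
            m: labels[int(rng.choice(config.n_str_alleles, p=pop[m]))]
            for m in config.str_markers
        }

    def founder_chromosome() -> dict[str, str]:
        out = {}
        for m in config.str_markers:
            if rng.random() < survival[m]:
                out[m] = ancestral[m]
            else:
                out[m] = labels[int(rng.choice(config.n_str_alleles, p=pop[m]))]
        return out

    rows = []
    genotypes: list[StrGenotype] = []
    carrier_ids: set[str] = set()

    def add_subject(subject_id: str, chrom1: dict, chrom2: dict) -> None:
        for idx, chrom in ((1, chrom1), (2, chrom2)):
            for m in config.str_markers:
                rows.append(
                    {"subject_id": subject_id, "chrom_index": idx, "marker": m, "allele": chrom[m]}
                )
        for m in config.str_markers:
            pair = tuple(sorted((chrom1[m], chrom2[m])))
            genotypes.append(StrGenotype(subject_id=subject_id, marker=m, alleles=pair))

    for i in range(config.n_str_carriers):
        subject_id = f"H{i + 1:04d}"
        carrier_ids.add(subject_id)
        add_subject(subject_id, founder_chromosome(), population_draw())
    for i in range(config.n_str_controls):
        add_subject(f"C{i + 1:04d}", population_draw(), population_draw())

    return StrPanelSim(
        genotypes=genotypes,
        phased=pd.DataFrame(rows),
        carrier_ids=carrier_ids,
        ancestral=ancestral,
        population_frequencies=pop,
        allele_labels=labels,
    )


def simulate_penetrance_study(
    rng: np.random.Generator,
    carrier_freq: float,
    penetrance: float,
    background_risk: float,
    n_case: int,
    n_ctrl: int,
) -> tuple[float, float, float]:
    """One replicate of a penetrance parameter-recovery experiment.

    Generative model: a fraction ``carrier_freq`` of the population carries
    the mutation; carriers develop disease with probability ``penetrance``,
    non-carriers with ``background_risk``.  Cases and cancer-free controls
    are then ascertained.  Returns the observed carrier frequencies
    (f_case_hat, f_ctrl_hat) and the implied population lifetime risk K.
    """
    q, pi, k0 = carrier_freq, penetrance, background_risk
    k = q * pi + (1 - q) * k0
    p_case = q * pi / k
    p_ctrl = q * (1 - pi) / (1 - k)
    f_case_hat = rng.binomial(n_case, p_case) / n_case
    f_ctrl_hat = rng.binomial(n_ctrl, p_ctrl) / n_ctrl
    return f_case_hat, f_ctrl_hat, k


def write_str_tables(sim: StrPanelSim, genotypes_path: str | Path, phased_path: str | Path) -> None:
    """Write genotype and phased tables in the schemas the STR readers consume."""
    grows = [
        {
            "subject_id": g.subject_id,
            "marker": g.marker,
            "allele1": g.alleles[0],
            "allele2": g.alleles[1],
        }
        for g in sim.genotypes
    ]
    pd.DataFrame(grows).to_csv(genotypes_path, sep="\t", index=False)
    sim.phased.to_csv(phased_path, sep="\t", index=False)


def write_cohort_tables(
    config: SimConfig, subjects_path: str | Path, variants_path: str | Path
) -> None:
    subjects, variants = simulate_cohort(config)
    write_cohort(subjects, variants, subjects_path, variants_path)
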