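import numpy as np
import pytest

from brcascan.cohort import Gene, Status, read_cohort, summarize_carriers
from brcascan.errors import ConfigurationError
from brcascan.ror import interval_counts, ror_stats
from brcascan.simulate import (
    SimConfig,
    simulate_cohort,
    simulate_str_panel,
    write_cohort_tables,
    write_str_tables,
)
from brcascan.str_markers import core_haplotype_sharing

SMALL = dict(n_breast=300, n_ovarian=250, n_controls=400)


class TestCohortGenerator:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        cfg = SimConfig(seed=42, **SMALL)
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            write_cohort_tables(cfg, tmp_path / d / "s.tsv", tmp_path / d / "v.tsv")
        assert (tmp_path / "a/s.tsv").read_bytes() == (tmp_path / "b/s.tsv").read_bytes()
        assert (tmp_path / "a/v.tsv").read_bytes() == (tmp_path / "b/v.tsv").read_bytes()

    def test_different_seed_differs(self, tmp_path):
        for seed, d in ((1, "a"), (2, "b")):
            (tmp_path / d).mkdir()
            write_cohort_tables(SimConfig(seed=seed, **SMALL), tmp_path / d / "s.tsv", tmp_path / d / "v.tsv")
        assert (tmp_path / "a/v.tsv").read_bytes() != (tmp_path / "b/v.tsv").read_bytes()

    def test_written_tables_satisfy_reader_schema(self, tmp_path):
        cfg = SimConfig(seed=3, **SMALL)
        write_cohort_tables(cfg, tmp_path / "s.tsv", tmp_path / "v.tsv")
        subjects, variants = read_cohort(tmp_path / "s.tsv", tmp_path / "v.tsv")
        assert len(subjects) == 950
        assert all(v.cds_coord is not None for v in variants)
        summary = summarize_carriers(subjects, variants)
        assert 0 < summary.total_carriers < len(subjects)

    def test_arm_sizes_and_statuses(self):
        subjects, _ = simulate_cohort(SimConfig(seed=4, **SMALL))
        by_status = {}
        for s in subjects:
            by_status[s.status] = by_status.get(s.status, 0) + 1
        assert by_status[Status.BREAST] == 300
        assert by_status[Status.OVARY] == 250
        assert by_status[Status.CANCER_FREE] == 400

    def test_hotspot_mass_concentrates_carriers(self):
        cfg = SimConfig(seed=5, founder_hotspots=((5470, 0.4),))
        _, variants = simulate_cohort(cfg)
        at_hotspot = sum(1 for v in variants if v.cds_coord.base == 5470)
        assert at_hotspot / len(variants) == pytest.approx(0.4, abs=0.06)
        assert any(v.hgvs_c == "c.5470_5477delATTGGGCA" for v in variants)

    def test_designed_region_ror_recovered_roughly(self):
        # single large cohort; the designed interval's ROR should land near 3
        cfg = SimConfig(seed=6, region_map=((1000, 2700, 3.0),))
        subjects, variants = simulate_cohort(cfg)
        s = ror_stats(interval_counts(subjects, variants, Gene.BRCA1, 1000, 2700))
        assert s.ci95[0] < 3.0 < s.ci95[1]

    @pytest.mark.parametrize(
        "bad",
        [
            dict(region_map=((10, 100, 1.0), (50, 200, 2.0))),  # overlap
            dict(region_map=((10, 100, -1.0),)),
            dict(carrier_freq_cases=0.0),
            dict(founder_hotspots=((100, 0.7), (200, 0.5))),  # masses >= 1
            dict(recomb_fractions=(0.1, 0.2)),  # wrong length
        ],
    )
    def test_infeasible_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, **bad)


class TestStrGenerator:
    def test_zero_generations_copies_ancestral_haplotype(self):
        cfg = SimConfig(seed=7, founder_generations=0, n_str_carriers=10, n_str_controls=10)
        sim = simulate_str_panel(cfg)
        founder_chroms = sim.phased[
            sim.phased.subject_id.isin(sim.carrier_ids) & (sim.phased.chrom_index == 1)
        ]
        for marker, group in founder_chroms.groupby("marker"):
            assert set(group.allele) == {sim.ancestral[marker]}

    def test_high_recombination_reaches_population_equilibrium(self):
        # c = 0.5 for many generations: carrier chromosomes look like controls
        cfg = SimConfig(
            seed=8,
            recomb_fractions=(0.5,) * 9,
            founder_generations=200,
            n_str_carriers=150,
            n_str_controls=150,
        )
        sim = simulate_str_panel(cfg)
        summary = core_haplotype_sharing(sim.phased, sim.carrier_ids, k_consecutive=9)
        assert not summary.founder_flag or all(
            abs(s.carrier_frequency - s.control_frequency) < 0.12 for s in summary.markers
        )

    def test_sharing_decays_with_recombination_distance(self):
        # average ancestral-allele retention over replicates follows
        # (1-c)^g + (1-(1-c)^g) * p_anc, so widely spaced c values order the sharing
        reps = 40
        cfg0 = SimConfig(seed=0)
        markers = cfg0.str_markers
        obs = {m: [] for m in markers}
        for seed in range(reps):
            cfg = SimConfig(seed=seed, n_str_carriers=40)
            sim = simulate_str_panel(cfg)
            founder = sim.phased[
                sim.phased.subject_id.isin(sim.carrier_ids) & (sim.phased.chrom_index == 1)
            ]
            for m in markers:
                alleles = founder[founder.marker == m].allele
                obs[m].append((alleles == sim.ancestral[m]).mean())
        mean_sharing = {m: np.mean(obs[m]) for m in markers}
        # the focal-adjacent marker (smallest c) retains most, the ends least
        focal = markers[np.argmin(cfg0.recomb_fractions)]
        assert mean_sharing[focal] == max(mean_sharing.values())
        assert mean_sharing[markers[0]] < mean_sharing[focal]
        assert mean_sharing[markers[-1]] < mean_sharing[focal]

    def test_genotype_and_phased_tables_consistent(self, tmp_path):
        cfg = SimConfig(seed=9, n_str_carriers=5, n_str_controls=5)
        sim = simulate_str_panel(cfg)
        write_str_tables(sim, tmp_path / "g.tsv", tmp_path / "p.tsv")
        import pandas as pd

        g = pd.read_csv(tmp_path / "g.tsv", sep="\t", dtype=str)
        p = pd.read_csv(tmp_path / "p.tsv", sep="\t", dtype=str)
        assert len(g) == 10 * 9  # one row per subject per marker
        assert len(p) == 10 * 2 * 9  # one row per chromosome per marker
        # genotype pair equals the sorted pair of phased alleles
        for (sid, m), grp in p.groupby(["subject_id", "marker"]):
            pair = tuple(sorted(grp.allele))
            row = g[(g.subject_id == sid) & (g.marker == m)].iloc[0]
            assert (row.allele1, row.allele2) == pair
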