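import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brcascan.cohort import FamilyHistory, Gene, Status
from brcascan.errors import UndefinedPenetranceError
from brcascan.penetrance import (
    DEFAULT_LIFETIME_RISK,
    PenetranceInput,
    Stratum,
    bayes_penetrance,
    carrier_frequencies,
    stratified_penetrance,
)

from conftest import make_subject, make_variant

freqs = st.floats(1e-6, 1.0)


class TestBayesFormula:
    def test_absent_from_controls_means_complete_penetrance(self):
        est = bayes_penetrance(PenetranceInput(f_case=0.004, f_ctrl=0.0))
        assert est.penetrance == 1.0
        assert est.above_reference

    def test_no_enrichment_returns_baseline_risk(self):
        est = bayes_penetrance(PenetranceInput(f_case=0.02, f_ctrl=0.02))
        assert est.penetrance == pytest.approx(DEFAULT_LIFETIME_RISK)
        assert not est.above_reference

    def test_worked_example(self):
        est = bayes_penetrance(PenetranceInput(f_case=0.02, f_ctrl=0.001, k=0.053))
        assert est.penetrance == pytest.approx(0.528, abs=5e-4)

    def test_absent_everywhere_is_undefined(self):
        with pytest.raises(UndefinedPenetranceError):
            bayes_penetrance(PenetranceInput(f_case=0.0, f_ctrl=0.0))

    @given(f_case=freqs, f_ctrl=freqs, k=st.floats(0.001, 0.999))
    @settings(deadline=None)
    def test_estimate_always_in_unit_interval(self, f_case, f_ctrl, k):
        p = bayes_penetrance(PenetranceInput(f_case, f_ctrl, k=k)).penetrance
        assert 0.0 <= p <= 1.0

    @given(f_ctrl=freqs, k=st.floats(0.01, 0.5))
    @settings(deadline=None)
    def test_strictly_increasing_in_case_frequency(self, f_ctrl, k):
        lo = bayes_penetrance(PenetranceInput(0.01, f_ctrl, k=k)).penetrance
        hi = bayes_penetrance(PenetranceInput(0.02, f_ctrl, k=k)).penetrance
        assert hi > lo

    @given(f_case=freqs, k=st.floats(0.01, 0.5))
    @settings(deadline=None)
    def test_strictly_decreasing_in_control_frequency(self, f_case, k):
        lo = bayes_penetrance(PenetranceInput(f_case, 0.02, k=k)).penetrance
        hi = bayes_penetrance(PenetranceInput(f_case, 0.01, k=k)).penetrance
        assert hi > lo


def _cohort(case_carriers, case_total, ctrl_carriers, ctrl_total, fh=FamilyHistory.NEGATIVE):
    subjects, variants = [], []
    for i in range(case_total):
        sid = f"case{i}"
        subjects.append(make_subject(sid, Status.BREAST, fh))
        if i < case_carriers:
            variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
    for i in range(ctrl_total):
        sid = f"ctrl{i}"
        subjects.append(make_subject(sid, Status.CANCER_FREE, fh))
        if i < ctrl_carriers:
            variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
    return subjects, variants


class TestCohortFrequencies:
    def test_frequencies_counted_from_cohort(self):
        subjects, variants = _cohort(4, 200, 2, 1000)
        inp = carrier_frequencies(subjects, variants, "BRCA2", "c.3109C>T")
        assert inp.f_case == pytest.approx(4 / 200)
        assert inp.f_ctrl == pytest.approx(2 / 1000)

    def test_fh_negative_controls_are_the_default_baseline(self):
        subjects, variants = _cohort(4, 200, 0, 500, fh=FamilyHistory.NEGATIVE)
        # add FH-positive control carriers that must NOT enter the default baseline
        for i in range(5):
            sid = f"fhpos{i}"
            subjects.append(make_subject(sid, Status.CANCER_FREE, FamilyHistory.POSITIVE))
            variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
        inp = carrier_frequencies(subjects, variants, "BRCA2", "c.3109C>T")
        assert inp.f_ctrl == 0.0
        inp_all = carrier_frequencies(
            subjects, variants, "BRCA2", "c.3109C>T", controls="all-cancer-free"
        )
        assert inp_all.f_ctrl == pytest.approx(5 / 505)

    def test_allele_mode_gives_identical_penetrance_for_heterozygotes(self):
        subjects, variants = _cohort(4, 200, 2, 1000)
        per_subject = carrier_frequencies(subjects, variants, "BRCA2", "c.3109C>T")
        per_allele = carrier_frequencies(
            subjects, variants, "BRCA2", "c.3109C>T", allele_mode=True
        )
        assert per_allele.f_case == pytest.approx(per_subject.f_case / 2)
        assert bayes_penetrance(per_allele).penetrance == pytest.approx(
            bayes_penetrance(per_subject).penetrance
        )


class TestStratification:
    def test_fh_positive_only_penetrance_splits_strata(self):
        # built so FH-positive controls carry nothing but FH-negative controls do
        subjects, variants = [], []
        for i in range(100):
            fh = FamilyHistory.POSITIVE if i < 50 else FamilyHistory.NEGATIVE
            sid = f"case{i}"
            subjects.append(make_subject(sid, Status.BREAST, fh))
            if i % 10 == 0:
                variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
        for i in range(1000):
            fh = FamilyHistory.POSITIVE if i < 500 else FamilyHistory.NEGATIVE
            sid = f"ctrl{i}"
            subjects.append(make_subject(sid, Status.CANCER_FREE, fh))
            if fh is FamilyHistory.NEGATIVE and i % 100 == 0:
                variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
        ests = {
            e.stratum: e
            for e in stratified_penetrance(subjects, variants, "BRCA2", "c.3109C>T")
        }
        assert ests[Stratum.FH_POSITIVE].penetrance == 1.0
        assert ests[Stratum.FH_NEGATIVE].penetrance < 1.0
        assert Stratum.ALL in ests

    def test_identical_strata_give_identical_estimates(self):
        subjects, variants = [], []
        for fh in (FamilyHistory.POSITIVE, FamilyHistory.NEGATIVE):
            tag = fh.value
            for i in range(100):
                sid = f"case{tag}{i}"
                subjects.append(make_subject(sid, Status.BREAST, fh))
                if i < 10:
                    variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
            for i in range(500):
                sid = f"ctrl{tag}{i}"
                subjects.append(make_subject(sid, Status.CANCER_FREE, fh))
                if i < 5:
                    variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
        ests = {
            e.stratum: e.penetrance
            for e in stratified_penetrance(
                subjects, variants, "BRCA2", "c.3109C>T", controls="all-cancer-free"
            )
        }
        assert ests[Stratum.FH_POSITIVE] == pytest.approx(ests[Stratum.FH_NEGATIVE])
        assert ests[Stratum.ALL] == pytest.approx(ests[Stratum.FH_POSITIVE])

    def test_pooled_estimate_between_stratum_estimates(self):
        import numpy as np

        rng = np.random.default_rng(11)
        for _ in range(20):
            n_case, n_ctrl = 400, 2000
            subjects, variants = [], []
            for fh, case_rate, ctrl_rate in (
                (FamilyHistory.POSITIVE, rng.uniform(0.02, 0.2), rng.uniform(0.001, 0.02)),
                (FamilyHistory.NEGATIVE, rng.uniform(0.02, 0.2), rng.uniform(0.001, 0.02)),
            ):
                tag = fh.value
                for i in range(n_case):
                    sid = f"case{tag}{i}"
                    subjects.append(make_subject(sid, Status.BREAST, fh))
                    if rng.random() < case_rate:
                        variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
                for i in range(n_ctrl):
                    sid = f"ctrl{tag}{i}"
                    subjects.append(make_subject(sid, Status.CANCER_FREE, fh))
                    if rng.random() < ctrl_rate:
                        variants.append(make_variant(sid, "c.3109C>T", gene=Gene.BRCA2))
            ests = {
                e.stratum: e.penetrance
                for e in stratified_penetrance(
                    subjects, variants, "BRCA2", "c.3109C>T", controls="all-cancer-free"
                )
            }
            if {Stratum.FH_POSITIVE, Stratum.FH_NEGATIVE} <= ests.keys():
                lo = min(ests[Stratum.FH_POSITIVE], ests[Stratum.FH_NEGATIVE])
                hi = max(ests[Stratum.FH_POSITIVE], ests[Stratum.FH_NEGATIVE])
                assert lo - 1e-12 <= ests[Stratum.ALL] <= hi + 1e-12
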