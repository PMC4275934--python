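"""Kaplan-Meier estimation, log-rank testing, and the therapy-duration demo."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from clintime.errors import ClintimeError
from clintime.reasoner import default_axioms
from clintime.survival import (
    compare_groups,
    extract_survival_table,
    km_estimate,
    logrank_test,
)
from clintime.synthetic_corpus import CorpusSpec, simulate_document
from clintime.temporal_model import (
    AnnotatedDocument,
    Duration,
    Event,
    Granularity,
    Relation,
    TemporalAssertion,
)

G = Granularity


class TestKMEstimate:
    def test_mass_at_single_time(self):
        km = km_estimate([5, 5, 5])
        assert km.table["survival"].tolist() == [0.0]
        assert km.median == 5

    def test_hand_computed_product_limit(self):
        km = km_estimate([1, 2, 3, 4])
        assert km.table["survival"].tolist() == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert km.survival_at(2) == pytest.approx(0.5)
        assert km.median == 2

    def test_monotone_non_increasing_with_censoring(self):
        km = km_estimate([1, 2, 2, 3, 5, 8], observed=[1, 1, 0, 1, 0, 0])
        survival = km.table["survival"].to_numpy()
        assert np.all(np.diff(survival) <= 0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.integers(1, 20, 30).astype(float)
        km = km_estimate(times)
        for _, row in km.table.iterrows():
            empirical = np.mean(times > row["time"])
            assert row["survival"] == pytest.approx(empirical)

    def test_median_inf_when_curve_stays_high(self):
        km = km_estimate([1, 2, 3, 4], observed=[True, False, False, False])
        assert km.median == float("inf")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        result = logrank_test([1, 2, 3], [1, 2, 3])
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_hand_computed_separated_groups(self):
        """{1,2,3} vs {10,20,30}: all observed-minus-expected from the risk table.

        Event times 1,2,3 have n1=3,2,1 of n=6,5,4 at risk and one group-1
        event each; times 10,20,30 have n1=0.  O-E = (1-3/6)+(1-2/5)+(1-1/4)
        + (0-3/3)... the second block contributes 0-0 expectations of group 1
        membership only after group 1 is exhausted; the variance sum follows
        d*(n1/n)*(n2/n)*(n-d)/(n-1) with d=1 everywhere.
        """
        o_minus_e = (1 - 3 / 6) + (1 - 2 / 5) + (1 - 1 / 4)
        variance = (3 / 6) * (3 / 6) + (2 / 5) * (3 / 5) + (1 / 4) * (3 / 4)
        expected = o_minus_e**2 / variance
        result = logrank_test([1, 2, 3], [10, 20, 30])
        assert result.statistic == pytest.approx(expected)

    def test_symmetric_under_relabelling(self):
        a, b = [1.0, 4.0, 6.0, 9.0], [2.0, 3.0, 8.0]
        r1 = logrank_test(a, b)
        r2 = logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert 0 < r1.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [1, 2])


class TestAgainstEstablishedImplementation:
    @pytest.mark.parametrize("seed", range(10))
    def test_km_and_logrank_match_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(4, 30, 2)
        t1 = np.round(rng.lognormal(2.0, 0.7, n1), 1) + 0.1
        t2 = np.round(rng.lognormal(2.4, 0.7, n2), 1) + 0.1
        km = km_estimate(t1)
        fitter = KaplanMeierFitter().fit(t1)
        for _, row in km.table.iterrows():
            assert row["survival"] == pytest.approx(
                float(fitter.predict(row["time"])), abs=1e-9
            )
        ours = logrank_test(t1, t2)
        theirs = lifelines_logrank(t1, t2)
        assert ours.statistic == pytest.approx(theirs.test_statistic, abs=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, abs=1e-9)


class TestExtractSurvivalTable:
    def _doc(self, doc_id, therapy_months, lst_months):
        return AnnotatedDocument(
            doc_id=doc_id,
            events=[
                Event("implant", "stent_implantation"),
                Event("therapy", "antiplatelet_therapy"),
                Event("lst", "late_stent_thrombosis"),
            ],
            assertions=[
                TemporalAssertion(
                    "implant",
                    Relation.BEFORE,
                    "lst",
                    offset=Duration(lst_months, G.MONTH),
                )
            ],
            event_durations={"therapy": Duration(therapy_months, G.MONTH)},
        )

    def test_threshold_rule(self):
        docs = [self._doc("short", 2, 14), self._doc("exact", 6, 20), self._doc("long", 9, 30)]
        records = extract_survival_table(docs, axioms=default_axioms())
        groups = {r.doc_id: r.group for r in records}
        assert groups == {"short": "shorter", "exact": "longer", "long": "longer"}
        assert {r.doc_id: r.time_to_lst_months for r in records} == {
            "short": 14.0,
            "exact": 20.0,
            "long": 30.0,
        }

    def test_unresolvable_documents_excluded(self):
        doc = AnnotatedDocument(
            doc_id="noinfo",
            events=[
                Event("implant", "stent_implantation"),
                Event("therapy", "antiplatelet_therapy"),
                Event("lst", "late_stent_thrombosis"),
            ],
        )
        assert extract_survival_table([doc], axioms=default_axioms()) == []

    def test_group_effect_increases_rejection_rate(self):
        """With a longer-therapy group shifted later, log-rank rejects more often."""

        def rejections(effect, n_corpora=8, n_docs=40):
            count = 0
            for c in range(n_corpora):
                spec = CorpusSpec(
                    n_docs=n_docs,
                    seed=1000 + c,
                    lst_group_effect=effect,
                    p_missing_duration=0.0,
                    p_range_duration=0.0,
                    expression_style_mix={
                        "absolute_day": 0.6,
                        "offset_days": 0.2,
                        "explicit_duration": 0.2,
                        "absolute_month": 0.0,
                        "offset_months": 0.0,
                    },
                )
                docs = [
                    simulate_document(spec, np.random.default_rng([spec.seed, i]), f"d{i}")[0]
                    for i in range(n_docs)
                ]
                records = extract_survival_table(docs, axioms=default_axioms())
                try:
                    summary = compare_groups(records)
                except ClintimeError:
                    continue
                if summary["logrank_p_value"] < 0.05:
                    count += 1
            return count

        assert rejections(effect=2.5) > rejections(effect=1.0)

    def test_compare_groups_requires_both_groups(self):
        with pytest.raises(ClintimeError):
            compare_groups([])
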