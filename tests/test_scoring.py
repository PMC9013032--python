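import numpy as np
import pytest

from jscore.features import binarize_outcome
from jscore.model import SeverityModel
from jscore.scoring import (
    bimodality_coefficient,
    group_comparison,
    high_severity_proportion,
    read_records,
    score_distribution,
    score_encounters,
    trend_report,
    write_records,
)

from conftest import make_encounter


@pytest.fixture(scope="module")
def fitted(small_cohort):
    maps, encounters, _ = small_cohort
    res_adm = SeverityModel.from_encounters(
        encounters, maps, variant="body_system", phase="admission"
    ).fit()
    res_dis = SeverityModel.from_encounters(
        encounters, maps, variant="body_system", phase="discharge"
    ).fit()
    return maps, encounters, res_adm, res_dis


@pytest.fixture(scope="module")
def records(fitted):
    maps, encounters, res_adm, res_dis = fitted
    return score_encounters(res_adm, res_dis, maps, encounters, cutoff_poa=0.4, cutoff=0.4)


class TestScoreEncounters:
    def test_all_poa_codes_give_equal_scores_under_one_model(self, fitted):
        maps, _, _, res_dis = fitted
        codes = [c for c in sorted(maps.body_system)[:4]]
        e = make_encounter([(c, "Y") for c in codes])
        # same fitted model for both phases: identical features -> identical scores
        rec = score_encounters(res_dis, res_dis, maps, [e])[0]
        assert rec.j_score_poa == rec.j_score

    def test_zero_diagnosis_encounter_scores_at_intercept_only(self, fitted):
        maps, _, res_adm, res_dis = fitted
        from scipy.special import expit
        from jscore.contrasts import ContrastDesign
        from jscore.features import SeverityFeatures

        e = make_encounter([])
        rec = score_encounters(res_adm, res_dis, maps, [e])[0]
        zero = SeverityFeatures("discharge", np.zeros(18, int), np.zeros(30, int))
        assert rec.j_score == pytest.approx(res_dis.predict(zero), abs=1e-12)
        assert rec.j_score_poa == pytest.approx(res_adm.predict(zero), abs=1e-12)

    def test_deterministic(self, fitted):
        maps, encounters, res_adm, res_dis = fitted
        r1 = score_encounters(res_adm, res_dis, maps, encounters[:50])
        r2 = score_encounters(res_adm, res_dis, maps, encounters[:50])
        assert r1 == r2

    def test_variant_mismatch_fatal(self, fitted, small_cohort):
        maps, encounters, res_adm, _ = fitted
        other = SeverityModel.from_encounters(
            encounters[:500], maps, variant="comorbidity", phase="discharge"
        ).fit()
        with pytest.raises(ValueError, match="variant"):
            score_encounters(res_adm, other, maps, encounters[:5])

    def test_predicted_classes_follow_cutoffs(self, records):
        for r in records[:200]:
            assert r.predicted_class == ("high" if r.j_score >= 0.4 else "low")
            assert r.predicted_class_poa == ("high" if r.j_score_poa >= 0.4 else "low")


class TestRecordIO:
    def test_round_trip_and_report_reproducibility(self, records, tmp_path):
        path = write_records(records, tmp_path / "scores.csv")
        back = read_records(path)
        assert back == list(records)
        # analytics computed from the file alone match in-memory analytics
        assert trend_report(back) == trend_report(records)
        assert group_comparison(back, "cds_reviewed") == group_comparison(
            records, "cds_reviewed"
        )
        assert score_distribution(back) == score_distribution(records)


class TestScoreDistribution:
    def test_bin_counts_conserve_n(self, records):
        dist = score_distribution(records)
        assert sum(dist["j_score"]["counts"]) == len(records)
        assert sum(dist["j_score_poa"]["counts"]) == len(records)

    def test_constant_scores_single_bin(self, records):
        from dataclasses import replace

        flat = [
            replace(r, j_score=0.5, j_score_poa=0.5, predicted_class="high",
                    predicted_class_poa="high")
            for r in records[:10]
        ]
        dist = score_distribution(flat)
        assert max(dist["j_score"]["counts"]) == 10
        assert sum(1 for c in dist["j_score"]["counts"] if c) == 1

    def test_saturation_proportion(self, records):
        from dataclasses import replace

        mixed = [replace(records[i], j_score=0.999) for i in range(5)] + [
            replace(records[i], j_score=0.2) for i in range(5, 20)
        ]
        dist = score_distribution(mixed)
        assert dist["j_score"]["proportion_at_one"] == pytest.approx(0.25)

    def test_separated_cohort_more_bimodal_than_label_shuffled(self, small_cohort):
        """Scores from the true-signal fit are bimodal; scores from a fit on
        shuffled labels collapse to the base rate and are not."""
        maps, encounters, _ = small_cohort
        model = SeverityModel.from_encounters(
            encounters, maps, variant="body_system", phase="discharge"
        )
        res_true = model.fit()
        rng = np.random.default_rng(31)
        shuffled = SeverityModel(
            rng.permutation(model.endog), variant="body_system", exog=model.exog
        )
        res_null = shuffled.fit(ridge=1e-3)
        b_true = bimodality_coefficient(res_true.predict(model.exog))
        b_null = bimodality_coefficient(res_null.predict(model.exog))
        assert b_true > b_null


class TestTrendReport:
    def test_single_period_equals_global_means(self, records):
        from dataclasses import replace

        one_month = [replace(r, discharge_month="2019-01") for r in records[:100]]
        rep = trend_report(one_month)
        assert list(rep) == ["2019-01"]
        assert rep["2019-01"]["mean_j_score"] == pytest.approx(
            float(np.mean([r.j_score for r in one_month]))
        )

    def test_gap_zero_when_scores_equal(self, fitted):
        maps, _, _, res_dis = fitted
        codes = sorted(maps.body_system)[:3]
        encounters = [
            make_encounter([(c, "Y") for c in codes], encounter_id=f"A{i}")
            for i in range(6)
        ]
        recs = score_encounters(res_dis, res_dis, maps, encounters)
        rep = trend_report(recs)
        for row in rep.values():
            assert row["gap"] == 0.0

    def test_matches_hand_grouped_means(self, records):
        sub = records[:20]
        rep = trend_report(sub)
        by_month = {}
        for r in sub:
            by_month.setdefault(r.discharge_month, []).append(r)
        assert set(rep) == set(by_month)
        for month, rs in by_month.items():
            assert rep[month]["n"] == len(rs)
            assert rep[month]["mean_j_score_poa"] == pytest.approx(
                sum(r.j_score_poa for r in rs) / len(rs)
            )


class TestGroupComparison:
    def test_group_means_match_direct_computation(self, records):
        from dataclasses import replace

        sub = [
            replace(r, cds_reviewed=(i % 3 == 0)) for i, r in enumerate(records[:10])
        ]
        rep = group_comparison(sub, "cds_reviewed")
        yes = [r for r in sub if r.cds_reviewed]
        no = [r for r in sub if not r.cds_reviewed]
        assert rep["yes"]["n"] == len(yes) and rep["no"]["n"] == len(no)
        assert rep["yes"]["mean_j_score"] == pytest.approx(
            sum(r.j_score for r in yes) / len(yes)
        )
        assert rep["no"]["gap"] == pytest.approx(
            sum(r.j_score for r in no) / len(no)
            - sum(r.j_score_poa for r in no) / len(no)
        )

    def test_single_group_other_absent(self, records):
        from dataclasses import replace

        sub = [replace(r, cds_queried=True) for r in records[:5]]
        rep = group_comparison(sub, "cds_queried")
        assert set(rep) == {"yes"}

    def test_unknown_field_rejected(self, records):
        with pytest.raises(ValueError):
            group_comparison(records, "facility")


class TestHighSeverityProportion:
    def test_counts_match_direct(self, records):
        rep = high_severity_proportion(records, phase="admission")
        for facility, row in rep.items():
            rs = [r for r in records if (r.facility or "(none)") == facility]
            assert row["n"] == len(rs)
            assert row["predicted_high"] == pytest.approx(
                sum(r.predicted_class_poa == "high" for r in rs) / len(rs)
            )
            assert row["observed_high"] == pytest.approx(
                sum(binarize_outcome(r.admit_soi) for r in rs) / len(rs)
            )
            assert 0.0 <= row["predicted_high"] <= 1.0

    def test_all_low_facility_zero(self, records):
        from dataclasses import replace

        sub = [
            replace(r, facility="FX", predicted_class_poa="low") for r in records[:8]
        ]
        rep = high_severity_proportion(sub, phase="admission")
        assert rep["FX"]["predicted_high"] == 0.0
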