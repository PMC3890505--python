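import dataclasses

import numpy as np
import pytest

from sedi.instrument import DOMAINS
from sedi.cohort import apply_exclusions
from sedi.scoring import score_cohort, scores_frame
from sedi.stats import adjusted_odds_ratio, oneway_anova
from sedi.synthetic import (
    SyntheticConfig,
    fixture_printed_marginals,
    generate_cohort,
    generate_domain_scores,
    implied_vulnerability_or,
)
from sedi.vulnerability import classify_cohort, compute_cutoffs, profiles_frame


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = SyntheticConfig(n_pupils=150, rng_seed=99)
        a = generate_cohort(cfg).to_csv()
        b = generate_cohort(cfg).to_csv()
        assert a == b
        c = generate_cohort(dataclasses.replace(cfg, rng_seed=100)).to_csv()
        assert a != c

    def test_roster_parses_cleanly_without_missingness(self, reg):
        cfg = SyntheticConfig(n_pupils=120, rng_seed=5, item_missing_rate=0.0)
        parsed = generate_cohort(cfg, reg).records(reg)
        assert len(parsed.records) == 120
        assert parsed.issues == []

    def test_fast_path_matches_roster_path(self, reg):
        """The domain-score shortcut and the full CSV round-trip agree."""
        cfg = SyntheticConfig(n_pupils=80, rng_seed=21, item_missing_rate=0.0,
                              optout_rate=0.0, short_enrolment_rate=0.0,
                              special_needs_rate=0.0)
        _, fast = generate_domain_scores(cfg, reg)
        parsed = generate_cohort(cfg, reg).records(reg)
        slow = scores_frame(score_cohort(parsed.records, reg))
        for d in DOMAINS:
            np.testing.assert_allclose(fast[d].to_numpy(),
                                       slow[d].to_numpy(), atol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            SyntheticConfig(rho=1.2).validate()
        with pytest.raises(ValueError, match="quintile_probs"):
            SyntheticConfig(quintile_probs=(0.5, 0.5, 0.5, 0, 0)).validate()

    def test_null_cohort_quintiles_exchangeable(self):
        """With every effect zeroed the quintiles are exchangeable: each
        quintile's vulnerable fraction matches the domain's overall fraction
        (which itself is at most 10%; item-score ties at the cutoff keep the
        strictly-below mass under the nominal decile, most visibly in the
        coarse 8-item CGK scale)."""
        cfg = SyntheticConfig(n_pupils=50_000, rng_seed=31,
                              item_missing_rate=0.0).null()
        meta, scores = generate_domain_scores(cfg)
        cuts = compute_cutoffs(scores)
        for d in DOMAINS:
            vuln = scores[d].to_numpy() < cuts[d]["c10"]
            overall = vuln.mean()
            assert 0.05 <= overall <= 0.10
            for q in (1, 2, 3, 4, 5):
                mask = (meta["quintile"] == q).to_numpy()
                assert vuln[mask].mean() == pytest.approx(overall, abs=0.01)

    def test_monotone_quintile_gradient_recovered(self):
        cfg = SyntheticConfig(n_pupils=20_000, rng_seed=17)
        meta, scores = generate_domain_scores(cfg)
        for d in DOMAINS:
            means = [scores.loc[(meta["quintile"] == q).to_numpy(), d].mean()
                     for q in (1, 2, 3, 4, 5)]
            assert all(a < b for a, b in zip(means, means[1:]))

    def test_gender_or_recovered_within_15pct(self):
        """Vulnerability odds ratio measured at n=20k sits within 15% of the
        model's large-sample value."""
        cfg = SyntheticConfig(n_pupils=20_000, rng_seed=29,
                              item_missing_rate=0.0)
        truth = implied_vulnerability_or(cfg, "gender", n_ref=150_000)
        meta, scores = generate_domain_scores(cfg)
        cuts = compute_cutoffs(scores)
        vuln = np.zeros(len(scores), dtype=bool)
        for d in DOMAINS:
            vuln |= scores[d].to_numpy() < cuts[d]["c10"]
        recorded = meta["gender"].isin(["male", "female"]).to_numpy()
        res = adjusted_odds_ratio(vuln[recorded].astype(int),
                                  meta["gender"].to_numpy()[recorded],
                                  "female")
        assert res[0].odds_ratio == pytest.approx(truth, rel=0.15)

    def test_q1_vs_q5_or_of_3_recovered_within_20pct(self):
        """A configured steeper gradient implying a Q1-vs-Q5 odds ratio of
        ~3 is recovered at n=20k."""
        cfg = SyntheticConfig(n_pupils=20_000, rng_seed=41,
                              item_missing_rate=0.0)
        truth = implied_vulnerability_or(cfg, "q1_vs_q5", n_ref=150_000)
        assert 2.4 <= truth <= 3.6  # defaults imply roughly threefold odds
        meta, scores = generate_domain_scores(cfg)
        cuts = compute_cutoffs(scores)
        vuln = np.zeros(len(scores), dtype=bool)
        for d in DOMAINS:
            vuln |= scores[d].to_numpy() < cuts[d]["c10"]
        mask = meta["quintile"].isin([1, 5]).to_numpy()
        res = adjusted_odds_ratio(vuln[mask].astype(int),
                                  meta["quintile"].to_numpy()[mask].astype(int).astype(str),
                                  "5")
        assert res[0].odds_ratio == pytest.approx(truth, rel=0.20)

    def test_exclusion_scenarios_materialize(self, reg):
        cfg = SyntheticConfig(n_pupils=2000, rng_seed=55,
                              heavy_missingness_rate=0.01)
        parsed = generate_cohort(cfg, reg).records(reg)
        _, log = apply_exclusions(parsed.records, reg)
        counts = log.counts
        assert counts["excluded_optout"] > 0
        assert counts["excluded_short_enrolment"] > 0
        assert counts["excluded_special_needs"] > 0
        assert counts["excluded_missingness"] > 0
        assert log.analysed_n + log.excluded_n == 2000


class TestReferenceRoster:
    """The deterministic fixture engineered to fixed reference marginals."""

    def test_exclusion_accounting(self, reg, reference_roster):
        assert len(reference_roster) == 1180
        analysed, log = apply_exclusions(reference_roster, reg)
        assert log.analysed_n == 1090
        assert log.counts["excluded_optout"] == 18
        assert log.excluded_n == 90

    def test_gender_composition(self, reg, reference_roster):
        analysed, _ = apply_exclusions(reference_roster, reg)
        genders = [r.gender for r in analysed]
        assert genders.count("female") == 524
        assert genders.count("male") == 563
        assert genders.count("unrecorded") == 3

    def test_multi_domain_vulnerability_marginals(self, reg, reference_roster):
        analysed, _ = apply_exclusions(reference_roster, reg)
        scored = score_cohort(analysed, reg)
        cuts = compute_cutoffs(scored)
        pf = profiles_frame(classify_cohort(scored, cuts))
        gender = {r.pupil_id: r.gender for r in analysed}
        pf["gender"] = [gender[p] for p in pf.index]
        assert pf["vulnerable_ge1"].sum() == 298
        assert pf["vulnerable_ge2"].sum() == 168
        by_g = pf.groupby("gender")[["vulnerable_ge1", "vulnerable_ge2"]].sum()
        assert by_g.loc["male"].tolist() == [193, 111]
        assert by_g.loc["female"].tolist() == [104, 56]

    def test_percentages_match_reference_at_printed_precision(
            self, reg, reference_roster):
        analysed, _ = apply_exclusions(reference_roster, reg)
        scored = score_cohort(analysed, reg)
        pf = profiles_frame(classify_cohort(scored, compute_cutoffs(scored)))
        assert round(100 * pf["vulnerable_ge1"].mean(), 1) == 27.3
        assert round(100 * pf["vulnerable_ge2"].mean(), 1) == 15.4

    def test_cgk_ceiling(self, reg, reference_roster):
        analysed, _ = apply_exclusions(reference_roster, reg)
        scored = score_cohort(analysed, reg)
        cuts = compute_cutoffs(scored)
        assert cuts["CGK"]["c50"] == 10.0
        pf = profiles_frame(classify_cohort(scored, cuts))
        assert (pf["CGK"] == "on_track_2").sum() == 0

    def test_quintile_missing_seven(self, reg, reference_roster):
        analysed, _ = apply_exclusions(reference_roster, reg)
        assert sum(1 for r in analysed if r.simd_quintile is None) == 7


class TestNullCalibration:
    def test_anova_type_one_error_near_nominal(self):
        """Under the null (no quintile effect) the quintile ANOVA rejects at
        ~5%: 500 replicate cohorts of 1,000 pupils."""
        reps = 500
        rejections = 0
        base = SyntheticConfig(n_pupils=1000, item_missing_rate=0.0,
                               quintile_missing_rate=0.0).null()
        for r in range(reps):
            cfg = dataclasses.replace(base, rng_seed=10_000 + r)
            meta, scores = generate_domain_scores(cfg)
            res = oneway_anova(scores["PHWB"], meta["quintile"])
            rejections += res.p_value < 0.05
        rate = rejections / reps
        # 3 sigma Monte-Carlo band around 0.05 for 500 draws
        assert 0.05 - 3 * 0.00975 <= rate <= 0.05 + 3 * 0.00975
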