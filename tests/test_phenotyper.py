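from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rxswitch import PhenotypeCriteria, classify_participant, find_candidate_switches, phenotype_cohort
from conftest import DRUG_POOL, random_history, rx_frame
from oracles import classify_oracle

CRIT = PhenotypeCriteria()


class TestFindCandidateSwitches:
    def test_clean_switch_passes_all_criteria(self):
        rx = rx_frame([(0, "fluoxetine", "SSRI"), (30, "amitriptyline", "TCA")])
        (ev,) = find_candidate_switches(rx, CRIT)
        assert ev.gap_days == 30 and ev.valid
        assert all(ev.criteria_pass.values())
        assert ev.post_switch_class == "TCA"

    def test_gap_below_minimum_yields_no_event(self):
        """An overlap within 5 days is augmentation, not a switch."""
        rx = rx_frame([(0, "fluoxetine", "SSRI"), (3, "amitriptyline", "TCA")])
        assert find_candidate_switches(rx, CRIT) == []

    def test_heavily_prescribed_index_fails_total_and_before(self):
        rx = rx_frame(
            [(0, "fluoxetine", "SSRI"), (28, "fluoxetine", "SSRI"), (56, "fluoxetine", "SSRI"),
             (84, "fluoxetine", "SSRI"), (90, "amitriptyline", "TCA")]
        )
        (ev,) = find_candidate_switches(rx, CRIT)
        assert ev.gap_days == 90
        assert not ev.criteria_pass["total_le_3"]
        assert not ev.criteria_pass["before_le_2"]
        assert not ev.valid

    def test_no_ssri_no_events(self):
        rx = rx_frame([(0, "amitriptyline", "TCA"), (40, "venlafaxine", "SNRI")])
        assert find_candidate_switches(rx, CRIT) == []

    def test_switch_to_another_ssri_counts(self):
        rx = rx_frame([(0, "fluoxetine", "SSRI"), (20, "sertraline", "SSRI")])
        events = find_candidate_switches(rx, CRIT)
        assert any(e.valid and e.index_ssri == "fluoxetine" and e.post_switch_drug == "sertraline" for e in events)

    def test_non_ad_never_a_switch_target(self):
        rx = rx_frame([(0, "fluoxetine", "SSRI"), (30, "ibuprofen", "NON_AD")])
        assert find_candidate_switches(rx, CRIT) == []

    def test_last_before_anchor_changes_gap(self):
        crit = PhenotypeCriteria(anchor="last_before")
        rx = rx_frame(
            [(0, "fluoxetine", "SSRI"), (90, "fluoxetine", "SSRI"), (100, "amitriptyline", "TCA")]
        )
        (ev,) = find_candidate_switches(rx, crit)
        assert ev.gap_days == 10  # measured from the day-90 issue
        assert find_candidate_switches(rx, CRIT) == []  # first-anchor gap 100 > 95


class TestClassifyParticipant:
    def test_three_issue_ssri_only_is_nonswitcher(self):
        rx = rx_frame([(0, "fluoxetine", "SSRI"), (28, "fluoxetine", "SSRI"), (56, "fluoxetine", "SSRI")])
        rec = classify_participant(rx, CRIT)
        assert rec["status"] == "NONSWITCHER" and rec["n_index_ssri_rx"] == 3
        assert rec["index_date"] == pd.Timestamp("1970-01-01")
        assert rec["time_to_switch_days"] is None

    def test_single_issue_is_unclassified(self):
        rec = classify_participant(rx_frame([(0, "fluoxetine", "SSRI")]), CRIT)
        assert rec["status"] == "UNCLASSIFIED"

    def test_switcher_index_fields(self):
        rx = rx_frame([(10, "citalopram", "SSRI"), (40, "venlafaxine", "SNRI")])
        rec = classify_participant(rx, CRIT)
        assert rec["status"] == "SWITCHER"
        assert rec["index_ssri"] == "citalopram"
        assert rec["time_to_switch_days"] == 30
        assert rec["post_switch_class"] == "SNRI"

    def test_augmentation_pattern_with_persistent_ssri_is_nonswitcher(self):
        """Invalid candidate events do not block the nonswitcher rule."""
        rx = rx_frame(
            [(0, "fluoxetine", "SSRI"), (2, "mirtazapine", "OTHER_AD"),
             (28, "fluoxetine", "SSRI"), (56, "fluoxetine", "SSRI"), (84, "fluoxetine", "SSRI")]
        )
        rec = classify_participant(rx, CRIT)
        assert rec["status"] == "NONSWITCHER"

    def test_earliest_switch_wins_tiebreak_alphabetical(self):
        rx = rx_frame(
            [(0, "fluoxetine", "SSRI"), (30, "venlafaxine", "SNRI"), (30, "amitriptyline", "TCA")]
        )
        rec = classify_participant(rx, CRIT)
        assert rec["post_switch_drug"] == "amitriptyline"

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle_on_random_histories(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            hist = random_history(rng)
            rec = classify_participant(rx_frame(hist), CRIT)
            assert rec["status"] == classify_oracle(hist, CRIT), hist

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 120),
                st.sampled_from(DRUG_POOL),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_oracle_equivalence_property(self, raw):
        hist = [(day, drug, cls) for day, (drug, cls) in raw]
        rec = classify_participant(rx_frame(hist), CRIT)
        assert rec["status"] == classify_oracle(hist, CRIT)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_row_order_invariance(self, perm):
        hist = [(0, "fluoxetine", "SSRI"), (10, "fluoxetine", "SSRI"),
                (40, "sertraline", "SSRI"), (60, "amitriptyline", "TCA"),
                (80, "ibuprofen", "NON_AD"), (95, "venlafaxine", "SNRI")]
        shuffled = [hist[i] for i in perm]
        a = classify_participant(rx_frame(shuffled), CRIT)
        b = classify_participant(rx_frame(hist), CRIT)
        assert a == b


class TestPhenotypeCohort:
    def test_composition_counts(self):
        rx = pd.concat(
            [
                rx_frame([(0, "fluoxetine", "SSRI"), (28, "fluoxetine", "SSRI"), (56, "fluoxetine", "SSRI")], "P1"),
                rx_frame([(0, "fluoxetine", "SSRI")], "P2"),
            ]
        ).sort_values(["participant_id", "issue_date"]).reset_index(drop=True)
        pheno, counts = phenotype_cohort(rx)
        got = counts.set_index("status")["n"]
        assert got["SWITCHER"] == 0 and got["NONSWITCHER"] == 1 and got["UNCLASSIFIED"] == 1

    def test_statuses_are_exhaustive_and_exclusive(self, small_phenotyped):
        _, _, pheno, _ = small_phenotyped
        assert pheno["status"].isin(["SWITCHER", "NONSWITCHER", "UNCLASSIFIED"]).all()
        sw = pheno[pheno["status"] == "SWITCHER"]
        assert sw["time_to_switch_days"].between(CRIT.min_gap_days, CRIT.max_gap_days).all()
        assert (sw["n_index_ssri_rx"] <= CRIT.max_index_rx_total).all()
        ns = pheno[pheno["status"] == "NONSWITCHER"]
        assert (ns["n_index_ssri_rx"] >= CRIT.min_nonswitcher_rx).all()
        assert ns["time_to_switch_days"].isna().all()

    def test_excluded_participants_dropped_from_counts(self, small_phenotyped):
        cohort, mem, pheno, counts = small_phenotyped
        excluded = set(mem.loc[mem["excluded"], "participant_id"])
        assert excluded.isdisjoint(set(pheno["participant_id"]))

    def test_recovered_prevalence_near_target(self, small_phenotyped):
        cohort, _, pheno, _ = small_phenotyped
        target = cohort.config.target_prevalence
        classified = pheno[pheno["status"] != "UNCLASSIFIED"]
        prev = (classified["status"] == "SWITCHER").mean()
        sd = np.sqrt(target * (1 - target) / len(classified))
        assert abs(prev - target) < 3 * sd

    def test_tightening_max_gap_never_adds_switchers(self, small_cohort):
        rx = small_cohort.prescriptions
        loose = phenotype_cohort(rx, criteria=PhenotypeCriteria(max_gap_days=95))[0]
        tight = phenotype_cohort(rx, criteria=PhenotypeCriteria(max_gap_days=60))[0]
        n_loose = (loose["status"] == "SWITCHER").sum()
        n_tight = (tight["status"] == "SWITCHER").sum()
        assert n_tight <= n_loose
        # per-participant: no one becomes a switcher under the tighter rule
        merged = loose.merge(tight, on="participant_id", suffixes=("_loose", "_tight"))
        gained = (merged["status_tight"] == "SWITCHER") & (merged["status_loose"] != "SWITCHER")
        assert not gained.any()


def test_criteria_validation():
    with pytest.raises(ValueError):
        PhenotypeCriteria(min_gap_days=0)
    with pytest.raises(ValueError):
        PhenotypeCriteria(max_gap_days=5, min_gap_days=5)
    with pytest.raises(ValueError):
        PhenotypeCriteria(anchor="middle")
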