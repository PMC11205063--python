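"""Loading, cleaning, exclusion, median split and binarization."""

import numpy as np
import pandas as pd
import pytest

from fluencynet import (
    CleaningRules,
    IntegrityError,
    SchemaError,
    build_response_matrix,
    clean_responses,
    exclude_low_fluency,
    frequency_filter,
    load_fluency,
    median_split,
)
from fluencynet.errors import EmptyResultError
from fluencynet.fluency_data import FluencyDataset, validate_fluency_table


# ---------------------------------------------------------------------------
# loading


class TestLoad:
    def test_toy_file_loads_identity(self, toy_fluency, tmp_path):
        f = tmp_path / "toy.csv"
        toy_fluency.to_csv(f, index=False)
        tab = load_fluency(f)
        assert len(tab) == 3
        assert list(tab["position"]) == [1, 2, 3]

    def test_tab_delimited_is_sniffed(self, toy_fluency, tmp_path):
        f = tmp_path / "toy.tsv"
        toy_fluency.to_csv(f, sep="\t", index=False)
        assert len(load_fluency(f)) == 3

    def test_missing_column_names_it(self, toy_fluency):
        with pytest.raises(SchemaError, match="token"):
            validate_fluency_table(toy_fluency.drop(columns=["token"]))

    def test_duplicate_position_key_rejected(self, toy_fluency):
        dup = pd.concat([toy_fluency, toy_fluency.iloc[[0]]])
        with pytest.raises(IntegrityError):
            validate_fluency_table(dup)

    def test_gapped_positions_reindexed(self, toy_fluency):
        toy_fluency["position"] = [1, 2, 4]
        tab = validate_fluency_table(toy_fluency)
        assert list(tab["position"]) == [1, 2, 3]
        assert list(tab["token"]) == ["dog", "cat", "emu"]


# ---------------------------------------------------------------------------
# cleaning


def _one_list(tokens):
    return pd.DataFrame({
        "participant_id": "p1", "task": "domain_general", "timepoint": "T1",
        "position": range(1, len(tokens) + 1), "token": tokens})


class TestCleaning:
    def test_case_fold_merges_duplicates_keeping_earliest(self):
        ds = clean_responses(_one_list([" Dog", "dog", "cat"]),
                             CleaningRules())
        assert list(ds.responses["token"]) == ["dog", "cat"]
        assert set(ds.cleaning_log["action"]) >= {"duplicate_removed"}

    def test_normalization_map_applied(self):
        rules = CleaningRules(normalization_map={"dgo": "dog"})
        ds = clean_responses(_one_list(["dgo", "cat"]), rules)
        assert list(ds.responses["token"]) == ["dog", "cat"]

    def test_non_category_members_excluded(self):
        # intrusions like "dragon" in an animal task are dropped
        rules = CleaningRules(exclusion_list=frozenset({"dragon"}))
        ds = clean_responses(_one_list(["dragon", "cat"]), rules)
        assert list(ds.responses["token"]) == ["cat"]
        assert (ds.cleaning_log["action"] == "excluded").sum() == 1

    def test_non_idempotent_map_rejected(self):
        with pytest.raises(IntegrityError):
            CleaningRules(normalization_map={"a": "b", "b": "c"})

    def test_cleaning_is_idempotent(self):
        rng = np.random.default_rng(5)
        tokens = [f" {t.upper()} " if rng.random() < 0.5 else t
                  for t in rng.choice(list("abcdefg"), size=30)]
        rows = []
        for pid in ("p1", "p2", "p3"):
            for pos, tok in enumerate(tokens[:10], 1):
                rows.append({"participant_id": pid, "task": "t",
                             "timepoint": "T1", "position": pos,
                             "token": tok})
            tokens = tokens[10:]
        rules = CleaningRules(normalization_map={"a": "g"},
                              exclusion_list=frozenset({"b"}))
        once = clean_responses(pd.DataFrame(rows), rules)
        twice = clean_responses(once.responses, rules)
        pd.testing.assert_frame_equal(once.responses, twice.responses)
        assert twice.cleaning_log.empty


# ---------------------------------------------------------------------------
# low-fluency exclusion


class TestLowFluencyExclusion:
    def _two_task_ds(self):
        rows = []
        for pid, n_psy, n_ani in [("p1", 2, 10), ("p2", 5, 5), ("p3", 4, 6)]:
            for task, n in [("domain_specific", n_psy),
                            ("domain_general", n_ani)]:
                for pos in range(1, n + 1):
                    rows.append({"participant_id": pid, "task": task,
                                 "timepoint": "T1", "position": pos,
                                 "token": f"{task[:2]}{pos}"})
        return clean_responses(pd.DataFrame(rows))

    def test_short_list_on_one_task_removes_participant_everywhere(self):
        ds = exclude_low_fluency(self._two_task_ds(), min_responses=3)
        assert ds.participants == ["p2", "p3"]
        assert "p1" not in set(ds.responses["participant_id"])

    def test_identity_when_all_lists_long_enough(self):
        before = self._two_task_ds()
        after = exclude_low_fluency(before, min_responses=2)
        pd.testing.assert_frame_equal(before.responses, after.responses)

    def test_everyone_excluded_is_fatal(self):
        with pytest.raises(EmptyResultError):
            exclude_low_fluency(self._two_task_ds(), min_responses=11)


# ---------------------------------------------------------------------------
# median split


class TestMedianSplit:
    def test_hand_example_with_ties_at_median(self):
        ga = median_split({"a": 1, "b": 2, "c": 3, "d": 3, "e": 4, "f": 5})
        assert ga.median == 3
        assert ga.low == ["a", "b"]
        assert ga.high == ["e", "f"]
        assert ga.excluded_at_median == ["c", "d"]

    def test_unique_median_element_excluded(self):
        ga = median_split({"a": 1, "b": 2, "c": 3})
        assert ga.low == ["a"] and ga.high == ["c"]
        assert ga.excluded_at_median == ["b"]

    def test_even_n_between_values_drops_nobody(self):
        ga = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert ga.excluded_at_median == []
        assert ga.low == ["a", "b"] and ga.high == ["c", "d"]

    def test_identical_scores_fatal(self):
        with pytest.raises(IntegrityError):
            median_split({"a": 2, "b": 2, "c": 2})

    def test_partition_and_separation_properties(self):
        rng = np.random.default_rng(11)
        scores = {f"p{i}": int(rng.integers(0, 30)) for i in range(97)}
        ga = median_split(scores)
        assert (len(ga.low) + len(ga.high) + len(ga.excluded_at_median)
                == len(scores))
        assert max(scores[p] for p in ga.low) < ga.median
        assert min(scores[p] for p in ga.high) > ga.median


# ---------------------------------------------------------------------------
# binarization and frequency filtering


class TestResponseMatrix:
    def test_two_participant_example(self, two_participant_dataset):
        ds = FluencyDataset(
            responses=validate_fluency_table(two_participant_dataset))
        m = build_response_matrix(ds, "domain_general", "T1")
        assert m.shape == (2, 3)
        assert list(m.columns) == ["a", "b", "c"]
        assert m.loc["p1"].tolist() == [1, 1, 0]
        assert m.loc["p2"].tolist() == [0, 1, 1]

    def test_repeated_token_binarized_after_cleaning(self):
        ds = clean_responses(_one_list(["dog", "dog", "cat"]))
        m = build_response_matrix(ds, "domain_general", "T1")
        assert m.to_numpy().max() == 1
        assert m.loc["p1", "dog"] == 1

    def test_column_sums_match_brute_force_tally(self):
        rng = np.random.default_rng(23)
        vocab = [f"w{i}" for i in range(15)]
        rows, tally = [], {}
        for i in range(10):
            produced = rng.choice(vocab, size=rng.integers(3, 9),
                                  replace=False)
            for pos, tok in enumerate(produced, 1):
                rows.append({"participant_id": f"p{i}", "task": "t",
                             "timepoint": "T1", "position": pos,
                             "token": tok})
                tally[tok] = tally.get(tok, 0) + 1
        ds = FluencyDataset(responses=validate_fluency_table(
            pd.DataFrame(rows)))
        m = build_response_matrix(ds, "t", "T1")
        for tok, count in tally.items():
            assert m[tok].sum() == count

    def test_frequency_filter_drops_rare_columns(self):
        m = pd.DataFrame([[1, 1, 1], [0, 1, 1], [0, 0, 1], [0, 0, 1],
                          [0, 0, 1]], columns=["x", "y", "z"])
        out = frequency_filter(m, min_producers=2)
        assert list(out.columns) == ["y", "z"]
        assert frequency_filter(m, min_producers=1).shape == m.shape

    def test_frequency_filter_matches_producer_count_oracle(self):
        rng = np.random.default_rng(31)
        m = pd.DataFrame((rng.random((50, 40)) < 0.08).astype(int),
                         columns=[f"w{i}" for i in range(40)])
        m.iloc[0, 0] = 1  # guarantee at least one retained column path
        m.iloc[1, 0] = 1
        expected = sum((m[c].sum() >= 2) for c in m.columns)
        assert frequency_filter(m, 2).shape[1] == expected

    def test_all_columns_dropped_is_fatal(self):
        m = pd.DataFrame([[1, 0], [0, 1]], columns=["a", "b"])
        with pytest.raises(EmptyResultError):
            frequency_filter(m, min_producers=2)

    def test_resampling_never_introduces_new_columns(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame((rng.random((12, 10)) < 0.4).astype(int),
                         columns=[f"w{i}" for i in range(10)])
        universe = set(m.columns)
        for _ in range(20):
            idx = rng.integers(0, 12, size=12)
            sub = m.iloc[idx]
            produced = set(sub.columns[sub.sum(axis=0) > 0])
            assert produced <= universe
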