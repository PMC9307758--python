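"""Crossover worklist simulation and time metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctanomaly.worklist_sim import (
    Block,
    ReadingEventLog,
    compute_time_metrics,
    load_external_times,
    lognormal_reader,
    make_blocks,
    partition_and_randomize,
    reprioritize,
    run_session,
    simulate_crossover,
    summarize_outcomes,
    write_times,
)


def ids(n, prefix="c"):
    return [f"{prefix}{i:04d}" for i in range(n)]


class TestPartition:
    def test_1795_splits_898_897(self):
        a, b, _ = partition_and_randomize(ids(1795), seed=0)
        assert sum(len(bl.case_ids) for bl in a) == 898
        assert sum(len(bl.case_ids) for bl in b) == 897

    def test_898_gives_39_blocks_last_24(self):
        blocks = make_blocks(ids(898), block_size=23)
        assert len(blocks) == 39
        assert [len(b.case_ids) for b in blocks[:-1]] == [23] * 38
        assert len(blocks[-1].case_ids) == 24

    def test_single_block(self):
        blocks = make_blocks(ids(23), block_size=23)
        assert len(blocks) == 1 and len(blocks[0].case_ids) == 23

    def test_session_orders_are_permutations(self):
        a, b, orders = partition_and_randomize(ids(100), block_size=10, seed=1)
        for (g, s), order in orders.items():
            n = len(a) if g == "A" else len(b)
            assert sorted(order) == list(range(n))

    def test_deterministic(self):
        r1 = partition_and_randomize(ids(50), seed=3)
        r2 = partition_and_randomize(ids(50), seed=3)
        assert [b.case_ids for b in r1[0]] == [b.case_ids for b in r2[0]]
        assert r1[2] == r2[2]

    def test_invalid_block_size(self):
        with pytest.raises(ValueError, match="block_size"):
            partition_and_randomize(ids(10), block_size=0)


def stable_partition_oracle(case_ids, scores, threshold):
    """Independent oracle: stable partition + insertion sort by -score."""
    flagged = sorted(
        [c for c in case_ids if scores[c] >= threshold], key=lambda c: -scores[c]
    )
    rest = [c for c in case_ids if scores[c] < threshold]
    return flagged + rest


class TestReprioritize:
    def test_none_flagged_order_unchanged(self):
        block = Block(ids(5), "A", 0)
        scores = {c: 0.0 for c in block.case_ids}
        order, flags = reprioritize(block, scores, threshold=1.0)
        assert order == block.case_ids
        assert not any(flags.values())

    def test_all_flagged_descending(self):
        block = Block(ids(5), "A", 0)
        scores = {c: float(i) for i, c in enumerate(block.case_ids)}
        order, flags = reprioritize(block, scores, threshold=-1.0)
        assert order == sorted(block.case_ids, key=lambda c: -scores[c])
        assert all(flags.values())

    def test_mixed_matches_oracle(self):
        block = Block(["a", "b", "c", "d", "e", "f"], "A", 0)
        scores = {"a": 0.2, "b": 5.0, "c": 0.1, "d": 7.0, "e": 0.3, "f": 6.0}
        order, flags = reprioritize(block, scores, threshold=1.0)
        assert order == stable_partition_oracle(block.case_ids, scores, 1.0)
        assert order == ["d", "f", "b", "a", "c", "e"]
        assert [flags[c] for c in order] == [True, True, True, False, False, False]

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            reprioritize(Block(["a", "b"], "A", 0), {"a": 1.0}, 0.0)

    @given(st.lists(st.floats(0, 10), min_size=2, max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_permutation_property(self, raw_scores):
        case_ids = [f"c{i}" for i in range(len(raw_scores))]
        scores = dict(zip(case_ids, raw_scores))
        order, _ = reprioritize(Block(case_ids, "A", 0), scores, threshold=5.0)
        assert sorted(order) == sorted(case_ids)


class TestRunSession:
    def test_cumulative_opens(self):
        block = Block(["a", "b", "c"], "A", 0)
        rts = {"a": 30.0, "b": 40.0, "c": 20.0}
        log = run_session([block], {0: block.case_ids}, lambda c, rng: rts[c])
        f = log.frame.set_index("case_id")
        assert f.loc[["a", "b", "c"], "open"].tolist() == [0.0, 30.0, 70.0]

    def test_single_case(self):
        block = Block(["a"], "A", 0)
        log = run_session([block], {0: ["a"]}, lambda c, rng: 29.0)
        tm = compute_time_metrics(log).frame.iloc[0]
        assert (tm["WT"], tm["RT"], tm["TAT"]) == (0.0, 29.0, 29.0)

    def test_permuted_worklist_consistent(self):
        block = Block(["a", "b", "c"], "A", 0)
        rts = {"a": 10.0, "b": 20.0, "c": 30.0}
        model = lambda c, rng: rts[c]
        log = run_session([block], {0: ["c", "a", "b"]}, model)
        f = log.frame.set_index("case_id")
        # oracle: recompute cumulative opens for the permuted order
        expected = {"c": 0.0, "a": 30.0, "b": 40.0}
        for cid, t in expected.items():
            assert f.loc[cid, "open"] == t

    def test_non_positive_rt_rejected(self):
        block = Block(["a"], "A", 0)
        with pytest.raises(ValueError, match="non-positive"):
            run_session([block], {0: ["a"]}, lambda c, rng: 0.0)

    def test_non_permutation_worklist_rejected(self):
        block = Block(["a", "b"], "A", 0)
        with pytest.raises(ValueError, match="permutation"):
            run_session([block], {0: ["a", "a"]}, lambda c, rng: 1.0)


class TestTimeMetrics:
    def test_fixture_10_40_40(self):
        log = ReadingEventLog(
            pd.DataFrame(
                [{"case_id": "x", "block": 0, "open": 10.0, "close": 40.0, "report": 40.0}]
            )
        )
        tm = compute_time_metrics(log).frame.iloc[0]
        assert (tm["WT"], tm["RT"], tm["TAT"]) == (10.0, 30.0, 40.0)

    def test_zero_rt(self):
        log = ReadingEventLog(
            pd.DataFrame(
                [{"case_id": "x", "block": 0, "open": 5.0, "close": 5.0, "report": 6.0}]
            )
        )
        assert compute_time_metrics(log).frame.iloc[0]["RT"] == 0.0

    def test_identity_tat_wt_rt(self):
        rng = np.random.default_rng(0)
        rows = []
        t = 0.0
        for i in range(10):
            rt = float(rng.uniform(5, 50))
            rows.append(
                {"case_id": f"c{i}", "block": 0, "open": t, "close": t + rt, "report": t + rt}
            )
            t += rt
        tm = compute_time_metrics(ReadingEventLog(pd.DataFrame(rows))).frame
        np.testing.assert_allclose(tm["TAT"] - tm["WT"], tm["RT"])

    def test_invalid_log_named(self):
        with pytest.raises(ValueError, match="bad-case"):
            ReadingEventLog(
                pd.DataFrame(
                    [{"case_id": "bad-case", "block": 0, "open": 10.0, "close": 5.0, "report": 10.0}]
                )
            )


class TestSummarize:
    def _times(self, n=10, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            wt = float(rng.uniform(10, 400))
            rt = float(rng.uniform(20, 40))
            for arm, off in (("pre", 0.0), ("post", delta)):
                rows.append(
                    {
                        "case_id": f"c{i}",
                        "group": "A",
                        "reader": 1,
                        "session": 1,
                        "arm": arm,
                        "WT": wt + off,
                        "RT": rt,
                        "TAT": wt + rt + off,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_pre_post(self):
        out = summarize_outcomes(self._times(delta=0.0))
        row = out[out["metric"] == "WT"].iloc[0]
        assert row["median_diff"] == 0.0
        assert row["p_signed_rank"] == 1.0

    def test_hand_computed_medians(self):
        rows = []
        wts = [10.0, 20.0, 30.0, 40.0, 100.0]
        for i, wt in enumerate(wts):
            for arm in ("pre", "post"):
                rows.append(
                    {"case_id": f"c{i}", "arm": arm, "WT": wt, "RT": 5.0, "TAT": wt + 5}
                )
        out = summarize_outcomes(pd.DataFrame(rows))
        row = out[out["metric"] == "WT"].iloc[0]
        assert row["pre_median"] == 30.0
        assert row["pre_iqr"] == pytest.approx(np.percentile(wts, 75) - np.percentile(wts, 25))
        assert row["pre_min"] == 10.0 and row["pre_max"] == 100.0

    def test_unpaired_case_rejected(self):
        df = self._times()
        df = df.drop(df[(df["case_id"] == "c3") & (df["arm"] == "post")].index)
        with pytest.raises(ValueError, match="unpaired"):
            summarize_outcomes(df)

    def test_iqr_matches_sort_based_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 17)
        df = self._times(n=17, seed=1)
        row = summarize_outcomes(df)[lambda d: d["metric"] == "WT"].iloc[0]
        wts = df[df["arm"] == "pre"]["WT"].to_numpy()
        srt = np.sort(wts)
        assert row["pre_median"] == pytest.approx(np.median(srt))


class TestCrossover:
    def test_directional_pattern_perfect_classifier(self):
        rng = np.random.default_rng(0)
        n = 200
        case_ids = ids(n)
        emergency = rng.random(n) < 0.11
        scores = {c: (10.0 if e else 0.0) for c, e in zip(case_ids, emergency)}
        times = simulate_crossover(case_ids, scores, threshold=5.0, seed=2)
        emerg_ids = [c for c, e in zip(case_ids, emergency) if e]
        non_ids = [c for c, e in zip(case_ids, emergency) if not e]
        out = summarize_outcomes(times, {"emergency": emerg_ids, "non_emergency": non_ids})
        wt_e = out[(out["subgroup"] == "emergency") & (out["metric"] == "WT")].iloc[0]
        wt_n = out[(out["subgroup"] == "non_emergency") & (out["metric"] == "WT")].iloc[0]
        assert wt_e["post_median"] < wt_e["pre_median"]
        assert wt_n["post_median"] >= wt_n["pre_median"]

    def test_observation_counts(self):
        case_ids = ids(46)
        scores = {c: 0.0 for c in case_ids}
        times = simulate_crossover(case_ids, scores, threshold=1.0, seed=0, n_readers=2)
        # each case: 2 readers x 2 sessions = 4 observations, 2 per arm
        counts = times.groupby(["case_id", "arm"]).size()
        assert (counts == 2).all()

    def test_flagged_prefix_wt_invariant(self):
        """Within any block, flagged cases have lower mean WT than unflagged."""
        case_ids = ids(46)
        rng = np.random.default_rng(4)
        scores = {c: float(rng.random() < 0.2) * 10 for c in case_ids}
        blocks = make_blocks(case_ids, 23)
        for blk in blocks:
            order, flags = reprioritize(blk, scores, 5.0)
            log = run_session([blk], {blk.index: order}, lognormal_reader(), seed=1)
            tm = compute_time_metrics(log).frame.set_index("case_id")
            flagged = [c for c in order if flags[c]]
            unflagged = [c for c in order if not flags[c]]
            if flagged and unflagged:
                assert tm.loc[flagged, "WT"].mean() <= tm.loc[unflagged, "WT"].mean()


class TestExternalTimes:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            for arm in ("pre", "post"):
                wt = float(rng.uniform(0, 100))
                rt = float(rng.uniform(10, 40))
                rows.append(
                    {
                        "case_id": f"c{i}",
                        "group": "A",
                        "reader": 1,
                        "session": 1,
                        "arm": arm,
                        "WT": wt,
                        "TAT": wt + rt,
                        "RT": rt,
                    }
                )
        df = pd.DataFrame(rows)
        path = tmp_path / "times.csv"
        write_times(df, path)
        loaded = load_external_times(path)
        import pandas.testing as pdt

        pdt.assert_frame_equal(
            summarize_outcomes(loaded), summarize_outcomes(df)
        )

    def test_negative_rt_rejected(self, tmp_path):
        df = pd.DataFrame(
            [
                {
                    "case_id": "c0",
                    "group": "A",
                    "reader": 1,
                    "session": 1,
                    "arm": "pre",
                    "WT": 5.0,
                    "TAT": 10.0,
                    "RT": -1.0,
                }
            ]
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="invalid time"):
            load_external_times(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame([{"case_id": "a", "WT": 1.0}]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing column"):
            load_external_times(path)

    def test_emergency_subset_counts(self, tmp_path):
        rows = []
        emergency = {f"c{i}": i % 3 == 0 for i in range(9)}
        for cid in emergency:
            for arm in ("pre", "post"):
                rows.append(
                    {
                        "case_id": cid,
                        "group": "A",
                        "reader": 1,
                        "session": 1,
                        "arm": arm,
                        "WT": 1.0,
                        "TAT": 2.0,
                        "RT": 1.0,
                    }
                )
        path = tmp_path / "times.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        loaded = load_external_times(path)
        emerg_ids = [c for c, e in emergency.items() if e]
        out = summarize_outcomes(loaded, {"emergency": emerg_ids})
        assert (out["n"] == len(emerg_ids)).all()
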