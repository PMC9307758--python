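"""Randomized-crossover worklist reading simulation and time metrics.

Cases are split into two near-equal groups, partitioned into blocks of
nominal size 23 (the final block absorbs any remainder).  Within a
session, a reader opens a block's cases strictly in worklist order,
back-to-back from the block opening at t=0; triage moves cases at or
above the score threshold to the front, sorted by descending score,
leaving the rest in their original relative order.

Per-case wait time (WT), report turnaround time (TAT), and reading time
(RT) are measured from the block opening; summaries mirror the paired
pre/post comparison tables (median/IQR, mean/SD, min-max, paired
difference, signed-rank and rank-sum tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Block",
    "ReadingEventLog",
    "TimeMetrics",
    "make_blocks",
    "partition_and_randomize",
    "reprioritize",
    "run_session",
    "compute_time_metrics",
    "simulate_crossover",
    "summarize_outcomes",
    "load_external_times",
    "write_times",
    "lognormal_reader",
]

BLOCK_SIZE = 23


@dataclass
class Block:
    case_ids: list[str]
    group: str  # "A" | "B"
    index: int
    session: int | None = None
    with_triage: bool = False


@dataclass
class ReadingEventLog:
    """Per-case timestamps in seconds; block open defines t = 0."""

    frame: pd.DataFrame  # case_id, block, open, close, report

    def __post_init__(self):
        f = self.frame
        bad = f[(f["open"] > f["close"]) | (f["report"] < f["open"]) | (f["open"] < 0)]
        if len(bad):
            raise ValueError(
                f"invalid event log for case(s) {bad['case_id'].tolist()[:5]}"
            )


@dataclass
class TimeMetrics:
    frame: pd.DataFrame  # case_id, WT, TAT, RT

    def __post_init__(self):
        f = self.frame
        bad = f[(f["WT"] < 0) | (f["RT"] < 0) | (f["TAT"] < f["WT"])]
        if len(bad):
            raise ValueError(
                f"invalid time metrics for case(s) {bad['case_id'].tolist()[:5]}"
            )


def make_blocks(case_ids: list[str], block_size: int = BLOCK_SIZE, group: str = "A") -> list[Block]:
    """Chunk an ordered case list into ``floor(n / block_size)`` blocks;
    the remainder is absorbed into the final block."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    members = list(case_ids)
    n_blocks = max(len(members) // block_size, 1)
    blocks = []
    for b in range(n_blocks):
        lo = b * block_size
        hi = (b + 1) * block_size if b < n_blocks - 1 else len(members)
        blocks.append(Block(members[lo:hi], group, b))
    return blocks


def partition_and_randomize(
    case_ids: list[str], block_size: int = BLOCK_SIZE, seed: int = 0
) -> tuple[list[Block], list[Block], dict]:
    """Split cases into groups A/B, chunk each into blocks, and draw an
    independent block reading order for each session.

    The groups differ in size by at most one (larger group first); each
    group holds ``floor(n_group / block_size)`` blocks, with the
    remainder absorbed into the final block.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if len(case_ids) < 2:
        raise ValueError("need at least two cases")
    rng = np.random.default_rng(seed)
    ids = list(case_ids)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_a = (len(ids) + 1) // 2  # larger group first when n is odd
    groups = {"A": shuffled[:n_a], "B": shuffled[n_a:]}

    blocks = {
        gname: make_blocks(members, block_size, gname)
        for gname, members in groups.items()
    }

    session_orders = {
        (gname, session): rng.permutation(len(blocks[gname])).tolist()
        for gname in ("A", "B")
        for session in (1, 2)
    }
    return blocks["A"], blocks["B"], session_orders


def reprioritize(
    block: Block, scores: dict[str, float], threshold: float
) -> tuple[list[str], dict[str, bool]]:
    """Triage a block's worklist: flagged cases (score >= threshold) move
    to the front sorted by descending score; others keep their order."""
    missing = [c for c in block.case_ids if c not in scores]
    if missing:
        raise ValueError(f"missing anomaly score for case(s) {missing[:5]}")
    flagged = [c for c in block.case_ids if scores[c] >= threshold]
    flagged.sort(key=lambda c: -scores[c])
    rest = [c for c in block.case_ids if scores[c] < threshold]
    order = flagged + rest
    return order, {c: (c in set(flagged)) for c in order}


def lognormal_reader(median_s: float = 30.0, sigma: float = 0.3, vmax: float = 80.0):
    """Default stand-in reader: log-normal reading times with the given
    median, truncated to ``vmax`` seconds."""

    def model(case_id: str, rng: np.random.Generator) -> float:
        return float(min(np.exp(np.log(median_s) + sigma * rng.standard_normal()), vmax))

    return model


def run_session(
    blocks: list[Block],
    worklists: dict[int, list[str]],
    reader_model,
    seed: int = 0,
) -> ReadingEventLog:
    """Simulate one reader working through blocks; cases within a block
    open back-to-back in worklist order from the block opening at t=0."""
    rng = np.random.default_rng(seed)
    rows = []
    for block in blocks:
        order = worklists.get(block.index, block.case_ids)
        if sorted(order) != sorted(block.case_ids):
            raise ValueError(f"worklist for block {block.index} is not a permutation")
        t = 0.0
        for cid in order:
            rt = float(reader_model(cid, rng))
            if rt <= 0:
                raise ValueError(f"reader model returned non-positive RT for {cid}")
            rows.append(
                {
                    "case_id": cid,
                    "block": block.index,
                    "open": t,
                    "close": t + rt,
                    "report": t + rt,
                }
            )
            t += rt
    return ReadingEventLog(pd.DataFrame(rows))


def compute_time_metrics(log: ReadingEventLog) -> TimeMetrics:
    """WT = open - block open (0); TAT = report - block open; RT = close - open."""
    f = log.frame
    out = pd.DataFrame(
        {
            "case_id": f["case_id"],
            "WT": f["open"].astype(float),
            "TAT": f["report"].astype(float),
            "RT": (f["close"] - f["open"]).astype(float),
        }
    )
    return TimeMetrics(out)


def simulate_crossover(
    case_ids: list[str],
    scores: dict[str, float],
    threshold: float,
    seed: int = 0,
    n_readers: int = 2,
    reader_model=None,
    block_size: int = BLOCK_SIZE,
) -> pd.DataFrame:
    """Full crossover simulation.

    Session 1 reads group A without triage and group B with it; session 2
    swaps the arms.  Each reader contributes one pre and one post
    observation per case.  Returns tidy per-observation rows
    (case_id, group, reader, session, arm, WT, TAT, RT).
    """
    reader_model = reader_model or lognormal_reader()
    blocks_a, blocks_b, orders = partition_and_randomize(case_ids, block_size, seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for reader in range(1, n_readers + 1):
        for session in (1, 2):
            for gname, blocks in (("A", blocks_a), ("B", blocks_b)):
                with_triage = (gname == "B") == (session == 1)
                ordered = [blocks[i] for i in orders[(gname, session)]]
                worklists = {}
                for blk in ordered:
                    if with_triage:
                        worklists[blk.index], _ = reprioritize(blk, scores, threshold)
                    else:
                        worklists[blk.index] = list(blk.case_ids)
                log = run_session(
                    ordered, worklists, reader_model, seed=int(rng.integers(2**31))
                )
                tm = compute_time_metrics(log).frame
                tm["group"] = gname
                tm["reader"] = reader
                tm["session"] = session
                tm["arm"] = "post" if with_triage else "pre"
                rows.append(tm)
    return pd.concat(rows, ignore_index=True)[
        ["case_id", "group", "reader", "session", "arm", "WT", "TAT", "RT"]
    ]


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    return float(q3 - q1)


def _summary_cells(x: np.ndarray) -> dict:
    return {
        "median": float(np.median(x)),
        "iqr": _iqr(x),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def summarize_outcomes(
    times: pd.DataFrame,
    subgroups: dict[str, list[str]] | None = None,
    metrics: tuple[str, ...] = ("WT", "RT", "TAT"),
    pooled: bool = True,
) -> pd.DataFrame:
    """Paired pre/post summary per subgroup and metric.

    ``times`` holds tidy observations (case_id, reader, arm, WT/TAT/RT).
    Pre and post observations are paired by (case_id, reader) — pooled
    over readers by default.  ``subgroups`` maps a subgroup name to its
    case ids; by default a single "all" subgroup is used.
    """
    required = {"case_id", "arm"} | set(metrics)
    missing = required - set(times.columns)
    if missing:
        raise ValueError(f"times table is missing columns {sorted(missing)}")
    if not pooled and "reader" in times.columns:
        # per-reader averaging: one observation per case and arm
        times = times.groupby(["case_id", "arm"], as_index=False)[list(metrics)].mean()
    keys = ["case_id"] + (["reader"] if "reader" in times.columns else [])
    pre = times[times["arm"] == "pre"].set_index(keys)
    post = times[times["arm"] == "post"].set_index(keys)
    common = pre.index.intersection(post.index)
    unpaired = pre.index.symmetric_difference(post.index)
    if len(unpaired):
        raise ValueError(f"unpaired observation(s): {list(unpaired[:5])}")
    pre, post = pre.loc[common], post.loc[common]
    if subgroups is None:
        subgroups = {"all": sorted(set(times["case_id"]))}

    rows = []
    for name, members in subgroups.items():
        member_set = set(members)
        sel = pre.index.get_level_values("case_id").isin(member_set)
        if not sel.any():
            continue
        for metric in metrics:
            a = pre.loc[sel, metric].to_numpy(dtype=float)
            b = post.loc[sel, metric].to_numpy(dtype=float)
            diff = b - a
            if np.allclose(diff, 0.0):
                p_signed = 1.0
            else:
                p_signed = float(sps.wilcoxon(a, b, zero_method="wilcox").pvalue)
            row = {"subgroup": name, "metric": metric, "n": int(sel.sum())}
            row.update({f"pre_{k}": v for k, v in _summary_cells(a).items()})
            row.update({f"post_{k}": v for k, v in _summary_cells(b).items()})
            row["median_diff"] = float(np.median(diff))
            row["iqr_diff"] = _iqr(diff)
            row["p_signed_rank"] = p_signed
            rows.append(row)
    out = pd.DataFrame(rows)

    # between-subgroup rank-sum tests on the paired differences
    if len(subgroups) >= 2:
        names = list(subgroups)
        pair_ps = {}
        for metric in metrics:
            per = {}
            for name, members in subgroups.items():
                sel = pre.index.get_level_values("case_id").isin(set(members))
                if sel.any():
                    per[name] = (
                        post.loc[sel, metric].to_numpy(dtype=float)
                        - pre.loc[sel, metric].to_numpy(dtype=float)
                    )
            if len(per) == 2:
                a, b = per.values()
                pair_ps[metric] = float(sps.ranksums(np.abs(a), np.abs(b)).pvalue)
        if pair_ps:
            out["p_rank_sum_between"] = out["metric"].map(pair_ps)
    return out


EXTERNAL_COLUMNS = ["case_id", "group", "reader", "session", "arm", "WT", "TAT", "RT"]


def load_external_times(path) -> pd.DataFrame:
    """Load per-case time observations from a delimited file.

    The file must hold the columns ``case_id, group, reader, session,
    arm, WT, TAT, RT`` with ``arm`` in {pre, post}; times are validated.
    """
    df = pd.read_csv(path)
    missing = set(EXTERNAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"times file is missing column(s) {sorted(missing)}")
    for col in ("WT", "TAT", "RT"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"non-numeric value(s) in column {col}")
        df[col] = vals.astype(float)
    if not set(df["arm"]) <= {"pre", "post"}:
        raise ValueError("arm column must contain only 'pre' and 'post'")
    bad = df[(df["WT"] < 0) | (df["RT"] < 0) | (df["TAT"] < df["WT"])]
    if len(bad):
        raise ValueError(
            f"invalid time value(s) for case(s) {bad['case_id'].tolist()[:5]}"
        )
    return df[EXTERNAL_COLUMNS]


def write_times(df: pd.DataFrame, path) -> None:
    df[EXTERNAL_COLUMNS].to_csv(path, index=False)
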