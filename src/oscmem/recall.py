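"""Serial-recall scoring by relative order.

Participants recall a 20-word list cued position by position; an item
counts as remembered when it appears in the correct *relative* order: a
whole sequence shifted in output position (items 5-10 recalled at output
positions 7-12) is still fully remembered, whereas swapped items (6
recalled before 5) are not.  That rule is formalized here as a maximum-
cardinality increasing subsequence of the presented indices in recall
order; items recalled outside that subsequence are out-of-sequence (and
discarded from the design cells downstream), unrecalled items are
forgotten.  Ties between equally long subsequences are broken in favour
of the earliest output positions, which makes the labelling deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RecallLog", "RecallScore", "score_recall", "read_recall_tsv",
           "write_score_tsv"]

REMEMBERED = "remembered"
OUT_OF_SEQUENCE = "out_of_sequence"
FORGOTTEN = "forgotten"


@dataclass(frozen=True)
class RecallLog:
    """One list's recall transcript.

    ``recalled`` holds presented indices (1-based) in output order; output
    positions are implicit in the ordering.  Duplicate indices are invalid.
    """

    n_items: int
    recalled: tuple[int, ...]

    def __post_init__(self):
        seq = self.recalled
        if len(set(seq)) != len(seq):
            raise ValueError("duplicate presented_index in recall log")
        for i in seq:
            if not (1 <= i <= self.n_items):
                raise ValueError(f"presented_index {i} outside 1..{self.n_items}")


@dataclass(frozen=True)
class RecallScore:
    """Per-item labels partitioning 1..n_items, plus label counts."""

    labels: tuple[str, ...]  # index k -> label of presented item k+1

    @property
    def counts(self) -> dict[str, int]:
        return {lab: self.labels.count(lab)
                for lab in (REMEMBERED, OUT_OF_SEQUENCE, FORGOTTEN)}

    def items(self, label: str) -> tuple[int, ...]:
        return tuple(i + 1 for i, lab in enumerate(self.labels) if lab == label)


def _lis_earliest(seq: tuple[int, ...]) -> list[int]:
    """Output positions of the maximum increasing subsequence.

    Among all maximum-cardinality increasing subsequences the one whose
    output positions are lexicographically earliest is selected: after
    computing, for every position, the length of the longest increasing
    run starting there, a left-to-right greedy picks the first position
    that still admits a maximum-length completion.  O(n^2), n <= 20 here.
    """
    n = len(seq)
    if n == 0:
        return []
    start_len = [1] * n  # longest increasing subsequence starting at i
    for i in range(n - 2, -1, -1):
        best = 0
        for j in range(i + 1, n):
            if seq[j] > seq[i] and start_len[j] > best:
                best = start_len[j]
        start_len[i] = 1 + best
    remaining = max(start_len)
    out: list[int] = []
    last = -np.inf
    for i in range(n):
        if remaining == 0:
            break
        if start_len[i] == remaining and seq[i] > last:
            out.append(i)
            last = seq[i]
            remaining -= 1
    return out


def score_recall(log: RecallLog) -> RecallScore:
    """Label every presented item remembered / out-of-sequence / forgotten."""
    keep = set(_lis_earliest(log.recalled))
    labels = [FORGOTTEN] * log.n_items
    for pos, item in enumerate(log.recalled):
        labels[item - 1] = REMEMBERED if pos in keep else OUT_OF_SEQUENCE
    return RecallScore(tuple(labels))


def read_recall_tsv(path: str | Path, n_items: int = 20) -> dict[str, RecallLog]:
    """Read recall transcripts from TSV (list_id, output_position, presented_index)."""
    df = pd.read_csv(path, sep="\t")
    required = {"list_id", "output_position", "presented_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"recall TSV needs columns {sorted(required)}")
    logs = {}
    for list_id, grp in df.groupby("list_id", sort=True):
        grp = grp.sort_values("output_position")
        if grp["output_position"].duplicated().any():
            raise ValueError(f"list {list_id}: duplicate output positions")
        logs[str(list_id)] = RecallLog(n_items, tuple(int(i) for i in grp["presented_index"]))
    return logs


def write_score_tsv(scores: dict[str, RecallScore], path: str | Path) -> None:
    rows = [
        {"list_id": lid, "presented_index": i + 1, "label": lab}
        for lid, score in scores.items()
        for i, lab in enumerate(score.labels)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
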