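"""Ranking of candidate source samples by their similarity scores.

Four methods: ``teq`` and ``concentration`` sort by the corresponding
single score; ``weighted`` sorts by the combined weight-based score; and
``consensus`` intersects the top-n TEQ and top-n concentration lists and
orders the common candidates by the mean of their two scores.  Ties are
broken by ascending candidate id so rankings are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from popmatch.similarity import SimilarityResult

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 5

METHODS = ("teq", "concentration", "consensus", "weighted")


class RankingConfigError(ValueError):
    """The requested ranking method is misconfigured."""


@dataclass
class RankingTable:
    """An ordered top-n candidate list under one ranking method."""

    method: str
    rows: list[dict]
    n_requested: int

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def candidate_ids(self) -> list[str]:
        return [r["candidate_id"] for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        cols = ["rank", "candidate_id", "score", "s_teq", "s_conc"]
        df = pd.DataFrame(self.rows)
        if df.empty:
            return pd.DataFrame(columns=cols)
        return df[cols]

    def to_text(self, target_id: str = "") -> str:
        """Human-readable report; scores shown to 4 decimals."""
        head = f"Ranking method: {self.method}"
        if target_id:
            head += f"\nContaminated sample: {target_id}"
        head += f"\nTop {self.n_requested} requested, {len(self.rows)} returned\n"
        if not self.rows:
            return head + "(no candidates common to both top lists)\n"
        lines = [head, f"{'Rank':<6}{'Candidate':<45}{'Score':>8}"]
        for r in self.rows:
            lines.append(f"{r['rank']:<6}{r['candidate_id']:<45}{r['score']:>8.4f}")
        return "\n".join(lines) + "\n"


def _sorted_rows(scored: list[tuple[str, float, SimilarityResult]]) -> list:
    # descending score, then ascending candidate id for determinism
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def _make_rows(ordered, n: int) -> list[dict]:
    rows = []
    for rank, (cid, score, res) in enumerate(ordered[:n], start=1):
        rows.append(
            {
                "rank": rank,
                "candidate_id": cid,
                "score": score,
                "s_teq": res.s_teq,
                "s_conc": res.s_conc,
            }
        )
    return rows


def rank_single(
    results: Sequence[SimilarityResult],
    method: str,
    n: int = DEFAULT_TOP_N,
) -> RankingTable:
    """Rank candidates by one score: ``teq``, ``concentration`` or ``weighted``."""
    if n < 1:
        raise RankingConfigError("n must be >= 1")
    if method == "teq":
        key = lambda r: r.s_teq
    elif method == "concentration":
        key = lambda r: r.s_conc
    elif method == "weighted":
        if any(r.s_combined is None for r in results):
            raise RankingConfigError(
                "weighted ranking requires combined scores; configure "
                "teq_weight and conc_weight"
            )
        key = lambda r: r.s_combined
    else:
        raise RankingConfigError(
            f"unknown single-score method {method!r}; use one of {METHODS}"
        )
    ordered = _sorted_rows([(r.candidate_id, key(r), r) for r in results])
    return RankingTable(method=method, rows=_make_rows(ordered, n), n_requested=n)


def rank_consensus(
    results: Sequence[SimilarityResult],
    n: int = DEFAULT_TOP_N,
) -> RankingTable:
    """Consensus ranking over the top-n TEQ and top-n concentration lists.

    Candidates present in both lists are ordered by the mean of their TEQ
    and concentration scores.  The table may hold fewer than n rows; a
    disjoint pair of lists yields an empty table with a warning.
    """
    if n < 1:
        raise RankingConfigError("n must be >= 1")
    top_teq = set(rank_single(results, "teq", n).candidate_ids)
    top_conc = set(rank_single(results, "concentration", n).candidate_ids)
    common = top_teq & top_conc
    if not common:
        logger.warning(
            "consensus ranking: top-%d TEQ and concentration lists share "
            "no candidates", n,
        )
    scored = [
        (r.candidate_id, (r.s_teq + r.s_conc) / 2.0, r)
        for r in results
        if r.candidate_id in common
    ]
    ordered = _sorted_rows(scored)
    return RankingTable(method="consensus", rows=_make_rows(ordered, n), n_requested=n)


def rank(
    results: Sequence[SimilarityResult],
    method: str,
    n: int = DEFAULT_TOP_N,
) -> RankingTable:
    """Dispatch to the requested ranking method."""
    if method == "consensus":
        return rank_consensus(results, n)
    return rank_single(results, method, n)
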