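"""End-to-end workflow: align -> censor -> normalize -> score -> rank.

This is the library surface behind the command line: it loads the
contaminated (target) sample, candidate source samples and an optional blank
collection, applies blank-based censoring, computes concentration and TEQ
similarity scores for every candidate and writes the ranking table plus the
all-vs-all similarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from popmatch.preprocessing import (
    DEFAULT_ADJUSTMENT_FACTOR,
    DEFAULT_CENSOR_MULTIPLIER,
    censor,
    fit_blank_stats,
    normalize,
    read_blank_collection,
)
from popmatch.profiles import (
    CongenerProfile,
    ProfileValidationError,
    WeightVector,
    align_congeners,
    read_profile,
)
from popmatch.ranking import DEFAULT_TOP_N, METHODS, RankingTable, rank
from popmatch.similarity import pairwise_matrix, score_candidates

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one ranking run."""

    target: str | Path
    candidates: list[str | Path]
    blanks: str | Path | None = None
    method: str = "teq"
    top_n: int = DEFAULT_TOP_N
    teq_weight: float | None = None
    conc_weight: float | None = None
    weights_file: str | Path | None = None
    adjustment: float | None = None          # override; else from blanks or default
    censor_multiplier: float = DEFAULT_CENSOR_MULTIPLIER
    apply_censor_to_target: bool = True
    strict_denominator: bool = False
    out_dir: str | Path | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ProfileValidationError(
                f"method must be one of {METHODS}, got {self.method!r}"
            )
        if not self.candidates:
            raise ProfileValidationError("at least one candidate is required")


def run_pipeline(config: RunConfig) -> RankingTable:
    """Execute the full workflow and write artifacts to ``config.out_dir``.

    Returns the ranking table.  Writes ``ranking.csv``, ``ranking.txt`` and
    ``similarity_matrix.csv`` when an output directory is configured; every
    censored congener value is logged.
    """
    target = read_profile(config.target)
    candidates = [read_profile(p) for p in config.candidates]

    blanks = None
    if config.blanks is not None:
        blanks = read_blank_collection(config.blanks)

    weights = None
    if config.weights_file is not None:
        weights = WeightVector.from_csv(config.weights_file)

    table, matrix = run_pipeline_profiles(
        target, candidates, blanks=blanks, weights=weights, config=config
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = table.to_frame().copy()
        for col in ("score", "s_teq", "s_conc"):
            df[col] = df[col].map(lambda v: f"{v:.4f}")
        df.insert(1, "target_id", target.sample_id)
        df.to_csv(out / "ranking.csv", index=False)
        (out / "ranking.txt").write_text(table.to_text(target.sample_id))
        matrix.round(4).to_csv(out / "similarity_matrix.csv")
        logger.info("wrote ranking and similarity matrix to %s", out)
    return table


def run_pipeline_profiles(
    target: CongenerProfile,
    candidates: list[CongenerProfile],
    blanks: list[CongenerProfile] | None = None,
    weights: WeightVector | None = None,
    config: RunConfig | None = None,
):
    """In-memory variant of :func:`run_pipeline`.

    Returns ``(ranking_table, similarity_matrix)``.  With no blank
    collection, censoring is skipped and the similarity adjustment falls
    back to the canonical default (0.2566) unless overridden.
    """
    if config is None:
        config = RunConfig(target="<memory>", candidates=["<memory>"])

    adjustment = config.adjustment
    if blanks is not None:
        aligned = align_congeners([target, *candidates, *blanks])
        target, candidates = aligned[0], aligned[1 : 1 + len(candidates)]
        stats = fit_blank_stats(
            aligned[1 + len(candidates):],
            censor_multiplier=config.censor_multiplier,
        )
        if adjustment is None:
            adjustment = stats.adjustment_factor
        candidates = [censor(c, stats) for c in candidates]
        if config.apply_censor_to_target:
            target = censor(target, stats)
    else:
        if adjustment is None:
            adjustment = DEFAULT_ADJUSTMENT_FACTOR
        aligned = align_congeners([target, *candidates])
        target, candidates = aligned[0], aligned[1:]

    target_conc = normalize(target, "concentration")
    target_teq = normalize(target, "teq")
    cand_norms = [
        (normalize(c, "concentration"), normalize(c, "teq")) for c in candidates
    ]

    results = score_candidates(
        target_conc,
        target_teq,
        cand_norms,
        weights=weights,
        adjustment=adjustment,
        teq_weight=config.teq_weight,
        conc_weight=config.conc_weight,
        strict_denominator=config.strict_denominator,
    )
    table = rank(results, config.method, config.top_n)

    all_conc = [target_conc] + [c for c, _ in cand_norms]
    matrix = pairwise_matrix(
        all_conc, weights, adjustment, config.strict_denominator
    )
    return table, matrix
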