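"""Weighted per-congener similarity between normalized congener patterns.

For normalized patterns c (contaminated) and p (potential source) over n
shared congeners, with congener weights w_i and additive adjustment a, the
score is

    S = sum_i  [ w_i (c_i + p_i + a) / sum_j w_j (c_j + p_j + a) ]
             * [ 2 / (1 + |c_i - p_i|) - 1 ]

Each bracketed agreement factor lies in [0, 1] (it is 1 when the congener
matches exactly and 0 when one pattern is at 1 and the other at 0), and the
prefactors form a convex combination, so S is in [0, 1], equals 1 exactly
for identical patterns, and is symmetric.  The adjustment a — the mean blank
congener concentration, 0.2566 by default — keeps congeners censored to zero
in both samples contributing, which is what makes two fully-censored
(low-POP) samples score 1.

The denominator here includes the weights so that the prefactors always sum
to 1 and S(x, x) = 1 under any 0/1 focus weighting; ``strict_denominator``
switches to an unweighted denominator (sum_j (c_j + p_j + a)), under which
down-weighting congeners caps the score below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from popmatch.preprocessing import DEFAULT_ADJUSTMENT_FACTOR, NormalizedProfile
from popmatch.profiles import ProfileValidationError, WeightVector

#: Additive adjustment used when no blank collection supplies one.
DEFAULT_ADJUSTMENT = DEFAULT_ADJUSTMENT_FACTOR


@dataclass
class SimilarityResult:
    """Scores for one (contaminated, candidate) pair.

    ``s_combined`` is present only when the weighted-combination method is
    requested; ``teq_weight``/``conc_weight`` record the combination used.
    """

    candidate_id: str
    s_conc: float
    s_teq: float
    s_combined: float | None = None
    teq_weight: float | None = None
    conc_weight: float | None = None


def _as_values(profile) -> np.ndarray:
    if isinstance(profile, NormalizedProfile):
        return profile.values
    return np.asarray(profile, dtype=float)


def similarity_score(
    target,
    candidate,
    weights: WeightVector | Sequence[float] | None = None,
    adjustment: float = DEFAULT_ADJUSTMENT,
    strict_denominator: bool = False,
) -> float:
    """Similarity between two normalized patterns, in [0, 1].

    ``target`` and ``candidate`` are :class:`NormalizedProfile` objects
    sharing the same congener order (or plain value arrays in [0, 1]).
    ``weights`` may be a :class:`WeightVector`, an array of per-congener
    weights, or None for unit weights.
    """
    if isinstance(target, NormalizedProfile) and isinstance(candidate, NormalizedProfile):
        if target.congeners != candidate.congeners:
            raise ProfileValidationError(
                f"congener order mismatch between {target.sample_id} "
                f"and {candidate.sample_id}"
            )
    c = _as_values(target)
    p = _as_values(candidate)
    if c.shape != p.shape:
        raise ProfileValidationError("patterns have different lengths")
    if np.any((c < 0) | (c > 1)) or np.any((p < 0) | (p > 1)):
        raise ProfileValidationError("normalized values must lie in [0, 1]")
    if not adjustment > 0:
        raise ProfileValidationError("adjustment must be > 0")

    if weights is None:
        w = np.ones_like(c)
    elif isinstance(weights, WeightVector):
        w = weights.as_array(target.congeners)
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ProfileValidationError("weights must be >= 0")
    if not np.any(w > 0):
        raise ProfileValidationError("all congener weights are zero")

    mass = c + p + adjustment
    numer = w * mass
    denom = mass.sum() if strict_denominator else numer.sum()
    agreement = 2.0 / (1.0 + np.abs(c - p)) - 1.0
    s = float(np.dot(numer / denom, agreement))
    if strict_denominator:
        # bound only guaranteed for weights in [0, 1]; return the raw value
        return s
    # the exact score lies in [0, 1]; the float dot product can overshoot
    # either bound by an ulp, so clamp
    return min(1.0, max(0.0, s))


def combined_score(
    s_teq: float,
    s_conc: float,
    teq_weight: float,
    conc_weight: float,
) -> float:
    """Weight-based combination of the TEQ and concentration scores.

    The two weights are normalized to sum to 1, so the result is a convex
    combination and stays in [0, 1].
    """
    if teq_weight < 0 or conc_weight < 0:
        raise ProfileValidationError("combination weights must be >= 0")
    total = teq_weight + conc_weight
    if total == 0:
        raise ProfileValidationError("combination weights must not both be 0")
    for name, s in (("s_teq", s_teq), ("s_conc", s_conc)):
        if not 0.0 <= s <= 1.0:
            raise ProfileValidationError(f"{name}={s} outside [0, 1]")
    return (teq_weight * s_teq + conc_weight * s_conc) / total


def score_candidates(
    target_conc: NormalizedProfile,
    target_teq: NormalizedProfile,
    candidates: Iterable[tuple[NormalizedProfile, NormalizedProfile]],
    weights: WeightVector | None = None,
    adjustment: float = DEFAULT_ADJUSTMENT,
    teq_weight: float | None = None,
    conc_weight: float | None = None,
    strict_denominator: bool = False,
) -> list[SimilarityResult]:
    """Score every candidate's (concentration, TEQ) pattern pair.

    When ``teq_weight`` and ``conc_weight`` are given, the combined score is
    attached to each result.
    """
    out = []
    for cand_conc, cand_teq in candidates:
        s_conc = similarity_score(
            target_conc, cand_conc, weights, adjustment, strict_denominator
        )
        s_teq = similarity_score(
            target_teq, cand_teq, weights, adjustment, strict_denominator
        )
        s_comb = None
        if teq_weight is not None and conc_weight is not None:
            s_comb = combined_score(s_teq, s_conc, teq_weight, conc_weight)
        out.append(
            SimilarityResult(
                candidate_id=cand_conc.sample_id,
                s_conc=s_conc,
                s_teq=s_teq,
                s_combined=s_comb,
                teq_weight=teq_weight,
                conc_weight=conc_weight,
            )
        )
    return out


def pairwise_matrix(
    profiles: Sequence[NormalizedProfile],
    weights: WeightVector | None = None,
    adjustment: float = DEFAULT_ADJUSTMENT,
    strict_denominator: bool = False,
) -> pd.DataFrame:
    """Symmetric all-vs-all similarity matrix with unit diagonal."""
    if len(profiles) < 2:
        raise ProfileValidationError("pairwise matrix needs at least 2 profiles")
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = similarity_score(
                profiles[i], profiles[j], weights, adjustment, strict_denominator
            )
            mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=ids, columns=ids)
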