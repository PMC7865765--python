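"""Blank-based censoring and max-normalization of congener profiles.

Detection noise is estimated per congener from a collection of blank
(analyte-free control) samples: the expected detection error is
mean + ``censor_multiplier`` x SD (default 2).  Sample values below that
threshold are set to zero (the congener is considered absent); values above
it have the threshold subtracted.  Censored profiles are then normalized by
their maximum value so each pattern lives on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from popmatch.profiles import (
    CongenerLookupError,
    CongenerProfile,
    ProfileValidationError,
    align_congeners,
    canonical_name,
    read_profile,
)

logger = logging.getLogger(__name__)

#: Additive smoothing constant in the similarity score when no blank
#: collection is supplied: the mean blank congener concentration reported
#: for the reference laboratory's 100 blanks.
DEFAULT_ADJUSTMENT_FACTOR = 0.2566

DEFAULT_CENSOR_MULTIPLIER = 2.0


@dataclass
class BlankStats:
    """Per-congener blank statistics and derived censoring thresholds.

    Thresholds (mean + multiplier x SD) are fit separately for concentration
    and TEQ.  ``conc_max``/``teq_max`` are the per-congener maxima over the
    blank collection (plotting reference lines).  ``adjustment_factor`` is
    the grand mean of all blank concentrations, the additive constant of the
    similarity score.
    """

    congeners: list[str]
    conc_mean: np.ndarray
    conc_sd: np.ndarray
    conc_threshold: np.ndarray
    teq_mean: np.ndarray
    teq_sd: np.ndarray
    teq_threshold: np.ndarray
    conc_max: np.ndarray
    teq_max: np.ndarray
    adjustment_factor: float
    n_blanks: int
    censor_multiplier: float = DEFAULT_CENSOR_MULTIPLIER
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.congeners = [canonical_name(c) for c in self.congeners]
        self._index = {c: i for i, c in enumerate(self.congeners)}
        if not self.adjustment_factor > 0:
            raise ProfileValidationError("adjustment_factor must be > 0")
        for name in ("conc", "teq"):
            mean = getattr(self, f"{name}_mean")
            sd = getattr(self, f"{name}_sd")
            thr = getattr(self, f"{name}_threshold")
            if np.any(sd < 0) or np.any(mean < 0) or np.any(thr < mean):
                raise ProfileValidationError(f"invalid blank {name} statistics")

    def lookup(self, congeners: Sequence[str]) -> np.ndarray:
        """Row indices for ``congeners``; raises naming any missing one."""
        idx = []
        for c in congeners:
            key = canonical_name(c)
            if key not in self._index:
                raise CongenerLookupError(f"no blank statistics for {key!r}")
            idx.append(self._index[key])
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "congener": self.congeners,
                "conc_mean": self.conc_mean,
                "conc_sd": self.conc_sd,
                "conc_threshold": self.conc_threshold,
                "conc_max": self.conc_max,
                "teq_mean": self.teq_mean,
                "teq_sd": self.teq_sd,
                "teq_threshold": self.teq_threshold,
                "teq_max": self.teq_max,
            }
        )


@dataclass
class NormalizedProfile:
    """A censored pattern divided by its maximum: values in [0, 1].

    ``kind`` records whether the pattern is the concentration or the TEQ
    fingerprint.  An all-zero profile (everything below detection) stays
    all-zero rather than dividing by zero.
    """

    sample_id: str
    congeners: list[str]
    values: np.ndarray
    kind: str = "concentration"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.congeners),):
            raise ProfileValidationError(
                f"{self.sample_id}: values length mismatch"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ProfileValidationError(
                f"{self.sample_id}: normalized values outside [0, 1]"
            )


def fit_blank_stats(
    blanks: Iterable[CongenerProfile],
    censor_multiplier: float = DEFAULT_CENSOR_MULTIPLIER,
    adjustment_factor: float | None = None,
) -> BlankStats:
    """Fit per-congener detection-error thresholds from a blank collection.

    Uses the sample SD (n-1 denominator).  The threshold is
    mean + ``censor_multiplier`` x SD, fit independently for concentration
    and TEQ.  ``adjustment_factor`` defaults to the grand mean of all blank
    concentrations over congeners and samples; pass a value to override.
    """
    blanks = list(blanks)
    if len(blanks) < 2:
        raise ProfileValidationError(
            "need at least 2 blank samples to estimate an SD"
        )
    blanks = align_congeners(blanks)
    conc = np.vstack([b.concentration for b in blanks])
    teq = np.vstack([b.teq for b in blanks])
    conc_mean = conc.mean(axis=0)
    teq_mean = teq.mean(axis=0)
    conc_sd = conc.std(axis=0, ddof=1)
    teq_sd = teq.std(axis=0, ddof=1)
    if adjustment_factor is None:
        adjustment_factor = float(conc.mean())
    return BlankStats(
        congeners=list(blanks[0].congeners),
        conc_mean=conc_mean,
        conc_sd=conc_sd,
        conc_threshold=conc_mean + censor_multiplier * conc_sd,
        teq_mean=teq_mean,
        teq_sd=teq_sd,
        teq_threshold=teq_mean + censor_multiplier * teq_sd,
        conc_max=conc.max(axis=0),
        teq_max=teq.max(axis=0),
        adjustment_factor=adjustment_factor,
        n_blanks=len(blanks),
        censor_multiplier=censor_multiplier,
    )


def read_blank_collection(source: str | Path) -> list[CongenerProfile]:
    """Load blanks from a directory of sample CSVs or one long-format CSV.

    The long format has columns ``sample_id,congener,concentration,teq``.
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(source.glob("*.csv"))
        if not paths:
            raise ProfileValidationError(f"no CSV files in {source}")
        return [read_profile(p) for p in paths]
    df = pd.read_csv(source)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"sample_id", "congener", "concentration", "teq"}
    if not required.issubset(df.columns):
        raise ProfileValidationError(
            f"{source}: long-format blank file needs columns {sorted(required)}"
        )
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(
            CongenerProfile(
                sample_id=str(sid),
                congeners=list(grp["congener"]),
                concentration=grp["concentration"].to_numpy(dtype=float),
                teq=grp["teq"].to_numpy(dtype=float),
            )
        )
    return out


def censor(profile: CongenerProfile, stats: BlankStats) -> CongenerProfile:
    """Censor one profile against blank detection-error thresholds.

    A value below its congener's threshold is set to zero (considered
    absent); a value at or above it has the threshold subtracted.
    Concentration and TEQ are censored independently against their own
    thresholds.  Applying censoring twice would subtract the detection
    error twice, so a profile may only pass through once.
    """
    if profile.censored:
        raise ProfileValidationError(
            f"{profile.sample_id}: profile is already censored"
        )
    idx = stats.lookup(profile.congeners)
    conc_thr = stats.conc_threshold[idx]
    teq_thr = stats.teq_threshold[idx]

    below_conc = profile.concentration < conc_thr
    below_teq = profile.teq < teq_thr
    new_conc = np.where(below_conc, 0.0, profile.concentration - conc_thr)
    new_teq = np.where(below_teq, 0.0, profile.teq - teq_thr)

    for i in np.flatnonzero(below_conc):
        logger.info(
            "censor %s: %s concentration %.6g < threshold %.6g -> 0",
            profile.sample_id, profile.congeners[i],
            profile.concentration[i], conc_thr[i],
        )
    for i in np.flatnonzero(below_teq):
        logger.info(
            "censor %s: %s TEQ %.6g < threshold %.6g -> 0",
            profile.sample_id, profile.congeners[i], profile.teq[i], teq_thr[i],
        )

    return CongenerProfile(
        sample_id=profile.sample_id,
        congeners=list(profile.congeners),
        concentration=new_conc,
        teq=new_teq,
        is_censored=below_conc & below_teq,
        censored=True,
    )


def _normalize_values(values: np.ndarray) -> np.ndarray:
    m = values.max() if len(values) else 0.0
    if m <= 0:
        return np.zeros_like(values, dtype=float)
    return values / m


def normalize(profile: CongenerProfile, kind: str = "concentration") -> NormalizedProfile:
    """Normalize one pattern of a profile by its maximum value.

    ``kind`` selects the concentration or TEQ vector.  The result lies in
    [0, 1] with the maximum mapped to exactly 1; a profile whose values are
    all zero (fully censored) normalizes to all zeros.
    """
    if kind == "concentration":
        values = profile.concentration
    elif kind == "teq":
        values = profile.teq
    else:
        raise ValueError(f"kind must be 'concentration' or 'teq', got {kind!r}")
    return NormalizedProfile(
        sample_id=profile.sample_id,
        congeners=list(profile.congeners),
        values=_normalize_values(values),
        kind=kind,
    )
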