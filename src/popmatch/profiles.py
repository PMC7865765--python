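"""Sample profiles, TEF tables and congener weights.

A sample is a three-column table (congener, concentration in pg/g, TEQ in
pg-TEQ/g).  Congener names are canonicalized so that lab-export spelling
variants ("2378-TCDD", "2,3,7,8 TCDD") match by name across files.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ("congener", "concentration", "teq")

#: Strings treated as non-detects in numeric cells (stored as 0.0).
NON_DETECT_TOKENS = frozenset({"", "nd", "n.d.", "n/a", "na"})

_DASHES = re.compile(r"[‐‑‒–—−]")
_WS = re.compile(r"\s+")


class ProfileFormatError(ValueError):
    """A sample file does not follow the three-column contract."""


class ProfileValidationError(ValueError):
    """A parsed profile violates an invariant (duplicates, negatives...)."""


class CongenerLookupError(KeyError):
    """A congener required by an operation is missing from a table."""


def canonical_name(name: str) -> str:
    """Canonicalize a congener name for cross-file matching.

    Uppercases, collapses internal whitespace, unifies unicode dashes to
    ``-``, and removes spaces around hyphens and commas, so that
    ``"2,3,7,8 - tcdd"`` and ``"2,3,7,8-TCDD"`` compare equal.
    """
    s = _DASHES.sub("-", str(name)).strip().upper()
    s = _WS.sub(" ", s)
    s = re.sub(r"\s*([-,])\s*", r"\1", s)
    return s


@dataclass
class CongenerProfile:
    """One sample's per-congener concentrations (pg/g) and TEQs (pg-TEQ/g).

    ``is_censored`` marks congeners zeroed by blank-based censoring;
    ``censored`` records that censoring ran at all (it must run exactly
    once — a second pass would re-subtract the detection error).
    """

    sample_id: str
    congeners: list[str]
    concentration: np.ndarray
    teq: np.ndarray
    is_censored: np.ndarray = field(default=None)  # type: ignore[assignment]
    censored: bool = False

    def __post_init__(self) -> None:
        self.congeners = [canonical_name(c) for c in self.congeners]
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.teq = np.asarray(self.teq, dtype=float)
        if self.is_censored is None:
            self.is_censored = np.zeros(len(self.congeners), dtype=bool)
        else:
            self.is_censored = np.asarray(self.is_censored, dtype=bool)
        n = len(self.congeners)
        if len(set(self.congeners)) != n:
            dupes = {c for c in self.congeners if self.congeners.count(c) > 1}
            raise ProfileValidationError(
                f"{self.sample_id}: duplicate congener names {sorted(dupes)}"
            )
        for name, vec in (("concentration", self.concentration),
                          ("teq", self.teq),
                          ("is_censored", self.is_censored)):
            if vec.shape != (n,):
                raise ProfileValidationError(
                    f"{self.sample_id}: {name} has length {vec.shape}, "
                    f"expected ({n},)"
                )
        for name, vec in (("concentration", self.concentration), ("teq", self.teq)):
            if not np.all(np.isfinite(vec)):
                raise ProfileValidationError(
                    f"{self.sample_id}: non-finite {name} values"
                )
            if np.any(vec < 0):
                bad = [self.congeners[i] for i in np.flatnonzero(vec < 0)]
                raise ProfileValidationError(
                    f"{self.sample_id}: negative {name} for {bad}"
                )

    def __len__(self) -> int:
        return len(self.congeners)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CongenerProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.congeners == other.congeners
            and np.array_equal(self.concentration, other.concentration)
            and np.array_equal(self.teq, other.teq)
        )

    def subset(self, congeners: Sequence[str]) -> "CongenerProfile":
        """Restrict to ``congeners`` in the given order."""
        index = {c: i for i, c in enumerate(self.congeners)}
        try:
            idx = [index[canonical_name(c)] for c in congeners]
        except KeyError as exc:
            raise CongenerLookupError(
                f"{self.sample_id}: congener {exc.args[0]!r} not in profile"
            ) from exc
        return CongenerProfile(
            sample_id=self.sample_id,
            congeners=[self.congeners[i] for i in idx],
            concentration=self.concentration[idx],
            teq=self.teq[idx],
            is_censored=self.is_censored[idx],
            censored=self.censored,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "congener": self.congeners,
                "concentration": self.concentration,
                "teq": self.teq,
            }
        )


class TEFTable:
    """Mapping congener -> WHO toxic equivalency factor (dimensionless > 0)."""

    def __init__(self, tefs: Mapping[str, float]):
        self._tefs = {canonical_name(k): float(v) for k, v in tefs.items()}
        bad = [k for k, v in self._tefs.items() if not v > 0]
        if bad:
            raise ProfileValidationError(f"non-positive TEF for {bad}")

    def __getitem__(self, congener: str) -> float:
        key = canonical_name(congener)
        if key not in self._tefs:
            raise CongenerLookupError(f"no TEF for congener {congener!r}")
        return self._tefs[key]

    def __contains__(self, congener: str) -> bool:
        return canonical_name(congener) in self._tefs

    def __len__(self) -> int:
        return len(self._tefs)

    def items(self):
        return self._tefs.items()

    @classmethod
    def from_csv(cls, path: str | Path) -> "TEFTable":
        """Load from a two-column CSV with header ``congener,tef``."""
        df = pd.read_csv(path)
        _require_columns(df, ("congener", "tef"), path)
        return cls(dict(zip(df["congener"], df["tef"])))

    @classmethod
    def who2005(cls) -> "TEFTable":
        """The packaged WHO-2005 TEF table (17 dioxins/furans, 12 dl-PCBs)."""
        with resources.files("popmatch.data").joinpath("who2005_tef.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls(dict(zip(df["congener"], df["tef"])))


class WeightVector:
    """Per-congener nonnegative weights; congeners not listed default to 1."""

    def __init__(self, weights: Mapping[str, float] | None = None, default: float = 1.0):
        self.default = float(default)
        self._weights = {
            canonical_name(k): float(v) for k, v in (weights or {}).items()
        }
        if any(v < 0 for v in self._weights.values()) or self.default < 0:
            raise ProfileValidationError("congener weights must be >= 0")

    def __getitem__(self, congener: str) -> float:
        return self._weights.get(canonical_name(congener), self.default)

    def as_array(self, congeners: Sequence[str]) -> np.ndarray:
        w = np.array([self[c] for c in congeners], dtype=float)
        if not np.any(w > 0):
            raise ProfileValidationError("all congener weights are zero")
        return w

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeightVector":
        """Load from a two-column CSV with header ``congener,weight``."""
        df = pd.read_csv(path)
        _require_columns(df, ("congener", "weight"), path)
        return cls(dict(zip(df["congener"], df["weight"])))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    have = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in cols if c not in have]
    if missing:
        raise ProfileFormatError(f"{path}: missing column(s) {missing}")
    df.columns = have


def _parse_value(raw, *, where: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return 0.0
    if isinstance(raw, str):
        token = raw.strip()
        if token.lower() in NON_DETECT_TOKENS:
            return 0.0
        raw = token
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ProfileFormatError(f"{where}: cannot parse {raw!r} as number") from exc


def read_profile(path: str | Path, sample_id: str | None = None) -> CongenerProfile:
    """Read a sample profile from a three-column CSV.

    The file must have a header row with columns ``congener``,
    ``concentration`` and ``teq`` (comma-separated, UTF-8).  Empty cells and
    ``ND`` parse to 0.0 (non-detect).  The congener order of the file is
    preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PROFILE_COLUMNS, path)
    conc = np.array(
        [_parse_value(v, where=f"{path} concentration row {i}")
         for i, v in enumerate(df["concentration"])]
    )
    teq = np.array(
        [_parse_value(v, where=f"{path} teq row {i}")
         for i, v in enumerate(df["teq"])]
    )
    return CongenerProfile(
        sample_id=sample_id if sample_id is not None else path.stem,
        congeners=list(df["congener"]),
        concentration=conc,
        teq=teq,
    )


def write_profile(profile: CongenerProfile, path: str | Path) -> None:
    """Write a profile as a three-column CSV with full float precision.

    ``read_profile(write_profile(p))`` reproduces ``p`` exactly: values are
    written with ``repr`` so every float round-trips bit-identically.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PROFILE_COLUMNS)
        for name, c, t in zip(profile.congeners, profile.concentration, profile.teq):
            writer.writerow([name, repr(float(c)), repr(float(t))])


def compute_teq(profile: CongenerProfile, tefs: TEFTable) -> CongenerProfile:
    """Recompute TEQs as concentration x TEF; concentrations are unchanged."""
    factors = np.array([tefs[c] for c in profile.congeners])
    return replace(profile, teq=profile.concentration * factors)


def align_congeners(profiles: Iterable[CongenerProfile]) -> list[CongenerProfile]:
    """Restrict all profiles to their common congeners, in a shared order.

    Similarity is computed over congeners shared by every sample; congeners
    absent from any sample are dropped with a warning.  The shared order is
    lexicographic by canonical name, so output is independent of input order.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ProfileValidationError("alignment needs at least 2 profiles")
    common = set(profiles[0].congeners)
    union = set(profiles[0].congeners)
    for p in profiles[1:]:
        common &= set(p.congeners)
        union |= set(p.congeners)
    if not common:
        raise ProfileValidationError("profiles share no congeners")
    dropped = sorted(union - common)
    if dropped:
        logger.warning(
            "dropping %d congener(s) not shared by all samples: %s",
            len(dropped), ", ".join(dropped),
        )
    order = sorted(common)
    return [p.subset(order) for p in profiles]
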