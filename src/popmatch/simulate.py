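"""Synthetic blank, source, duplicate and contaminated-sample generators.

Real regulatory congener data are confidential, so the pipeline is exercised
on synthetic scenarios that emulate their structure: a 20-congener panel
(7 dioxins, 10 furans, 3 dioxin-like PCBs), blanks with low positive noise
around a fraction of a pg/g, candidate source samples with distinctive
multi-congener patterns, duplicates with proportional analytical error, and
a contaminated sample formed as the true source's pattern under
multiplicative lognormal transfer noise plus blank-level background.

All generation is driven by ``numpy.random.default_rng`` from the scenario
seed, so fixtures are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from popmatch.profiles import CongenerProfile, TEFTable, write_profile

#: 20-congener panel: 7 dioxins, 10 furans, 3 dioxin-like PCBs.
DEFAULT_PANEL: tuple[str, ...] = (
    "2,3,7,8-TCDD",
    "1,2,3,7,8-PECDD",
    "1,2,3,4,7,8-HXCDD",
    "1,2,3,6,7,8-HXCDD",
    "1,2,3,7,8,9-HXCDD",
    "1,2,3,4,6,7,8-HPCDD",
    "OCDD",
    "2,3,7,8-TCDF",
    "1,2,3,7,8-PECDF",
    "2,3,4,7,8-PECDF",
    "1,2,3,4,7,8-HXCDF",
    "1,2,3,6,7,8-HXCDF",
    "1,2,3,7,8,9-HXCDF",
    "2,3,4,6,7,8-HXCDF",
    "1,2,3,4,6,7,8-HPCDF",
    "1,2,3,4,7,8,9-HPCDF",
    "OCDF",
    "PCB-77",
    "PCB-126",
    "PCB-169",
)


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic contamination scenario.

    Defaults mirror the reference laboratory setting: 100 blanks whose
    congener concentrations sit around 0.25 pg/g (so the fitted adjustment
    factor lands near the canonical 0.2566), 11 candidate source samples of
    which one is the true source, source levels two orders of magnitude
    above blank noise, 5% duplicate analytical error and 20% transfer noise.
    """

    congeners: tuple[str, ...] = DEFAULT_PANEL
    n_blanks: int = 100
    blank_mean: float = 0.25          # pg/g
    blank_sd: float = 0.05            # pg/g
    n_sources: int = 11               # candidates, incl. the true source
    source_magnitude: float = 50.0    # pg/g, max congener of a source
    pattern_sigma: float = 1.5        # log-scale spread of source patterns
    transfer_fraction: float = 0.5    # source -> food carry-over
    transfer_cv: float = 0.2          # multiplicative transfer noise
    duplicate_cv: float = 0.05        # duplicate analytical error
    seed: int = 0
    tefs: TEFTable = field(default_factory=TEFTable.who2005)

    def __post_init__(self) -> None:
        if len(set(self.congeners)) != len(self.congeners):
            raise ValueError("congener panel contains duplicates")
        if self.n_blanks < 1 or self.n_sources < 1:
            raise ValueError("counts must be >= 1")
        if min(self.transfer_cv, self.duplicate_cv) < 0:
            raise ValueError("CVs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def tef_array(self) -> np.ndarray:
        return np.array([self.tefs[c] for c in self.congeners])


def _profile(config: ScenarioConfig, sample_id: str, conc: np.ndarray) -> CongenerProfile:
    conc = np.maximum(conc, 0.0)
    return CongenerProfile(
        sample_id=sample_id,
        congeners=list(config.congeners),
        concentration=conc,
        teq=conc * config.tef_array(),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_blanks(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> list[CongenerProfile]:
    """Draw ``n_blanks`` analyte-free control samples.

    Each congener value is normal(blank_mean, blank_sd) truncated at zero;
    with noise scale 0 every blank equals the configured mean exactly.
    """
    rng = config.rng() if rng is None else rng
    n = len(config.congeners)
    out = []
    for b in range(config.n_blanks):
        conc = np.full(n, config.blank_mean) + config.blank_sd * rng.standard_normal(n)
        out.append(_profile(config, f"blank_{b:03d}", conc))
    return out


def _random_pattern(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """A distinctive multi-congener pattern scaled to source magnitude."""
    shape = rng.lognormal(mean=0.0, sigma=config.pattern_sigma, size=len(config.congeners))
    return shape / shape.max() * config.source_magnitude


def generate_duplicate(
    profile: CongenerProfile,
    cv: float,
    rng: np.random.Generator,
    sample_id: str | None = None,
) -> CongenerProfile:
    """A re-analysis of the same material with proportional analytical error."""
    factor = _lognormal_factor(rng, cv, len(profile))
    return replace(
        profile,
        sample_id=sample_id or f"{profile.sample_id}_dup",
        concentration=profile.concentration * factor,
        teq=profile.teq * factor,
    )


def generate_source_and_contaminated(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CongenerProfile, CongenerProfile, list[CongenerProfile]]:
    """One true source, the contaminated sample derived from it, and decoys.

    The contaminated sample is the source pattern scaled by the transfer
    fraction, perturbed by unit-mean lognormal noise (``transfer_cv``), plus
    blank-level background.  Decoys are independent random patterns of the
    same magnitude.  Returns ``(source, contaminated, decoys)`` where the
    candidate set is ``[source] + decoys``.
    """
    rng = config.rng() if rng is None else rng
    n = len(config.congeners)

    source_conc = _random_pattern(config, rng)
    source = _profile(config, "source_true", source_conc)

    noise = _lognormal_factor(rng, config.transfer_cv, n)
    background = np.maximum(
        np.full(n, config.blank_mean) + config.blank_sd * rng.standard_normal(n), 0.0
    )
    contaminated_conc = source_conc * config.transfer_fraction * noise + background
    contaminated = _profile(config, "contaminated", contaminated_conc)

    decoys = [
        _profile(config, f"decoy_{d:02d}", _random_pattern(config, rng))
        for d in range(config.n_sources - 1)
    ]
    return source, contaminated, decoys


def write_scenario(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full scenario (blanks, target, candidates) as sample CSVs.

    Returns the paths written: ``target``, ``blanks`` (directory) and
    ``candidates`` (directory).  Deterministic given the scenario seed.
    """
    outdir = Path(outdir)
    blank_dir = outdir / "blanks"
    cand_dir = outdir / "candidates"
    blank_dir.mkdir(parents=True, exist_ok=True)
    cand_dir.mkdir(parents=True, exist_ok=True)

    rng = config.rng()
    blanks = generate_blanks(config, rng)
    source, contaminated, decoys = generate_source_and_contaminated(config, rng)

    for b in blanks:
        write_profile(b, blank_dir / f"{b.sample_id}.csv")
    for cand in [source, *decoys]:
        write_profile(cand, cand_dir / f"{cand.sample_id}.csv")
    target_path = outdir / "contaminated.csv"
    write_profile(contaminated, target_path)
    return {"target": target_path, "blanks": blank_dir, "candidates": cand_dir}
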