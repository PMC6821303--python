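"""Synthetic fluorescence-trace generator.

Emulates the statistical structure the analysis assumes: a lag phase, a
linearly rising phase whose slope is multiplicatively retarded by adduct
tagging, an optional plateau, and additive homoscedastic Gaussian noise.
The retardation model is phenomenological — the tagged channel's slope is

    S_tagged = S_control × (1 − max_retardation × f)

where f = content × labeling_efficiency + (1 − content) × nonspecific_rate
is the effective tagged fraction of templates. Noise-free, the pair's ΔS
is therefore exactly 100 × max_retardation × f, linear in content, which
is the behaviour the assay's calibration lines rest on.

Reproducibility: every noisy draw requires a seed. Replicate wells draw
from distinct, individually reproducible substreams obtained by spawning
``numpy.random.SeedSequence(seed)``: ``simulate_pair`` spawns two children
(control first, tagged second), and ``simulate_dilution_series`` spawns
one child per (content, replicate) point in row-major order before
delegating to ``simulate_pair``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .quantify import SamplePair, pair_delta_s
from .screening import ScreenConfig
from .trace import FluorescenceTrace

__all__ = [
    "AdductSpec",
    "TraceSimConfig",
    "PHPA_5FC",
    "CPBA_5GMC",
    "LY_5CAC",
    "adduct_presets",
    "m6a_rna",
    "effective_tagged_fraction",
    "retarded_slope",
    "simulate_trace",
    "simulate_pair",
    "simulate_dilution_series",
]


@dataclass(frozen=True)
class AdductSpec:
    """One tag chemistry, reduced to its effect on polymerase extension.

    max_retardation
        Fraction of the control slope lost on a fully tagged template,
        in [0, 1).
    labeling_efficiency
        Fraction of target bases actually carrying the tag after the
        chemistry, in [0, 1].
    nonspecific_rate
        Fraction of non-target templates spuriously tagged (default 0).
    """

    name: str
    max_retardation: float
    labeling_efficiency: float = 1.0
    nonspecific_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_retardation < 1.0):
            raise ValueError("max_retardation must be in [0, 1)")
        if not (0.0 <= self.labeling_efficiency <= 1.0):
            raise ValueError("labeling_efficiency must be in [0, 1]")
        if not (0.0 <= self.nonspecific_rate <= 1.0):
            raise ValueError("nonspecific_rate must be in [0, 1]")


# Presets from the reported tag chemistries: maximal slope reductions on
# fully tagged templates and HPLC-measured labeling efficiencies.
PHPA_5FC = AdductSpec("PHPA_5fC", max_retardation=0.258, labeling_efficiency=0.648)
CPBA_5GMC = AdductSpec("CPBA_5gmC", max_retardation=0.446, labeling_efficiency=0.624)
LY_5CAC = AdductSpec("LY_5caC", max_retardation=0.533, labeling_efficiency=0.519)

# Observed per-template slope reductions for RNA templates carrying one or
# two N6-methyladenine sites (methylation pre-exists; no tagging chemistry,
# so labeling efficiency is 1).
_M6A_TOTALS = {0: 0.0, 1: 0.091, 2: 0.149}


def m6a_rna(n_sites: int = 1) -> AdductSpec:
    """Preset for RNA templates with 0, 1 or 2 N6-methyladenine sites."""
    if n_sites not in _M6A_TOTALS:
        raise ValueError("m6A presets exist for 0, 1 or 2 sites")
    return AdductSpec(
        f"m6A_RNA_{n_sites}site",
        max_retardation=_M6A_TOTALS[n_sites],
        labeling_efficiency=1.0,
    )


def adduct_presets() -> dict[str, AdductSpec]:
    """Named presets for the CLI and config files."""
    return {
        "PHPA_5fC": PHPA_5FC,
        "CPBA_5gmC": CPBA_5GMC,
        "LY_5caC": LY_5CAC,
        "m6A_RNA_1site": m6a_rna(1),
        "m6A_RNA_2site": m6a_rna(2),
    }


@dataclass(frozen=True)
class TraceSimConfig:
    """Shape and noise of a simulated well.

    Defaults emulate the genomic-sample protocol: a 30-cycle run (one
    reading per minute for 30 min), a short lag before the rise, no
    plateau within the run, and per-reading Gaussian noise of 2% of the
    control slope. ``seed`` is mandatory whenever ``noise_sd > 0``.
    """

    n_cycles: int = 30
    baseline: float = 100.0
    base_slope: float = 50.0
    lag_cycles: int = 5
    plateau_cycle: int | None = None
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be at least 3")
        if not self.base_slope > 0:
            raise ValueError("base_slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.lag_cycles < self.n_cycles):
            raise ValueError("lag_cycles must be in [0, n_cycles)")
        if self.plateau_cycle is not None and not (
            self.lag_cycles < self.plateau_cycle <= self.n_cycles
        ):
            raise ValueError("plateau_cycle must lie in (lag_cycles, n_cycles]")

    def to_dict(self) -> dict:
        return asdict(self)


def effective_tagged_fraction(adduct: AdductSpec, content: float) -> float:
    """Fraction of templates carrying the tag at a given target content.

    content × labeling_efficiency + (1 − content) × nonspecific_rate,
    clipped to [0, 1].
    """
    if not (0.0 <= content <= 1.0):
        raise ValueError("content must be in [0, 1]")
    f = (
        content * adduct.labeling_efficiency
        + (1.0 - content) * adduct.nonspecific_rate
    )
    return min(1.0, max(0.0, f))


def retarded_slope(base_slope: float, adduct: AdductSpec, content: float) -> float:
    """Linear-phase slope of the tagged channel.

    base_slope × (1 − max_retardation × effective_tagged_fraction), so the
    pair's noise-free ΔS is 100 × max_retardation × effective fraction.
    """
    if not base_slope > 0:
        raise ValueError("base_slope must be positive")
    return base_slope * (
        1.0 - adduct.max_retardation * effective_tagged_fraction(adduct, content)
    )


def _resolve_rng(config: TraceSimConfig, rng) -> np.random.Generator | None:
    if config.noise_sd == 0:
        return None
    if rng is not None:
        return rng
    if config.seed is None:
        raise ValueError("a seed is mandatory when noise_sd > 0")
    return np.random.default_rng(config.seed)


def simulate_trace(
    config: TraceSimConfig,
    slope: float | None = None,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> FluorescenceTrace:
    """One well: lag → linear rise at ``slope`` → optional plateau, + noise.

    intensity(c) = baseline + slope × max(0, min(c, plateau) − lag) + ε_c
    with ε_c i.i.d. Gaussian(0, noise_sd²). ``slope`` defaults to the
    config's base_slope. Deterministic given the seed (or an explicit
    ``rng`` substream).
    """
    if slope is None:
        slope = config.base_slope
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    rng = _resolve_rng(config, rng)
    cycles = np.arange(1, config.n_cycles + 1)
    ceiling = (
        np.minimum(cycles, config.plateau_cycle)
        if config.plateau_cycle is not None
        else cycles
    )
    rise = np.maximum(0, ceiling - config.lag_cycles)
    values = config.baseline + slope * rise.astype(np.float64)
    if rng is not None:
        values = values + rng.normal(0.0, config.noise_sd, size=len(values))
    return FluorescenceTrace(cycles, values, label=label)


def simulate_pair(
    config: TraceSimConfig,
    adduct: AdductSpec,
    content: float,
    seed_seq: np.random.SeedSequence | None = None,
    label: str = "",
) -> SamplePair:
    """Matched control/tagged wells sharing lag, plateau and baseline.

    The two wells draw independent noise from substreams spawned off the
    seed (control first, tagged second).
    """
    if config.noise_sd > 0:
        if seed_seq is None:
            if config.seed is None:
                raise ValueError("a seed is mandatory when noise_sd > 0")
            seed_seq = np.random.SeedSequence(config.seed)
        control_rng, tagged_rng = map(np.random.default_rng, seed_seq.spawn(2))
    else:
        control_rng = tagged_rng = None
    control = simulate_trace(
        config, config.base_slope, control_rng, label=f"{label}B"
    )
    tagged = simulate_trace(
        config,
        retarded_slope(config.base_slope, adduct, content),
        tagged_rng,
        label=f"{label}A",
    )
    return SamplePair(tagged=tagged, control=control, label=label)


def simulate_dilution_series(
    config: TraceSimConfig,
    adduct: AdductSpec,
    contents,
    replicates: int = 3,
    seed: int | None = None,
    screen_config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Calibration points from a simulated dilution series.

    One (content, delta_s) row per content × replicate, each from an
    independent simulated pair screened for its credible slopes; the
    result feeds :func:`pria.calibration.fit_calibration` directly.
    """
    contents = list(contents)
    if not contents:
        raise ValueError("contents must be non-empty")
    if any(not (0.0 <= c <= 1.0) for c in contents):
        raise ValueError("contents must lie in [0, 1]")
    if seed is None:
        seed = config.seed
    if config.noise_sd > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sd > 0")
    streams = (
        np.random.SeedSequence(seed).spawn(len(contents) * replicates)
        if config.noise_sd > 0
        else [None] * (len(contents) * replicates)
    )
    rows = []
    k = 0
    for content in contents:
        for rep in range(replicates):
            pair = simulate_pair(
                config,
                adduct,
                content,
                seed_seq=streams[k],
                label=f"m{content:g}r{rep}",
            )
            rows.append((content, pair_delta_s(pair, screen_config)))
            k += 1
    return pd.DataFrame(rows, columns=["content", "delta_s"])
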