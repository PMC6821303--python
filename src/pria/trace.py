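"""Real-time fluorescence trace container.

A trace is one well's readout from an isothermal replication–scission
amplification reaction: fluorescence intensity sampled once per cycle
(one cycle = one sampling interval, typically one minute) on an RT-qPCR
instrument or microplate reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluorescenceTrace"]


@dataclass(frozen=True, eq=False)
class FluorescenceTrace:
    """One well's fluorescence-vs-cycle time series.

    Parameters
    ----------
    cycles
        1-based sampling-cycle indices, strictly increasing with unit step.
    intensities
        Fluorescence readings in arbitrary units, one per cycle; all finite.
    sampling_interval
        Minutes per cycle (default 1, the instrument cadence).
    label
        Free-text well/sample identifier.
    """

    cycles: np.ndarray
    intensities: np.ndarray
    sampling_interval: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=np.int64)
        intensities = np.asarray(self.intensities, dtype=np.float64)
        if cycles.ndim != 1 or intensities.ndim != 1:
            raise ValueError("cycles and intensities must be 1-D")
        if len(cycles) != len(intensities):
            raise ValueError(
                f"length mismatch: {len(cycles)} cycles vs "
                f"{len(intensities)} intensities"
            )
        if len(cycles) < 3:
            raise ValueError("a trace needs at least 3 points")
        if not np.all(np.diff(cycles) == 1):
            raise ValueError("cycles must be strictly increasing with unit step")
        if not np.all(np.isfinite(intensities)):
            bad = int(cycles[~np.isfinite(intensities)][0])
            raise ValueError(f"non-finite intensity at cycle {bad}")
        if not (self.sampling_interval > 0):
            raise ValueError("sampling_interval must be positive")
        cycles.setflags(write=False)
        intensities.setflags(write=False)
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "intensities", intensities)

    @classmethod
    def from_intensities(
        cls,
        intensities,
        start_cycle: int = 1,
        sampling_interval: float = 1.0,
        label: str = "",
    ) -> "FluorescenceTrace":
        """Build a trace from raw readings with consecutive cycle indices."""
        intensities = np.asarray(intensities, dtype=np.float64)
        cycles = np.arange(start_cycle, start_cycle + len(intensities))
        return cls(cycles, intensities, sampling_interval, label)

    def __len__(self) -> int:
        return len(self.cycles)

    def position(self, cycle: int) -> int:
        """Array position of a cycle index; IndexError if outside the trace."""
        first = int(self.cycles[0])
        pos = int(cycle) - first
        if pos < 0 or pos >= len(self.cycles):
            raise IndexError(
                f"cycle {cycle} outside trace range "
                f"[{first}, {int(self.cycles[-1])}]"
            )
        return pos

    def window(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Cycle and intensity arrays for the inclusive window [i, j]."""
        if i >= j:
            raise ValueError(f"window start {i} must be below end {j}")
        p, q = self.position(i), self.position(j)
        return (
            self.cycles[p : q + 1].astype(np.float64),
            self.intensities[p : q + 1],
        )
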