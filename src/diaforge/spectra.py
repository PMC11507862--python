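"""In-memory containers for centroided DIA runs.

MS2 scans carry their isolation window and acquired scan m/z range; a run
indexes its MS2 scans per isolation window so chromatogram extraction and
apex lookup are O(log n) in the number of scans.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

WindowKey = tuple[float, float]


@dataclass
class Spectrum:
    """One centroided scan. ``rt`` is in minutes; peaks sorted by m/z."""

    scan_id: str
    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    isolation_low: float | None = None
    isolation_high: float | None = None
    scan_min: float | None = None
    scan_max: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.ms_level == 2:
            if self.isolation_low is None or self.isolation_high is None:
                raise ValueError(f"MS2 scan {self.scan_id} lacks an isolation window")
            if not self.isolation_low < self.isolation_high:
                raise ValueError(
                    f"scan {self.scan_id}: isolation_low must be < isolation_high"
                )

    @property
    def window(self) -> WindowKey | None:
        if self.ms_level != 2:
            return None
        return (round(self.isolation_low, 4), round(self.isolation_high, 4))


@dataclass
class RunData:
    """All spectra of one run, rt-ordered, with a per-window MS2 index."""

    run_id: str
    spectra: list[Spectrum] = field(default_factory=list)
    ms2_by_window: dict[WindowKey, list[Spectrum]] = field(default_factory=dict)

    @classmethod
    def from_spectra(cls, run_id: str, spectra: list[Spectrum]) -> "RunData":
        spectra = sorted(spectra, key=lambda s: s.rt)
        index: dict[WindowKey, list[Spectrum]] = {}
        for s in spectra:
            if s.ms_level == 2:
                index.setdefault(s.window, []).append(s)
        return cls(run_id=run_id, spectra=spectra, ms2_by_window=index)

    def windows_covering(self, mz: float) -> list[WindowKey]:
        """Isolation windows whose [low, high) interval contains ``mz``."""
        return [w for w in self.ms2_by_window if w[0] <= mz < w[1]]

    def ms2_in_rt_range(
        self, window: WindowKey, rt_start: float, rt_stop: float
    ) -> list[Spectrum]:
        scans = self.ms2_by_window.get(window, [])
        rts = [s.rt for s in scans]
        lo = bisect_left(rts, rt_start)
        out = []
        for s in scans[lo:]:
            if s.rt > rt_stop:
                break
            out.append(s)
        return out

    @property
    def max_ms2_rt(self) -> float:
        rts = [s.rt for s in self.spectra if s.ms_level == 2]
        if not rts:
            raise ValueError(f"run {self.run_id} has no MS2 spectra")
        return max(rts)

    def scan_range(self) -> tuple[float, float]:
        """Widest acquired MS2 scan m/z range seen in the run."""
        mins = [s.scan_min for s in self.spectra if s.ms_level == 2 and s.scan_min]
        maxs = [s.scan_max for s in self.spectra if s.ms_level == 2 and s.scan_max]
        if not mins or not maxs:
            raise ValueError("no MS2 scan ranges recorded")
        return (min(mins), max(maxs))
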