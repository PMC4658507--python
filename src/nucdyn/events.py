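"""Event detection and temporal-coincidence scoring.

Detachment of a DNA segment is operationalised as the per-frame minimum
heavy-atom distance between the segment and the protein core exceeding a
threshold for a minimum number of consecutive frames, with hysteresis on the
way back down. Coincidence between two event series counts how many episodes
of A have a B episode starting within +/- a frame window of the A start.
All thresholds are reported alongside the results; none are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (MolecularSystem, NucleosomeAnnotation, TrajectorySegment,
                   select_sites)
from .contacts import min_distance_series
from .geometry import DistanceSeries

__all__ = [
    "EventSeries", "CoincidenceReport",
    "episodes_from_distance", "segment_detachment_series",
    "residue_site_distance_series", "event_coincidence",
    "threshold_events",
]


@dataclass
class EventSeries:
    label: str
    active: np.ndarray                     # (n_frames,) bool
    episodes: list[tuple[int, int]]        # half-open [start, end)
    definition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        prev_end = -1
        for s, e in self.episodes:
            if not (0 <= s < e <= len(self.active)):
                raise ValueError(f"episode [{s}, {e}) out of bounds")
            if s <= prev_end:
                raise ValueError("episodes must be sorted and non-overlapping")
            prev_end = e
        rebuilt = np.zeros_like(self.active)
        for s, e in self.episodes:
            rebuilt[s:e] = True
        if not np.array_equal(rebuilt, self.active):
            raise ValueError("episodes inconsistent with active flags")

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.episodes], dtype=int)

    @classmethod
    def from_active(cls, label: str, active: np.ndarray,
                    definition: dict | None = None) -> "EventSeries":
        active = np.asarray(active, dtype=bool)
        episodes: list[tuple[int, int]] = []
        i = 0
        n = len(active)
        while i < n:
            if active[i]:
                j = i
                while j < n and active[j]:
                    j += 1
                episodes.append((i, j))
                i = j
            else:
                i += 1
        return cls(label=label, active=active, episodes=episodes,
                   definition=definition or {})

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tactive\n")
            for i, a in enumerate(self.active):
                fh.write(f"{i}\t{int(a)}\n")


@dataclass
class CoincidenceReport:
    label_a: str
    label_b: str
    window: int
    n_a: int
    n_b: int
    coincident: int
    rate: float | None          # None when A has no episodes
    lags: list[int]             # signed frame offsets, one per matched A episode

    @property
    def median_lag(self) -> float | None:
        return float(np.median(self.lags)) if self.lags else None

    def to_dict(self) -> dict:
        return {"label_a": self.label_a, "label_b": self.label_b,
                "window": self.window, "n_a": self.n_a, "n_b": self.n_b,
                "coincident": self.coincident, "rate": self.rate,
                "lags": self.lags, "median_lag": self.median_lag}


def episodes_from_distance(distance: np.ndarray, threshold: float,
                           min_duration: int = 1,
                           hysteresis: float = 1.0) -> np.ndarray:
    """Active-flag array from a distance series with hysteresis.

    A run of >= ``min_duration`` consecutive frames above ``threshold``
    activates an episode at the run's first frame; the episode persists while
    the distance stays >= ``threshold - hysteresis`` and ends when it drops
    below that.
    """
    d = np.asarray(distance, dtype=float)
    n = len(d)
    active = np.zeros(n, dtype=bool)
    lo = threshold - hysteresis
    i = 0
    while i < n:
        if d[i] > threshold:
            j = i
            while j < n and d[j] > threshold:
                j += 1
            if j - i >= min_duration:
                k = j
                while k < n and d[k] >= lo:
                    k += 1
                active[i:k] = True
                i = k
            else:
                i = j
        else:
            i += 1
    return active


def segment_detachment_series(traj: TrajectorySegment,
                              system: MolecularSystem,
                              annotation: NucleosomeAnnotation,
                              bp_range: tuple[int, int],
                              core_selection: np.ndarray | None = None,
                              threshold: float = 8.0,
                              min_duration: int | None = None,
                              hysteresis: float = 1.0
                              ) -> tuple[EventSeries, DistanceSeries]:
    """Detachment events of a basepair range from the protein core.

    ``bp_range`` is inclusive on both ends. ``core_selection`` defaults to all
    protein heavy atoms. ``min_duration`` defaults to 1% of window frames
    (at least 1). Returns the event series and the underlying per-frame
    minimum-distance series.
    """
    b0, b1 = bp_range
    if b1 < b0:
        raise ValueError(f"empty basepair range {bp_range}")
    sel = select_sites(system, annotation, atom_class="basepair",
                       bp=list(range(b0, b1 + 1)), pooled=True)
    bp_atoms = sel.groups[0]
    if core_selection is None:
        heavy = system.heavy_mask()
        protein = np.zeros(system.n_atoms, dtype=bool)
        for chain, role in annotation.chain_roles.items():
            if not role.startswith("DNA"):
                protein[system.chain_atoms(chain)] = True
        core_selection = np.flatnonzero(heavy & protein)
    core_selection = np.asarray(core_selection, dtype=int)
    if core_selection.size == 0:
        raise ValueError("empty core selection")
    coords = traj.window_coords()
    values = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        tree = cKDTree(coords[f, core_selection])
        dmin, _ = tree.query(coords[f, bp_atoms], k=1)
        values[f] = dmin.min()
    if min_duration is None:
        min_duration = max(1, coords.shape[0] // 100)
    active = episodes_from_distance(values, threshold, min_duration, hysteresis)
    definition = {"bp_range": [int(b0), int(b1)], "threshold_A": threshold,
                  "min_duration_frames": int(min_duration),
                  "hysteresis_A": hysteresis}
    series = EventSeries.from_active(
        f"detachment bp{b0:+d}..bp{b1:+d}", active, definition)
    dist = DistanceSeries(label=series.label + " min distance", values=values,
                          times=traj.window_times())
    return series, dist


def residue_site_distance_series(traj: TrajectorySegment,
                                 system: MolecularSystem,
                                 annotation: NucleosomeAnnotation,
                                 residue: tuple[str, int],
                                 target_bp: int | None = None,
                                 target_residue: tuple[str, int] | None = None,
                                 atom_class: str = "heavy") -> DistanceSeries:
    """Per-frame minimum distance from a residue to a basepair or residue."""
    if (target_bp is None) == (target_residue is None):
        raise ValueError("give exactly one of target_bp / target_residue")
    if target_bp is not None:
        sel = select_sites(system, annotation, atom_class="basepair",
                           bp=[target_bp], pooled=True)
        series = min_distance_series(traj, system, residue, None,
                                     atom_class=atom_class,
                                     atoms_b=sel.groups[0])
        series.label = f"min({residue[0]}:{residue[1]}, bp{target_bp:+d})"
        return series
    return min_distance_series(traj, system, residue, target_residue,
                               atom_class=atom_class)


def event_coincidence(series_a: EventSeries, series_b: EventSeries,
                      window: int | None = None) -> CoincidenceReport:
    """Count A episodes matched by a B episode start within +/- ``window``
    frames of the A start.

    ``window`` defaults to 2% of the series length (at least 1). The signed
    lag of the nearest matching B start is recorded per matched A episode;
    with no A episodes the rate is undefined (None), not 0.
    """
    if len(series_a.active) != len(series_b.active):
        raise ValueError("event series have different frame counts")
    if window is None:
        window = max(1, len(series_a.active) // 50)
    starts_a = series_a.starts
    starts_b = series_b.starts
    lags: list[int] = []
    coincident = 0
    for sa in starts_a:
        if starts_b.size == 0:
            continue
        offsets = starts_b - sa
        ok = np.abs(offsets) <= window
        if np.any(ok):
            coincident += 1
            cand = offsets[ok]
            lags.append(int(cand[np.argmin(np.abs(cand))]))
    rate = (coincident / len(starts_a)) if len(starts_a) else None
    return CoincidenceReport(label_a=series_a.label, label_b=series_b.label,
                             window=int(window), n_a=len(starts_a),
                             n_b=len(starts_b), coincident=coincident,
                             rate=rate, lags=lags)


def threshold_events(series: DistanceSeries, label: str,
                     cutoff: float = 3.6, below: bool = True,
                     min_duration: int = 1) -> EventSeries:
    """Contact-style events by thresholding a distance series.

    ``below=True`` marks engagement (distance < cutoff); ``below=False``
    marks separation (distance > cutoff). No hysteresis is applied.
    """
    raw = series.values < cutoff if below else series.values > cutoff
    if min_duration > 1:
        active = np.zeros_like(raw)
        i = 0
        n = len(raw)
        while i < n:
            if raw[i]:
                j = i
                while j < n and raw[j]:
                    j += 1
                if j - i >= min_duration:
                    active[i:j] = True
                i = j
            else:
                i += 1
    else:
        active = raw
    return EventSeries.from_active(label, active, {
        "cutoff_A": cutoff, "below": below, "min_duration": min_duration})
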