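"""Enumeration of the detector pool.

A detector is an atomic condition "between t0 and t1, the average abundance
(or the slope of the abundance) of taxon j is above/below a threshold".  The
pool enumerates every admissible time window (unions of consecutive basic
windows in which every subject was sampled often enough), every retained
taxon, and data-driven thresholds placed between the sorted per-subject
window statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .preprocess import Cohort

__all__ = [
    "TimeWindow",
    "PoolParams",
    "DetectorPool",
    "enumerate_basic_windows",
    "enumerate_valid_windows",
    "window_average",
    "window_slope",
    "make_thresholds",
    "build_pool",
]

AVERAGE, SLOPE = 0, 1
KIND_NAMES = {AVERAGE: "average", SLOPE: "slope"}


@dataclass(frozen=True)
class TimeWindow:
    """A union of ``n_basic`` consecutive basic windows starting at index i0."""

    t0: float
    t1: float
    i0: int
    n_basic: int

    @property
    def length(self):
        return self.t1 - self.t0

    def overlaps(self, other: "TimeWindow") -> bool:
        return min(self.t1, other.t1) > max(self.t0, other.t0)


@dataclass
class PoolParams:
    """Pool construction parameters.

    ``n_w``: number of equal basic windows tiling the study.
    ``t_min``/``t_max``: admissible window lengths, t_min < length <= t_max
    (``t_max`` defaults to the full study duration).
    ``n_theta``: target number of threshold clusters per (taxon, window, kind).
    """

    n_w: int = 10
    t_min: float = 0.0
    t_max: float | None = None
    n_theta: int = 40

    def __post_init__(self):
        if self.n_w < 1:
            raise ValueError("n_w must be >= 1")
        if self.n_theta < 2:
            raise ValueError("n_theta must be >= 2")
        if self.t_min < 0:
            raise ValueError("t_min must be >= 0")
        if self.t_max is not None and self.t_max <= self.t_min:
            raise ValueError("need t_min < t_max")


def enumerate_basic_windows(t_start, t_end, n_w) -> list[TimeWindow]:
    """Tile [t_start, t_end] with n_w equal contiguous basic windows."""
    if n_w < 1:
        raise ValueError("n_w must be >= 1")
    if not t_end > t_start:
        raise ValueError("study duration must be positive")
    edges = np.linspace(t_start, t_end, n_w + 1)
    return [
        TimeWindow(float(edges[i]), float(edges[i + 1]), i, 1) for i in range(n_w)
    ]


def _samples_in(times, w: TimeWindow):
    return (times >= w.t0) & (times <= w.t1)


def enumerate_valid_windows(
    cohort: Cohort, params: PoolParams, min_samples_per_subject: int = 1
) -> list[TimeWindow]:
    """All unions of consecutive basic windows with admissible length in which
    every subject has >= ``min_samples_per_subject`` samples (for slopes, the
    in-window sample times must also not all coincide)."""
    basic = enumerate_basic_windows(cohort.t_start, cohort.t_end, params.n_w)
    t_max = params.t_max if params.t_max is not None else cohort.duration
    out = []
    for n_basic in range(1, params.n_w + 1):
        for i0 in range(params.n_w - n_basic + 1):
            w = TimeWindow(basic[i0].t0, basic[i0 + n_basic - 1].t1, i0, n_basic)
            if not (params.t_min < w.length <= t_max + 1e-9 * cohort.duration):
                continue
            ok = True
            for s in cohort.subjects:
                ts = cohort.times[s]
                inside = _samples_in(ts, w)
                if inside.sum() < min_samples_per_subject:
                    ok = False
                    break
                if min_samples_per_subject >= 2 and len(set(ts[inside])) < 2:
                    ok = False
                    break
            if ok:
                out.append(w)
    return out


def window_average(times, values, window: TimeWindow) -> float:
    """Arithmetic mean of the observations falling inside the window."""
    mask = _samples_in(np.asarray(times), window)
    if not mask.any():
        raise ValueError(f"no samples in window [{window.t0}, {window.t1}]")
    return float(np.mean(np.asarray(values)[mask]))


def window_slope(times, values, window: TimeWindow) -> float:
    """Ordinary least-squares slope of abundance against time in the window."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = _samples_in(times, window)
    t = times[mask]
    x = values[mask]
    if t.size < 2:
        raise ValueError(f"need >= 2 samples in window [{window.t0}, {window.t1}]")
    tc = t - t.mean()
    denom = (tc**2).sum()
    if denom == 0:
        raise ValueError("all in-window samples at identical time")
    return float((tc * (x - x.mean())).sum() / denom)


def _cluster_1d_average_linkage(values: np.ndarray, n_clusters: int) -> list[np.ndarray]:
    """Agglomerative average-linkage clustering of sorted 1-D values.

    With contiguous 1-D clusters the average-linkage distance between two
    clusters equals the difference of their means, so the closest pair is
    always adjacent; ties are broken by merging the leftmost pair.
    """
    clusters = [[v] for v in values]
    while len(clusters) > n_clusters:
        means = [np.mean(c) for c in clusters]
        gaps = np.array([means[i + 1] - means[i] for i in range(len(clusters) - 1)])
        i = int(np.argmin(gaps))  # argmin takes the first (leftmost) minimum
        clusters[i : i + 2] = [clusters[i] + clusters[i + 1]]
    return [np.asarray(c) for c in clusters]


def make_thresholds(values, n_theta: int) -> np.ndarray:
    """Thresholds between sorted per-subject window statistics.

    With fewer than ``n_theta + 1`` values: midpoints of consecutive values.
    Otherwise the values are clustered into ``n_theta`` groups (1-D
    average-linkage) and thresholds are midpoints between the boundary values
    of adjacent clusters.  Duplicate thresholds are collapsed; all-equal
    values yield no thresholds.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty value list")
    if values[0] == values[-1]:
        return np.empty(0)
    if values.size < n_theta + 1:
        mids = (values[:-1] + values[1:]) / 2.0
    else:
        clusters = _cluster_1d_average_linkage(values, n_theta)
        mids = np.array([
            (clusters[i][-1] + clusters[i + 1][0]) / 2.0
            for i in range(len(clusters) - 1)
        ])
    return np.unique(mids)


class DetectorPool:
    """Columnar pool of detectors over a fixed cohort.

    Detectors are grouped into "combos" (taxon, window, kind) sharing the
    per-subject statistic; detector truth for the training subjects is
    precomputed.  The pool order is deterministic given (cohort, params).
    """

    def __init__(self, cohort, params, combos, stats, det_combo, det_threshold,
                 det_above, avg_windows, slope_windows):
        self.cohort = cohort
        self.params = params
        self.subjects = list(cohort.subjects)
        self.taxa = list(cohort.taxa)
        self.combos = combos  # list of (taxon_idx, TimeWindow, kind)
        self.stats = stats  # (n_combos, n_subjects)
        self.det_combo = det_combo
        self.det_threshold = det_threshold
        self.det_above = det_above
        self.avg_windows = avg_windows
        self.slope_windows = slope_windows
        self.basic_windows = enumerate_basic_windows(
            cohort.t_start, cohort.t_end, params.n_w
        )
        n_det = len(det_combo)
        combo_taxon = np.array([c[0] for c in combos], dtype=np.int64)
        combo_dur = np.array([c[1].n_basic for c in combos], dtype=np.int64)
        self.det_taxon = combo_taxon[det_combo]
        det_dur = combo_dur[det_combo]
        self.durations = np.unique(det_dur)
        dur_index = {d: i for i, d in enumerate(self.durations)}
        self.det_dur_idx = np.array([dur_index[d] for d in det_dur], dtype=np.int64)
        # categories: (duration index, taxon index)
        cat_key = self.det_dur_idx * len(self.taxa) + self.det_taxon
        self.cat_of_det = np.empty(n_det, dtype=np.int64)
        uniq, inverse = np.unique(cat_key, return_inverse=True)
        self.cat_of_det = inverse
        self.n_cats = len(uniq)
        self.cat_dur_idx = uniq // len(self.taxa)
        self.cat_taxon = uniq % len(self.taxa)
        self.cat_count = np.bincount(inverse, minlength=self.n_cats)
        self.cat_members = [
            np.nonzero(inverse == c)[0] for c in range(self.n_cats)
        ]
        # truth matrix over training subjects
        stat = self.stats[det_combo, :]
        self.truth = np.where(
            det_above[:, None], stat > det_threshold[:, None],
            stat < det_threshold[:, None],
        )

    @property
    def n_detectors(self):
        return len(self.det_combo)

    @property
    def n_subjects(self):
        return len(self.subjects)

    def describe(self, i: int) -> dict:
        taxon_idx, window, kind = self.combos[self.det_combo[i]]
        return {
            "taxon": self.taxa[taxon_idx],
            "t0": window.t0,
            "t1": window.t1,
            "kind": KIND_NAMES[kind],
            "direction": "above" if self.det_above[i] else "below",
            "threshold": float(self.det_threshold[i]),
        }

    def window_of(self, i: int) -> TimeWindow:
        return self.combos[self.det_combo[i]][1]

    def stats_for_subject(self, times, abundance) -> np.ndarray:
        """Per-combo statistics for a new subject (rows follow self.taxa).

        Raises ValueError naming the windows a subject cannot cover.
        """
        times = np.asarray(times, dtype=float)
        out = np.empty(len(self.combos))
        missing = []
        for ci, (taxon_idx, window, kind) in enumerate(self.combos):
            try:
                if kind == AVERAGE:
                    out[ci] = window_average(times, abundance[taxon_idx], window)
                else:
                    out[ci] = window_slope(times, abundance[taxon_idx], window)
            except ValueError:
                missing.append((window.t0, window.t1))
                out[ci] = np.nan
        if missing:
            uniq = sorted(set(missing))
            raise ValueError(f"subject lacks required samples in windows {uniq}")
        return out

    def truth_for_stats(self, combo_stats: np.ndarray) -> np.ndarray:
        """Detector truth vector given per-combo statistics for one subject."""
        stat = combo_stats[self.det_combo]
        return np.where(
            self.det_above, stat > self.det_threshold, stat < self.det_threshold
        )

    def subset(self, detector_indices) -> "DetectorPool":
        """A pool restricted to the given detectors (used for miniature,
        exhaustively enumerable problems)."""
        idx = np.asarray(detector_indices, dtype=np.int64)
        return DetectorPool(
            self.cohort, self.params, self.combos, self.stats,
            self.det_combo[idx], self.det_threshold[idx], self.det_above[idx],
            self.avg_windows, self.slope_windows,
        )

    def dump_jsonl(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            for i in range(self.n_detectors):
                fh.write(json.dumps(self.describe(i), sort_keys=True) + "\n")


def build_pool(cohort: Cohort, params: PoolParams | None = None) -> DetectorPool:
    """Enumerate the full detector pool for a preprocessed cohort."""
    params = params or PoolParams()
    avg_windows = enumerate_valid_windows(cohort, params, 1)
    slope_windows = enumerate_valid_windows(cohort, params, 2)
    combos = []
    stats_rows = []
    det_combo, det_threshold, det_above = [], [], []
    for kind, windows in ((AVERAGE, avg_windows), (SLOPE, slope_windows)):
        for window in sorted(windows, key=lambda w: (w.n_basic, w.i0)):
            # per-window statistics for all taxa x subjects at once
            cols = []
            for s in cohort.subjects:
                ts = cohort.times[s]
                mask = _samples_in(ts, window)
                block = cohort.abundance[s][:, mask]
                if kind == AVERAGE:
                    cols.append(block.mean(axis=1))
                else:
                    t = ts[mask]
                    tc = t - t.mean()
                    denom = (tc**2).sum()
                    cols.append((block - block.mean(axis=1, keepdims=True)) @ tc / denom)
            window_stats = np.column_stack(cols)
            for taxon_idx, taxon in enumerate(cohort.taxa):
                values = window_stats[taxon_idx]
                thresholds = make_thresholds(values, params.n_theta)
                if thresholds.size == 0:
                    continue
                ci = len(combos)
                combos.append((taxon_idx, window, kind))
                stats_rows.append(values)
                for theta in thresholds:
                    for above in (True, False):
                        det_combo.append(ci)
                        det_threshold.append(float(theta))
                        det_above.append(above)
    if not det_combo:
        raise ValueError(
            "empty detector pool; consider reducing t_min, increasing t_max, "
            "or relaxing the taxon filters"
        )
    return DetectorPool(
        cohort, params, combos,
        np.vstack(stats_rows),
        np.asarray(det_combo, dtype=np.int64),
        np.asarray(det_threshold, dtype=float),
        np.asarray(det_above, dtype=bool),
        avg_windows, slope_windows,
    )
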