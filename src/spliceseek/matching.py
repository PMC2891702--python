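"""MS1 time-course screening: matching, peak detection, kinetic filtering.

The screen proceeds in strictly narrowing stages:

1. theoretical cluster representatives are matched against every observed
   centroid within an m/z tolerance;
2. for each matched cluster an extracted-ion chromatogram (XIC) is built
   and significant peaks (apex over median-noise ratio above a threshold)
   are located, yielding (m/z, RT) pairs;
3. for every pair a kinetic trace of intensity versus digestion time is
   assembled (starting at t = 0) and filtered: the t = 0 intensity must be
   below an absolute ceiling and the series must rise monotonically to its
   maximum — optionally followed by a monotone decline when product
   re-degradation ("re-entry") is allowed by the assay;
4. surviving (m/z, RT) pairs carry the digestion time of maximal signal
   (t_max) and are grouped by it into an inclusion list for targeted
   MS/MS, each group split into subgroups of bounded size (one targeted
   run each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakObservation",
    "KineticTrace",
    "FilterParams",
    "CandidateRecord",
    "InclusionList",
    "match_clusters",
    "extract_xic",
    "detect_peaks",
    "build_traces",
    "kinetic_filter",
    "group_candidates",
    "compare_rt",
    "write_inclusion_csv",
]


@dataclass(frozen=True)
class PeakObservation:
    mz: float
    rt_min: float
    intensity: float
    digestion_time: float

    def __post_init__(self) -> None:
        if self.intensity < 0 or self.rt_min < 0:
            raise ValueError("intensity and retention time must be non-negative")


@dataclass(frozen=True)
class FilterParams:
    max_t0_intensity: float = 1e7   # absolute ceiling on the t = 0 signal
    delta: float = 2.0              # peak signal-to-noise threshold
    mz_tolerance: float = 0.5       # Da, instrument mass accuracy
    epsilon: float = 0.05           # relative tolerance on monotonicity
    allow_reentry: bool = True
    rt_window: float = 1.0          # minutes, half-width around a peak apex

    def __post_init__(self) -> None:
        if min(self.max_t0_intensity, self.delta, self.mz_tolerance, self.rt_window) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")


@dataclass(frozen=True)
class KineticTrace:
    cluster_id: int
    cluster_mz: float
    rt_apex: float
    samples: tuple[tuple[float, float], ...]   # (digestion_time, intensity), t ascending

    def __post_init__(self) -> None:
        times = [t for t, _ in self.samples]
        if times and times[0] != 0:
            raise ValueError("kinetic trace must start at digestion time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("digestion times must be strictly increasing")


@dataclass(frozen=True)
class CandidateRecord:
    cluster_id: int
    cluster_mz: float
    rt_min: float
    t_max: float
    intensity_max: float


@dataclass
class InclusionList:
    """t_max-keyed candidate groups, split into bounded subgroups."""

    entries: list[dict]            # mz, rt, t_max, group_id, subgroup_id
    n_groups: int
    n_subgroups: int
    d_max: int


def match_clusters(
    cluster_mz: Sequence[float],
    peaks: pd.DataFrame,
    tolerance: float,
) -> list[int]:
    """Indices of clusters with at least one observation within ±tolerance."""
    if peaks.empty:
        raise ValueError("no peak observations to match against")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    observed = np.sort(peaks["mz"].to_numpy())
    matched = []
    for ci, mz in enumerate(cluster_mz):
        lo = np.searchsorted(observed, mz - tolerance, side="left")
        hi = np.searchsorted(observed, mz + tolerance, side="right")
        if hi > lo:
            matched.append(ci)
    return matched


def extract_xic(
    peaks: pd.DataFrame,
    mz: float,
    tolerance: float,
    rt_bin: float = 0.1,
    rt_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """XIC for one m/z window: (rt, intensity) rows on a zero-filled raster.

    Bins span the full chromatographic range (``rt_range`` defaults to
    [0, max observed RT + 1]); bins without an observation are zero, so the
    median of the raster reflects the baseline rather than the apex.
    """
    sel = peaks[(peaks["mz"] - mz).abs() <= tolerance]
    if rt_range is None:
        hi = float(peaks["rt_min"].max()) + 1.0 if len(peaks) else 1.0
        rt_range = (0.0, hi)
    n_bins = int(round((rt_range[1] - rt_range[0]) / rt_bin)) + 1
    rts = rt_range[0] + np.arange(n_bins) * rt_bin
    intens = np.zeros(n_bins)
    if not sel.empty:
        ix = np.clip(
            np.round((sel["rt_min"].to_numpy() - rt_range[0]) / rt_bin).astype(int), 0, n_bins - 1
        )
        np.maximum.at(intens, ix, sel["intensity"].to_numpy())
    return np.column_stack([rts, intens])


def detect_peaks(xic: np.ndarray, delta: float = 2.0) -> list[tuple[float, float]]:
    """Local maxima of an XIC with apex/noise ratio above ``delta``.

    Noise is the median intensity of the XIC.  A chromatogram may yield no
    peak or several peaks.  An all-zero trace yields none.
    """
    if len(xic) == 0:
        return []
    intens = xic[:, 1]
    if not intens.any():
        return []
    noise = float(np.median(intens))
    peaks = []
    for ix in range(len(intens)):
        left = intens[ix - 1] if ix > 0 else -np.inf
        right = intens[ix + 1] if ix < len(intens) - 1 else -np.inf
        if intens[ix] > left and intens[ix] >= right:
            snr = intens[ix] / noise if noise > 0 else np.inf
            if snr > delta:
                peaks.append((float(xic[ix, 0]), float(intens[ix])))
    return peaks


def build_traces(
    peaks: pd.DataFrame,
    cluster_id: int,
    cluster_mz: float,
    rt_apexes: Sequence[float],
    params: FilterParams,
    time_grid: Sequence[float] | None = None,
) -> list[KineticTrace]:
    """Intensity-versus-digestion-time series for each detected RT apex.

    Missing observations at a grid time count as zero intensity; the grid
    defaults to the digestion times present in the data and must include 0.
    """
    if time_grid is None:
        time_grid = sorted(peaks["digestion_time"].unique())
    time_grid = sorted(set(float(t) for t in time_grid) | {0.0})
    traces = []
    window = peaks[(peaks["mz"] - cluster_mz).abs() <= params.mz_tolerance]
    for apex in rt_apexes:
        near = window[(window["rt_min"] - apex).abs() <= params.rt_window]
        by_t = near.groupby("digestion_time")["intensity"].max()
        samples = tuple((t, float(by_t.get(t, 0.0))) for t in time_grid)
        traces.append(KineticTrace(cluster_id, cluster_mz, float(apex), samples))
    return traces


def _monotone_up(vals: Sequence[float], eps: float) -> bool:
    return all(b >= a * (1 - eps) for a, b in zip(vals, vals[1:]))


def _monotone_down(vals: Sequence[float], eps: float) -> bool:
    return all(b <= a * (1 + eps) for a, b in zip(vals, vals[1:]))


def kinetic_filter(traces: Sequence[KineticTrace], params: FilterParams) -> list[CandidateRecord]:
    """Keep traces with plausible product kinetics; attach t_max.

    A trace survives iff its t = 0 intensity is strictly below the ceiling,
    its maximum lies after t = 0 (otherwise nothing was generated during
    digestion), it rises monotonically (within relative tolerance
    ``epsilon``) to that maximum, and any following decline is itself
    monotone and only accepted when ``allow_reentry`` is set.  Ties for
    the maximum resolve to the earliest time.  Traces with fewer than two
    samples are rejected with a warning.
    """
    kept = []
    for tr in traces:
        if len(tr.samples) < 2:
            warnings.warn(
                f"trace at m/z {tr.cluster_mz:.4f} has fewer than 2 time points; rejected",
                stacklevel=2,
            )
            continue
        intens = [v for _, v in tr.samples]
        times = [t for t, _ in tr.samples]
        if intens[0] >= params.max_t0_intensity:
            continue
        peak = max(intens)
        if peak <= 0:
            continue
        imax = intens.index(peak)  # earliest tie wins
        if imax == 0:
            # signal already maximal before digestion started: not a product
            continue
        if not _monotone_up(intens[: imax + 1], params.epsilon):
            continue
        tail = intens[imax:]
        declines = intens[-1] < peak * (1 - params.epsilon)
        if declines:
            if not params.allow_reentry:
                continue
            if not _monotone_down(tail, params.epsilon):
                continue
        kept.append(
            CandidateRecord(tr.cluster_id, tr.cluster_mz, tr.rt_apex, times[imax], peak)
        )
    return kept


def group_candidates(records: Sequence[CandidateRecord], d_max: int = 15) -> InclusionList:
    """Group candidates by t_max; split groups of size > d_max evenly.

    A group of size D becomes ceil(D / d_max) subgroups whose sizes differ
    by at most one (all <= d_max).  Groups are ordered by t_max, members by
    m/z, for reproducibility.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    by_tmax: dict[float, list[CandidateRecord]] = {}
    for r in records:
        by_tmax.setdefault(r.t_max, []).append(r)
    entries = []
    n_sub_total = 0
    for gid, t in enumerate(sorted(by_tmax)):
        group = sorted(by_tmax[t], key=lambda r: (r.cluster_mz, r.rt_min))
        d_g = len(group)
        n_sub = -(-d_g // d_max)  # ceil
        base, extra = divmod(d_g, n_sub)
        start = 0
        for sub in range(n_sub):
            size = base + (1 if sub < extra else 0)
            for r in group[start : start + size]:
                entries.append(
                    {
                        "mz": r.cluster_mz,
                        "rt_min": r.rt_min,
                        "t_max": r.t_max,
                        "group_id": gid,
                        "subgroup_id": n_sub_total + sub,
                        "cluster_id": r.cluster_id,
                    }
                )
            start += size
        n_sub_total += n_sub
    return InclusionList(entries, n_groups=len(by_tmax), n_subgroups=n_sub_total, d_max=d_max)


def compare_rt(rt_a: float, rt_b: float, max_delta: float = 0.5) -> bool:
    """True iff two retention times agree within ``max_delta`` minutes."""
    return abs(rt_a - rt_b) < max_delta


def write_inclusion_csv(
    inclusion: InclusionList,
    path: str | Path,
    charge_of: dict[int, int] | None = None,
    rt_window: float = 1.0,
) -> None:
    rows = []
    for e in inclusion.entries:
        rows.append(
            {
                "mz": round(e["mz"], 5),
                "charge": (charge_of or {}).get(e["cluster_id"], 1),
                "rt_center_min": round(e["rt_min"], 3),
                "rt_window_min": rt_window,
                "t_max": e["t_max"],
                "group_id": e["group_id"],
                "subgroup_id": e["subgroup_id"],
            }
        )
    pd.DataFrame(
        rows,
        columns=["mz", "charge", "rt_center_min", "rt_window_min", "t_max", "group_id", "subgroup_id"],
    ).to_csv(path, index=False)
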