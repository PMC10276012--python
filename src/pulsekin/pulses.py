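"""Pulsation-cycle detection, phase segmentation and per-sequence metrics.

A pulsation cycle is split into three phases: contraction (from the onset
of the pulse to the velocity peak, which usually coincides with minimum
bell diameter), relaxation (from the velocity peak until bell re-expansion
reaches maximum diameter) and interpulse (the coasting span before the
next contraction, bell fully expanded, where passive energy recapture
produces a secondary velocity gain). Passive energy recapture (PER) is
quantified as the mean interpulse travel distance divided by the mean
per-cycle travel distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .kinematics import KinematicSeries, _moving_average

__all__ = ["PulseCycle", "SwimMetrics", "detect_cycles", "segment_phases", "swim_metrics", "analyze_sequence"]


@dataclass
class PulseCycle:
    """One segmented pulsation cycle (frame indices + phase times/distances)."""

    i_start: int
    i_peak_u: int
    i_max_d: int
    i_end: int
    C_time: float
    R_time: float
    I_time: float
    C_dist: float
    R_dist: float
    I_dist: float
    u_max: float
    re_max: float
    d_max: float
    fallback_velocity_only: bool = False

    @property
    def duration(self) -> float:
        return self.C_time + self.R_time + self.I_time

    @property
    def distance(self) -> float:
        return self.C_dist + self.R_dist + self.I_dist


@dataclass
class SwimMetrics:
    """Per-sequence swimming summary (across-cycle averages)."""

    n_pulses: int
    P_freq: float  # pulses / elapsed time, NaN when < 2 pulses
    P_freq_inv_mean_time: float  # 1 / mean cycle duration (alternative)
    P_time: float
    P_dist: float
    C_time: float
    R_time: float
    I_time: float
    C_dist: float
    R_dist: float
    I_dist: float
    PER: float  # mean(I_dist) / mean(P_dist)
    PER_per_cycle: float  # mean of per-cycle I_dist/P_dist (alternative)
    u_max: float
    re_max: float
    reference_diameter: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("extras")
        return d


def _rightmost_min(v: np.ndarray, lo: int, hi: int) -> int:
    """Rightmost index in v[lo:hi] attaining the window minimum.

    On a flat coasting trough the rightmost minimal sample is the onset of
    the velocity rise, i.e. the start of contraction.
    """
    w = v[lo:hi]
    mn = w.min()
    idx = np.nonzero(w == mn)[0]
    return lo + int(idx[-1])


def _smoothing_kernel(*widths: int) -> np.ndarray:
    """Combined kernel of cascaded centered moving averages (boxcar convolution)."""
    k = np.ones(1)
    for w in widths:
        if w > 1:
            if w % 2 == 0:
                w += 1
            k = np.convolve(k, np.ones(w) / w)
    return k


def _vertex_shift(kernel: np.ndarray, curvature_ratio: float) -> float:
    """Peak displacement caused by symmetric smoothing of an asymmetric peak.

    For a two-sided quadratic peak with left/right curvatures B_l, B_r
    (``curvature_ratio`` = B_l/B_r), the smoothed maximum sits where
    B_l * m-(t) = B_r * m+(t), with m-/m+ the kernel's one-sided first
    moments about t. Solved by bisection; returned in samples (positive =
    smoothing pushed the peak toward the flatter, later flank).
    """
    if len(kernel) <= 1 or curvature_ratio <= 0:
        return 0.0
    h = (len(kernel) - 1) / 2.0
    s = np.arange(len(kernel)) - h

    def g(t: float) -> float:
        mm = float(np.sum(kernel[s > t] * (s[s > t] - t)))
        mp = float(np.sum(kernel[s < t] * (t - s[s < t])))
        return curvature_ratio * mm - mp

    lo, hi = -h, h
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _quadratic_peak(v: np.ndarray, i: int, w: int) -> int:
    """Vertex of a least-squares parabola through v[i-w : i+w+1], as an index."""
    lo, hi = max(0, i - w), min(len(v), i + w + 1)
    idx = np.arange(lo, hi, dtype=float)
    seg = v[lo:hi]
    if len(seg) < 3:
        return i
    c2, c1, _ = np.polyfit(idx - i, seg, 2)
    if c2 >= 0:  # not concave: keep the detected sample
        return i
    vertex = i - c1 / (2.0 * c2)
    return int(np.clip(round(vertex), lo, hi - 1))


def detect_cycles(
    u: np.ndarray,
    f: np.ndarray | None = None,
    prominence_frac: float = 0.25,
    min_separation_frac: float = 0.5,
    height_frac: float = 0.5,
    smooth_window: int = 0,
    refine_window: int = 0,
) -> list[tuple[int, int, int]]:
    """Detect pulsation cycles from a velocity profile.

    Velocity peaks are local maxima of (optionally moving-average-smoothed)
    u with prominence >= ``prominence_frac`` * (95th - 5th percentile of u),
    height >= 5th percentile + ``height_frac`` * that same span (the
    contraction peak sits in the upper part of the velocity range, which
    excludes the smaller passive-energy-recapture bump), and separation
    >= ``min_separation_frac`` * median inter-peak spacing.
    Each cycle starts at the onset of contraction — the rightmost minimal
    velocity sample before the peak, refined to the last fully-relaxed-bell
    frame (minimum fineness) when ``f`` is supplied — and ends at the next
    cycle's start. The trailing edge-truncated segment is discarded.

    Returns a list of (i_start, i_peak, i_end) index triples into the
    velocity series; an empty list when no pulsation is found.
    """
    u = np.asarray(u, dtype=float)
    us = _moving_average(u, smooth_window) if smooth_window > 1 else u
    p5, p95 = np.nanpercentile(us, [5, 95])
    span = p95 - p5
    if span <= 0:
        return []
    prom = prominence_frac * span
    height = p5 + height_frac * span
    peaks, _ = find_peaks(us, prominence=prom, height=height)
    if len(peaks) >= 3 and min_separation_frac > 0:
        dist = max(1, int(round(min_separation_frac * float(np.median(np.diff(peaks))))))
        peaks, _ = find_peaks(us, prominence=prom, height=height, distance=dist)
    if len(peaks) < 2:
        return []
    if refine_window > 0:
        # heavy smoothing biases an asymmetric peak toward its flatter
        # flank; re-locate each peak as the vertex of a local quadratic fit
        # on the unsmoothed series
        refined = []
        for pk in peaks:
            r = _quadratic_peak(u, pk, refine_window)
            if refined and r <= refined[-1] + 1:
                r = refined[-1] + 2
            refined.append(r)
        peaks = np.array([r for r in refined if r < len(u)])
        if len(peaks) < 2:
            return []

    starts = []
    prev = 0
    for pk in peaks:
        s = _rightmost_min(us, prev, pk)
        if f is not None:
            fw = np.asarray(f, dtype=float)[prev:pk]
            if np.any(np.isfinite(fw)):
                fmn = np.nanmin(fw)
                tol = 1e-9 * max(1.0, abs(fmn))
                idx = np.nonzero(fw <= fmn + tol)[0]
                s = prev + int(idx[-1])
        starts.append(s)
        prev = pk
    cycles = []
    for k in range(len(starts) - 1):
        cycles.append((starts[k], int(peaks[k]), starts[k + 1]))
    return cycles


def segment_phases(
    cycle: tuple[int, int, int],
    t: np.ndarray,
    m: np.ndarray,
    u: np.ndarray,
    f: np.ndarray | None = None,
    d: np.ndarray | None = None,
    re: np.ndarray | None = None,
) -> PulseCycle:
    """Split one detected cycle into contraction / relaxation / interpulse.

    Contraction spans [i_start, i_peak_u]; relaxation ends at the first
    maximum-diameter frame after the velocity peak (minimum fineness is the
    proxy when only ``f`` is available — note maximum diameter corresponds
    to *minimum* fineness); the interpulse is the remainder. With neither
    bell series available, relaxation ends at the post-peak velocity
    minimum (flagged ``fallback_velocity_only``).

    All series share one grid (``t`` may be frame times or interval
    midtimes, with ``m``/``u``/``re`` aligned to it). Phase times are
    timestamp differences and phase distances are sums of m over each
    half-open span, so the three phases partition the cycle exactly.
    """
    i_start, i_peak, i_end = cycle
    if not (0 <= i_start < i_peak <= i_end <= len(t) - 1):
        raise ValueError("invalid cycle boundaries")
    fallback = False
    if d is not None and np.any(np.isfinite(np.asarray(d, dtype=float)[i_peak : i_end + 1])):
        seg = np.asarray(d, dtype=float)[i_peak : i_end + 1]
        i_max_d = i_peak + int(np.nanargmax(seg))  # earliest index wins ties
    elif f is not None and np.any(np.isfinite(np.asarray(f, dtype=float)[i_peak : i_end + 1])):
        seg = np.asarray(f, dtype=float)[i_peak : i_end + 1]
        i_max_d = i_peak + int(np.nanargmin(seg))  # max D == min fineness
    else:
        fallback = True
        seg = np.asarray(u, dtype=float)[i_peak : max(i_peak + 1, i_end)]
        i_max_d = i_peak + int(np.argmin(seg))

    i_max_d = min(max(i_max_d, i_peak), i_end)
    u_seg = u[i_start:i_end]
    cyc_d = np.asarray(d, dtype=float)[i_start : i_end + 1] if d is not None else None
    return PulseCycle(
        i_start=i_start,
        i_peak_u=i_peak,
        i_max_d=i_max_d,
        i_end=i_end,
        C_time=float(t[i_peak] - t[i_start]),
        R_time=float(t[i_max_d] - t[i_peak]),
        I_time=float(t[i_end] - t[i_max_d]),
        C_dist=float(np.sum(m[i_start:i_peak])),
        R_dist=float(np.sum(m[i_peak:i_max_d])),
        I_dist=float(np.sum(m[i_max_d:i_end])),
        u_max=float(np.max(u_seg)) if len(u_seg) else float("nan"),
        re_max=float(np.nanmax(re[i_start:i_end]))
        if re is not None and np.any(np.isfinite(re[i_start:i_end]))
        else float("nan"),
        d_max=float(np.nanmax(cyc_d))
        if cyc_d is not None and np.any(np.isfinite(cyc_d))
        else float("nan"),
        fallback_velocity_only=fallback,
    )


def swim_metrics(cycles: list[PulseCycle], t: np.ndarray) -> SwimMetrics:
    """Across-cycle averages for one sequence.

    Pulsation frequency uses the pulses-per-elapsed-time definition and is
    reported only for sequences with two or more pulses (NaN otherwise);
    1/mean(P_time) is carried as an alternative. PER is the ratio of the
    averages mean(I_dist)/mean(P_dist); the mean per-cycle ratio is carried
    as an alternative.
    """
    if not cycles:
        nan = float("nan")
        return SwimMetrics(*([0] + [nan] * 15))
    n = len(cycles)
    mean = lambda attr: float(np.mean([getattr(c, attr) for c in cycles]))
    p_time = mean("duration")
    p_dist = mean("distance")
    i_dist = mean("I_dist")
    span = float(t[cycles[-1].i_end] - t[cycles[0].i_start])
    p_freq = n / span if n >= 2 and span > 0 else float("nan")
    per_cycle = float(np.mean([c.I_dist / c.distance for c in cycles if c.distance > 0]))
    re_maxes = [c.re_max for c in cycles]
    d_maxes = [c.d_max for c in cycles]
    ref_d = float(np.nanmean(d_maxes)) if np.any(np.isfinite(d_maxes)) else float("nan")
    return SwimMetrics(
        n_pulses=n,
        P_freq=p_freq,
        P_freq_inv_mean_time=1.0 / p_time if p_time > 0 else float("nan"),
        P_time=p_time,
        P_dist=p_dist,
        C_time=mean("C_time"),
        R_time=mean("R_time"),
        I_time=mean("I_time"),
        C_dist=mean("C_dist"),
        R_dist=mean("R_dist"),
        I_dist=i_dist,
        PER=i_dist / p_dist if p_dist > 0 else float("nan"),
        PER_per_cycle=per_cycle,
        u_max=mean("u_max"),
        re_max=float(np.nanmean(re_maxes)) if np.any(np.isfinite(re_maxes)) else float("nan"),
        reference_diameter=ref_d,
        extras={"n_fallback_velocity_only": sum(c.fallback_velocity_only for c in cycles)},
    )


def analyze_sequence(
    series: KinematicSeries,
    prominence_frac: float = 0.25,
    min_separation_frac: float = 0.5,
    smooth_window: int = 0,
    refine_window: int = 0,
    peak_bias_correction: bool = True,
) -> tuple[SwimMetrics, list[PulseCycle]]:
    """Detect, segment and summarize all cycles in one kinematic series.

    Cycle detection runs on the interval velocity series; per-frame
    fineness/diameter are aligned to intervals by endpoint averaging for
    boundary placement. ``smooth_window`` smooths the velocity used for
    detection only; metrics use the raw series.

    Moving-average smoothing (either applied to positions upstream or via
    ``smooth_window`` here) displaces the velocity maximum of an asymmetric
    pulse toward its flatter flank, inflating contraction time. With
    ``peak_bias_correction`` (default) a second pass estimates the
    left/right curvature ratio from the first-pass contraction/relaxation
    durations and shifts each peak by the closed-form displacement of the
    known smoothing kernel.
    """
    f_int = 0.5 * (series.f[:-1] + series.f[1:])
    have_f = np.any(np.isfinite(f_int))
    cycles_idx = detect_cycles(
        series.u,
        f=f_int if have_f else None,
        prominence_frac=prominence_frac,
        min_separation_frac=min_separation_frac,
        smooth_window=smooth_window,
        refine_window=refine_window,
    )
    us = _moving_average(series.u, smooth_window) if smooth_window > 1 else series.u
    have_d = np.any(np.isfinite(series.d_interval))

    def _segment(idx_triples):
        return [
            segment_phases(
                c,
                t=series.interval_midtimes,
                m=series.m,
                u=us,
                f=f_int if have_f else None,
                d=series.d_interval if have_d else None,
                re=series.re,
            )
            for c in idx_triples
        ]

    cycles = _segment(cycles_idx)
    kernel = _smoothing_kernel(int(series.meta.get("smooth_window") or 0), smooth_window)
    if peak_bias_correction and cycles and len(kernel) > 1:
        # iterate: the first-pass durations are themselves biased, so the
        # curvature ratio (and hence the shift) improves on a second pass
        delta_f = 0.0
        for _ in range(3):
            c_bar = np.mean([c.i_peak_u - c.i_start for c in cycles])
            r_bar = np.mean([c.i_max_d - c.i_peak_u for c in cycles])
            if not (c_bar > 0 and r_bar > 0):
                break
            delta_f = _vertex_shift(kernel, (r_bar / c_bar) ** 2)
            delta = int(round(delta_f))
            shifted = [
                (s, int(np.clip(p - delta, s + 1, e - 1)), e) for s, p, e in cycles_idx
            ]
            new_cycles = _segment(shifted)
            if [c.i_peak_u for c in new_cycles] == [c.i_peak_u for c in cycles]:
                cycles = new_cycles
                break
            cycles = new_cycles
        # sub-sample remainder of the shift: move the contraction/relaxation
        # split in time without touching indices (partition is preserved)
        resid = delta_f - round(delta_f)
        if resid != 0.0 and cycles:
            dtm = float(np.median(np.diff(series.interval_midtimes)))
            for c in cycles:
                adj = resid * dtm
                if c.C_time - adj > 0 and c.R_time + adj > 0:
                    c.C_time -= adj
                    c.R_time += adj
    return swim_metrics(cycles, series.interval_midtimes), cycles


def cycles_frame(cycles: list[PulseCycle]) -> pd.DataFrame:
    """Per-cycle diagnostics as a DataFrame."""
    return pd.DataFrame([asdict(c) for c in cycles])
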