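"""Per-frame swimming biomechanics from digitized trajectories.

The observables are those used throughout the medusa-swimming literature:
instantaneous bell fineness ``f_i = h_i / D_i`` (height over diameter, a
shape index: f < 1 oblate, f > 1 prolate), inter-frame displacement ``m_i``
(Euclidean, from apex coordinates), instantaneous velocity ``u_i = m_i / dt_i``
and Reynolds number ``Re_i = D_i u_i / nu`` with the temperature-dependent
kinematic viscosity of seawater.

Units are cm and s throughout; SI conversion happens only inside the
Reynolds computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySequence",
    "KinematicSeries",
    "fineness_series",
    "displacement_series",
    "velocity_series",
    "reynolds_series",
    "kinematic_viscosity",
    "compute_kinematics",
    "sequence_means",
]

#: Kinematic viscosity of seawater (m^2 s^-1) by temperature (deg C).
#: Values between table points are linearly interpolated.
VISCOSITY_TABLE: Mapping[float, float] = {15.0: 1.17e-6, 20.0: 1.05e-6, 25.0: 0.95e-6}


@dataclass
class TrajectorySequence:
    """One recorded swim: apex positions over time, with optional bell shape.

    Parameters
    ----------
    t : array of s, strictly increasing, length >= 2
    x, y : apex coordinates, cm
    h, d : bell height / diameter series, cm (optional; NaN where missing)
    temperature : water temperature, deg C (default 20)
    species, individual : labels carried through to outputs
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    h: np.ndarray | None = None
    d: np.ndarray | None = None
    temperature: float = 20.0
    species: str = ""
    individual: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("h", "d"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.t):
                    raise ValueError(f"{name} length must match t")
                if np.any(v[np.isfinite(v)] <= 0):
                    raise ValueError(f"{name} must be positive where present")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        nan = np.full(len(self.t), np.nan)
        return pd.DataFrame(
            {
                "t_s": self.t,
                "x_cm": self.x,
                "y_cm": self.y,
                "h_cm": self.h if self.h is not None else nan,
                "d_cm": self.d if self.d is not None else nan,
                "temp_c": self.temperature,
                "species": self.species,
                "individual": self.individual,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySequence":
        def _opt(col: str) -> np.ndarray | None:
            if col not in df or df[col].isna().all():
                return None
            return df[col].to_numpy(float)

        return cls(
            t=df["t_s"].to_numpy(float),
            x=df["x_cm"].to_numpy(float),
            y=df["y_cm"].to_numpy(float),
            h=_opt("h_cm"),
            d=_opt("d_cm"),
            temperature=float(df["temp_c"].iloc[0]) if "temp_c" in df else 20.0,
            species=str(df["species"].iloc[0]) if "species" in df else "",
            individual=str(df["individual"].iloc[0]) if "individual" in df else "",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectorySequence":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class KinematicSeries:
    """Per-frame fineness and per-interval displacement/velocity/Reynolds.

    ``f`` has one entry per frame; ``m``, ``u``, ``re`` and
    ``interval_midtimes`` have one entry per inter-frame interval
    (n_frames - 1). ``d_interval`` is the endpoint-averaged bell diameter
    used for Re, kept for downstream cycle diagnostics.
    """

    t: np.ndarray
    f: np.ndarray
    m: np.ndarray
    u: np.ndarray
    re: np.ndarray
    interval_midtimes: np.ndarray
    d_interval: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_mid_s": self.interval_midtimes,
                "f": 0.5 * (self.f[:-1] + self.f[1:]),
                "m_cm": self.m,
                "u_cm_per_s": self.u,
                "re": self.re,
                "d_cm": self.d_interval,
            }
        )


def fineness_series(h: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Instantaneous bell fineness f_i = h_i / D_i (dimensionless).

    NaN in either input propagates; non-positive diameters are rejected.
    """
    h = np.asarray(h, dtype=float)
    d = np.asarray(d, dtype=float)
    if h.shape != d.shape:
        raise ValueError("h and D must have equal length")
    if np.any(d[np.isfinite(d)] <= 0):
        raise ValueError("bell diameter must be positive")
    with np.errstate(invalid="ignore"):
        return h / d


def displacement_series(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Inter-frame displacement m_i = sqrt(dx^2 + dy^2), cm; length n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 frames")
    return np.hypot(np.diff(x), np.diff(y))


def velocity_series(m: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Instantaneous velocity u_i = m_i / (t_{i+1} - t_i), cm/s."""
    m = np.asarray(m, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(t) != len(m) + 1:
        raise ValueError("need len(t) == len(m) + 1")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return m / dt


def kinematic_viscosity(temperature_c: float) -> float:
    """Seawater kinematic viscosity (m^2/s) interpolated from the table.

    Outside the tabulated 15-25 deg C range the nearest endpoint is used.
    """
    temps = np.array(sorted(VISCOSITY_TABLE))
    vals = np.array([VISCOSITY_TABLE[tt] for tt in temps])
    return float(np.interp(temperature_c, temps, vals))


def reynolds_series(
    d: np.ndarray, u: np.ndarray, viscosity: float = 1.05e-6
) -> np.ndarray:
    """Reynolds number Re_i = D_i u_i / nu, dimensionless.

    ``d`` (cm) may be per-frame (len(u)+1, averaged over interval endpoints)
    or already per-interval (len(u)). ``u`` is in cm/s; both are converted
    to SI internally; ``viscosity`` is in m^2/s.
    """
    d = np.asarray(d, dtype=float)
    u = np.asarray(u, dtype=float)
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if len(d) == len(u) + 1:
        d = 0.5 * (d[:-1] + d[1:])
    elif len(d) != len(u):
        raise ValueError("D must align to frames (n) or intervals (n-1)")
    return (d * 1e-2) * (u * 1e-2) / viscosity


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; window forced odd; edges use shrinking windows."""
    if window <= 1:
        return v
    if window % 2 == 0:
        window += 1
    half = window // 2
    out = np.empty_like(v, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = len(v)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def compute_kinematics(
    traj: TrajectorySequence,
    viscosity: float | None = None,
    resample_dt: float | None = None,
    smooth_window: int = 0,
) -> KinematicSeries:
    """Full kinematic series for one trajectory.

    Optional preprocessing, recorded in ``meta``: uniform resampling to
    ``resample_dt`` (linear interpolation, emulating frame subsampling at
    intervals of minimal body movement) and a centered moving average of
    ``smooth_window`` samples applied to positions before differentiation.
    ``viscosity`` (m^2/s) overrides the temperature-interpolated value.
    Fineness and Re are NaN where bell dimensions are missing; velocity
    metrics are always computed.
    """
    t, x, y = traj.t, traj.x, traj.y
    n = len(t)
    h = traj.h if traj.h is not None else np.full(n, np.nan)
    d = traj.d if traj.d is not None else np.full(n, np.nan)

    if resample_dt is not None:
        if resample_dt <= 0:
            raise ValueError("resample_dt must be positive")
        tn = np.arange(t[0], t[-1] + 0.5 * resample_dt, resample_dt)
        tn = tn[tn <= t[-1] + 1e-12]
        x = np.interp(tn, t, x)
        y = np.interp(tn, t, y)
        h = np.interp(tn, t, h)
        d = np.interp(tn, t, d)
        t = tn

    if smooth_window > 1:
        x = _moving_average(x, smooth_window)
        y = _moving_average(y, smooth_window)

    nu = viscosity if viscosity is not None else kinematic_viscosity(traj.temperature)
    with np.errstate(invalid="ignore"):
        f = fineness_series(h, d)
    m = displacement_series(x, y)
    u = velocity_series(m, t)
    d_int = 0.5 * (d[:-1] + d[1:])
    with np.errstate(invalid="ignore"):
        re = reynolds_series(d_int, u, nu)
    return KinematicSeries(
        t=t,
        f=f,
        m=m,
        u=u,
        re=re,
        interval_midtimes=0.5 * (t[:-1] + t[1:]),
        d_interval=d_int,
        meta={
            "viscosity_m2_per_s": nu,
            "resample_dt_s": resample_dt,
            "smooth_window": smooth_window,
            "species": traj.species,
            "individual": traj.individual,
        },
    )


def sequence_means(series: KinematicSeries) -> dict[str, float]:
    """Arithmetic means over the sequence, NaN-ignoring (all-NaN -> NaN)."""
    if len(series.u) == 0:
        raise ValueError("empty kinematic series")

    def _nanmean(v: np.ndarray) -> float:
        return float(np.nanmean(v)) if np.any(np.isfinite(v)) else float("nan")

    return {
        "f_mean": _nanmean(series.f),
        "u_mean": _nanmean(series.u),
        "re_mean": _nanmean(series.re),
    }
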