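"""Sensor-stream preprocessing for tagged marine animals.

Raw tag records come as a depth trace (pressure-derived, metres, positive
down) and a tri-axial acceleration trace.  This module turns them into the
derived objects the recovery estimators consume:

* a zero-offset-corrected depth trace (moving-quantile drift correction),
* a dive table (one row per excursion below the surface zone, with target
  depth, duration and a depth category),
* minute-scale series of the dynamic-body-acceleration metrics VeDBA and
  ODBA and of jerk (norm of the acceleration derivative).

Pressure transducers drift with temperature, so the recorded depth at the
surface wanders away from zero.  The correction applied here is a two-stage
moving-quantile smoother: a short centred median removes surface chop, then
a long centred low-quantile filter tracks the (drifting) surface level,
which is subtracted out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "AccelTrace",
    "DepthTrace",
    "MetricSeries",
    "SpeciesConfig",
    "DIVE_COLUMNS",
    "CATEGORIES",
    "zero_offset_correct",
    "resample",
    "segment_dives",
    "static_acceleration",
    "dynamic_acceleration",
    "vedba",
    "odba",
    "jerk",
    "aggregate_metric",
    "read_depth_csv",
    "read_accel_csv",
]

#: Depth-category alphabet, ordered from the surface down.
CATEGORIES = ("Shallow", "Medium", "Deep")

#: Column schema of a dive table (one row per completed dive).
DIVE_COLUMNS = ("animal_id", "start_h", "duration_s", "target_depth_m", "category")


@dataclass
class DepthTrace:
    """Uniformly sampled depth series, metres positive down.

    ``t0`` is the release time in hours (sample k sits at
    ``t0 + k / fs / 3600`` hours since release).
    """

    depth: np.ndarray
    fs: float
    animal_id: str = "animal"
    t0: float = 0.0
    corrected: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-d array")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def times_h(self) -> np.ndarray:
        return self.t0 + np.arange(self.depth.size) / (self.fs * 3600.0)


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration (consistent units, e.g. g)."""

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    animal_id: str = "animal"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (self.ax.shape == self.ay.shape == self.az.shape):
            raise ValueError("axes must have equal length")
        if self.ax.ndim != 1 or self.ax.size == 0:
            raise ValueError("axes must be non-empty 1-d arrays")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_samples(self) -> int:
        return self.ax.size

    @property
    def times_h(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / (self.fs * 3600.0)

    def stacked(self) -> np.ndarray:
        """(n, 3) array of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class MetricSeries:
    """A derived movement metric sampled at known times since release."""

    time_h: np.ndarray
    value: np.ndarray
    metric_name: str
    animal_id: str = "animal"
    aggregation_window_min: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_h.shape != self.value.shape:
            raise ValueError("time and value must have equal length")
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "metric": self.metric_name,
                "time_h": self.time_h,
                "value": self.value,
            }
        )


@dataclass
class SpeciesConfig:
    """Species-level processing constants.

    Depth-category edges follow typical dive-depth regimes: narwhals use
    (160, 360) m, bowhead whales (60, 120) m.  ``normal_region_start_h``
    (the hour from which baseline diving is assumed), ``upper_limit_h`` and
    ``block_h`` parameterize the dive-profile recovery analysis.
    """

    surface_threshold_m: float = 20.0
    category_edges_m: tuple[float, float] = (160.0, 360.0)
    target_fs_depth: float = 1.0
    target_fs_accel: float = 50.0
    lowpass_cutoff_hz: float = 0.1
    luque_window1_s: float = 20.0
    luque_window2_min: float = 30.0
    luque_q1: float = 0.5
    luque_q2: float = 0.01
    normal_region_start_h: float = 40.0
    upper_limit_h: float = 80.0
    block_h: float = 5.0
    name: str = "narwhal"

    def __post_init__(self) -> None:
        e1, e2 = self.category_edges_m
        if not (self.surface_threshold_m < e1 < e2):
            raise ValueError("category edges must be increasing and above the surface threshold")

    @classmethod
    def narwhal(cls) -> "SpeciesConfig":
        return cls()

    @classmethod
    def bowhead(cls) -> "SpeciesConfig":
        return cls(
            category_edges_m=(60.0, 120.0),
            target_fs_depth=1.0,
            target_fs_accel=5.0,
            normal_region_start_h=10.0,
            upper_limit_h=20.0,
            block_h=2.0,
            name="bowhead",
        )

    @classmethod
    def for_species(cls, name: str) -> "SpeciesConfig":
        key = name.strip().lower()
        if key == "narwhal":
            return cls.narwhal()
        if key in ("bowhead", "bowhead whale", "bowhead_whale"):
            return cls.bowhead()
        raise ValueError(f"unknown species {name!r}; use a SpeciesConfig directly")


# ---------------------------------------------------------------------------
# depth correction


def _odd_window(n_samples: float) -> int:
    w = max(1, int(round(n_samples)))
    return w if w % 2 == 1 else w + 1


def _centered_running_quantile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centred moving quantile; edge windows shrink symmetrically.

    At index i the window is x[i-h : i+h+1] with h reduced near the edges so
    the window stays centred (avoids phase shift in surface detection).
    """
    n = x.size
    window = min(window, n if n % 2 == 1 else n - 1)
    out = (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .quantile(q)
        .to_numpy()
    )
    h = window // 2
    # pandas truncates edge windows asymmetrically; redo them symmetrically
    for i in range(min(h, n - 1 - h + 1)):
        out[i] = np.quantile(x[: 2 * i + 1], q)
        out[n - 1 - i] = np.quantile(x[n - 2 * i - 1 :], q)
    return out


def zero_offset_correct(
    d: DepthTrace, cfg: SpeciesConfig | None = None, mode: str = "filtered"
) -> DepthTrace:
    """Remove pressure-sensor drift with a two-stage moving-quantile filter.

    Stage one is a centred running median over ``luque_window1_s`` seconds
    (surface de-noising); stage two a centred running ``luque_q2`` quantile
    over ``luque_window2_min`` minutes of the stage-one output (surface
    level tracking).  ``mode='filtered'`` (default) returns stage one minus
    stage two; ``mode='raw'`` subtracts the surface track from the raw
    trace instead, preserving within-dive high-frequency content.
    """
    cfg = cfg or SpeciesConfig()
    if mode not in ("filtered", "raw"):
        raise ValueError("mode must be 'filtered' or 'raw'")
    x = d.depth
    if not np.all(np.isfinite(x)):
        raise ValueError("depth trace contains non-finite samples")
    w1 = _odd_window(cfg.luque_window1_s * d.fs)
    w2 = _odd_window(cfg.luque_window2_min * 60.0 * d.fs)
    if x.size < w2:
        raise ValueError(
            f"trace of {x.size} samples is shorter than the surface-tracking "
            f"window ({w2} samples = {cfg.luque_window2_min} min at {d.fs} Hz)"
        )
    f1 = _centered_running_quantile(x, w1, cfg.luque_q1)
    f2 = _centered_running_quantile(f1, w2, cfg.luque_q2)
    corrected = (f1 if mode == "filtered" else x) - f2
    return replace(d, depth=corrected, corrected=True)


# ---------------------------------------------------------------------------
# resampling


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Integer-ratio resampling: block means down, sample repetition up.

    Downsampling truncates an incomplete final block.
    """
    x = np.asarray(x, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling frequencies must be positive")
    if fs_in == fs_out:
        return x.copy()
    if fs_in > fs_out:
        ratio = fs_in / fs_out
        r = int(round(ratio))
        if abs(ratio - r) > 1e-9:
            raise ValueError(f"fs_in/fs_out = {ratio} is not an integer")
        n = (x.size // r) * r
        return x[:n].reshape(-1, r).mean(axis=1)
    ratio = fs_out / fs_in
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ValueError(f"fs_out/fs_in = {ratio} is not an integer")
    return np.repeat(x, r)


# ---------------------------------------------------------------------------
# dive segmentation


def categorize_depth(target_depth_m: np.ndarray, cfg: SpeciesConfig) -> np.ndarray:
    """Depth category per dive; intervals are left-open/right-closed."""
    t = np.asarray(target_depth_m, dtype=float)
    e1, e2 = cfg.category_edges_m
    out = np.where(t <= e1, CATEGORIES[0], np.where(t <= e2, CATEGORIES[1], CATEGORIES[2]))
    return out.astype(object)


def segment_dives(d: DepthTrace, cfg: SpeciesConfig | None = None) -> pd.DataFrame:
    """Extract completed dives from a corrected depth trace.

    A dive is a maximal run of consecutive samples strictly below the
    surface zone (depth > ``surface_threshold_m``); its target depth is the
    deepest depth attained in the run and its duration the run length over
    the sampling rate.  Runs open at the record start or end are discarded
    (their target depth is unknowable).  Returns a ``DIVE_COLUMNS`` frame.
    """
    cfg = cfg or SpeciesConfig()
    if not d.corrected:
        warnings.warn("segmenting an uncorrected depth trace", stacklevel=2)
    below = d.depth > cfg.surface_threshold_m
    padded = np.concatenate([[False], below, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]  # [start, stop) sample runs
    rows = []
    for s, e in zip(starts, stops):
        if s == 0 or e == d.depth.size:  # open at a record boundary
            continue
        seg = d.depth[s:e]
        rows.append(
            (
                d.animal_id,
                d.t0 + s / (d.fs * 3600.0),
                (e - s) / d.fs,
                float(seg.max()),
            )
        )
    table = pd.DataFrame(rows, columns=DIVE_COLUMNS[:4])
    table["category"] = (
        categorize_depth(table["target_depth_m"].to_numpy(), cfg)
        if len(table)
        else pd.Series([], dtype=object)
    )
    return table


# ---------------------------------------------------------------------------
# acceleration metrics


def static_acceleration(a: AccelTrace, cutoff_hz: float = 0.1) -> AccelTrace:
    """Gravity (postural) component: zero-phase low-pass per axis.

    4th-order Butterworth applied forward-backward, so the static estimate
    has no lag relative to the raw series.
    """
    if not a.fs > 2 * cutoff_hz:
        raise ValueError(
            f"sampling rate {a.fs} Hz cannot resolve a {cutoff_hz} Hz cutoff"
        )
    sos = signal.butter(4, cutoff_hz, btype="low", fs=a.fs, output="sos")
    filt = lambda x: signal.sosfiltfilt(sos, x)
    return replace(a, ax=filt(a.ax), ay=filt(a.ay), az=filt(a.az))


def dynamic_acceleration(a: AccelTrace, cutoff_hz: float = 0.1) -> AccelTrace:
    """Raw minus static acceleration, per axis."""
    s = static_acceleration(a, cutoff_hz)
    return replace(a, ax=a.ax - s.ax, ay=a.ay - s.ay, az=a.az - s.az)


def _dba_series(a: AccelTrace, cutoff_hz: float, ord_: int, name: str) -> MetricSeries:
    da = dynamic_acceleration(a, cutoff_hz).stacked()
    value = np.linalg.norm(da, ord=ord_, axis=1)
    return MetricSeries(a.times_h, value, name, animal_id=a.animal_id)


def vedba(a: AccelTrace, cutoff_hz: float = 0.1) -> MetricSeries:
    """Vectorial dynamic body acceleration: Euclidean norm of the dynamic
    acceleration per sample.  Proxy for energy expenditure."""
    return _dba_series(a, cutoff_hz, 2, "VeDBA")


def odba(a: AccelTrace, cutoff_hz: float = 0.1) -> MetricSeries:
    """Overall dynamic body acceleration: L1 norm of the dynamic
    acceleration per sample."""
    return _dba_series(a, cutoff_hz, 1, "ODBA")


def jerk(a: AccelTrace) -> MetricSeries:
    """Norm of the acceleration derivative (first difference scaled by fs,
    so units are per second and values are comparable across sampling
    rates).  Timestamped at the later of each sample pair."""
    if a.n_samples < 2:
        raise ValueError("jerk needs at least two samples")
    diff = np.diff(a.stacked(), axis=0) * a.fs
    value = np.linalg.norm(diff, axis=1)
    return MetricSeries(a.times_h[1:], value, "jerk", animal_id=a.animal_id)


def aggregate_metric(m: MetricSeries, window_min: float = 1.0) -> MetricSeries:
    """Non-overlapping block means over ``window_min``-minute windows.

    Output samples sit at window centres; empty windows are dropped.  The
    operation is idempotent at a fixed window.
    """
    if m.time_h.size == 0:
        return replace(m, aggregation_window_min=window_min)
    w_h = window_min / 60.0
    bins = np.floor(m.time_h / w_h).astype(np.int64)
    uniq, inv = np.unique(bins, return_inverse=True)
    sums = np.bincount(inv, weights=m.value)
    counts = np.bincount(inv)
    return replace(
        m,
        time_h=(uniq + 0.5) * w_h,
        value=sums / counts,
        aggregation_window_min=window_min,
    )


# ---------------------------------------------------------------------------
# CSV input dialects


def read_depth_csv(path, fs: float | None = None, animal_id: str = "animal") -> DepthTrace:
    """Read a depth trace CSV with columns ``time_s, depth_m``.

    If ``fs`` is omitted it is inferred from the median time step.
    """
    df = pd.read_csv(path)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return DepthTrace(df["depth_m"].to_numpy(), fs=fs, animal_id=animal_id)


def read_accel_csv(path, fs: float | None = None, animal_id: str = "animal") -> AccelTrace:
    """Read an acceleration trace CSV with columns ``time_s, ax, ay, az``."""
    df = pd.read_csv(path)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return AccelTrace(
        df["ax"].to_numpy(), df["ay"].to_numpy(), df["az"].to_numpy(), fs=fs, animal_id=animal_id
    )
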