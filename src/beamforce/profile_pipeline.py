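"""Displacement-trace processing: laser reading -> force/dimpling channels,
membrane-rupture detection, and insertion-outcome classification.

A trial records the laser reading ``d_c`` of the sensing beam at 500 Hz
while the stage feeds the anesthetized animal's brain onto the microwire at
a constant rate (100 µm/s by default).  Calibration turns ``d_c`` into the
insertion force ``F_i`` and the load-point deflection ``d_l``; the stage
channel ``d_t`` follows from the feed rate, and tissue dimpling is the
difference ``d_i = d_t - d_l``.

Membrane rupture shows as a sudden force drop off a fresh running maximum —
much faster than the 1–2 s breathing oscillation riding on every in vivo
trace — so the detector looks for a drop of at least ``drop_fraction`` of
the running maximum (and at least ``min_drop_mn`` absolute, so that
breathing excursions early in the ramp cannot trip the relative criterion)
within a ``drop_window_s`` window, searching only before retraction onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numpy.typing import NDArray
from scipy import signal

from .beam_mechanics import CalibrationMap, LaserSpec, WireSpec, critical_buckling_load

__all__ = [
    "Membrane",
    "Outcome",
    "DisplacementTrace",
    "ForceProfile",
    "RuptureEvent",
    "InsertionTrial",
    "DetectionConfig",
    "BreathingEstimate",
    "convert_trace",
    "detect_rupture",
    "classify_outcome",
    "extract_breathing",
    "analyze_trace",
    "read_trace",
    "write_trace",
]


class Membrane(str, Enum):
    PIA_ONLY = "pia_only"
    DURA_PIA = "dura_pia"


class Outcome(str, Enum):
    PENETRATED = "penetrated"
    BUCKLED = "buckled"
    INVALID = "invalid"


@dataclass
class DisplacementTrace:
    """Raw laser time series ``d_c`` (mm) sampled at a fixed period.

    ``start_index`` marks first wire-membrane contact; ``retraction_index``
    (optional) marks stage reversal.  ``insertion_rate`` is the stage feed
    in µm/s.
    """

    samples: NDArray[np.float64]
    sample_period: float = 0.002
    insertion_rate: float = 100.0
    start_index: int = 0
    retraction_index: int | None = None
    beam_name: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("trace must be a nonempty 1-D series")
        if self.retraction_index is not None and not (
            0 <= self.start_index < self.retraction_index <= self.samples.size
        ):
            raise ValueError("require 0 <= start_index < retraction_index <= length")

    @property
    def time(self) -> NDArray[np.float64]:
        return np.arange(self.samples.size) * self.sample_period


@dataclass
class ForceProfile:
    """Derived channels of one insertion, all the same length.

    time (s), force ``F_i`` (mN), loadpoint_deflection ``d_l`` (mm),
    stage_displacement ``d_t`` (mm) and dimpling ``d_i = d_t - d_l`` (mm).
    """

    time: NDArray[np.float64]
    force: NDArray[np.float64]
    loadpoint_deflection: NDArray[np.float64]
    stage_displacement: NDArray[np.float64]
    dimpling: NDArray[np.float64]
    start_index: int = 0
    retraction_index: int | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("force", "loadpoint_deflection", "stage_displacement", "dimpling"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel '{name}' length mismatch")

    @property
    def sample_period(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.002


@dataclass(frozen=True)
class RuptureEvent:
    """Membrane rupture: where the force fell off its running maximum."""

    index: int
    rupture_force: float
    dimpling_at_rupture: float
    drop_magnitude: float


@dataclass
class InsertionTrial:
    """One insertion's bookkeeping: hardware, membrane, outcome, rupture."""

    wire: WireSpec | None
    membrane: Membrane
    beam_name: str | None
    outcome: Outcome
    rupture: RuptureEvent | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.outcome is Outcome.PENETRATED) != (self.rupture is not None):
            raise ValueError("outcome is 'penetrated' iff a rupture event is present")


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds for rupture/buckling detection.

    drop_fraction : relative force drop (of the running max) that counts as
        rupture; 0.05 by default.
    drop_window_s : the drop must complete within this window (s); 0.1 —
        an order of magnitude faster than breathing.
    min_drop_mn : absolute drop floor (mN) so breathing cannot trip the
        relative criterion while the running max is still small.
    plateau_window_s / plateau_slope_mn_s : a trace "plateaus" when the
        fitted force slope over the trailing window is below this (mN/s).
    buckling_tolerance : relative band around the wire's Euler load within
        which a plateau is called buckling.
    contact_noise_mult : contact is declared where force first exceeds this
        multiple of the pre-contact noise sd (used when start_index unknown).
    """

    drop_fraction: float = 0.05
    drop_window_s: float = 0.1
    min_drop_mn: float = 0.2
    plateau_window_s: float = 2.0
    plateau_slope_mn_s: float = 0.05
    buckling_tolerance: float = 0.30
    contact_noise_mult: float = 3.0


@dataclass(frozen=True)
class BreathingEstimate:
    period: float
    amplitude: float


def convert_trace(
    trace: DisplacementTrace,
    calib: CalibrationMap,
    laser: LaserSpec | None = None,
) -> ForceProfile:
    """Convert a laser trace into force / deflection / stage / dimpling channels.

    ``force = (F_i/d_c) d_c`` and ``d_l = (d_l/d_c) d_c``; the stage channel
    ramps at the insertion rate from ``start_index`` and back down after
    ``retraction_index``.  Readings at or beyond the laser range set the
    ``saturated`` flag (they are never clipped silently).
    """
    d_c = trace.samples
    t = trace.time
    force = calib.force_per_laser_deflection * d_c
    d_l = calib.loadpoint_per_laser_deflection * d_c

    rate_mm_s = trace.insertion_rate * 1e-3
    t0 = t[trace.start_index]
    d_t = np.clip((t - t0) * rate_mm_s, 0.0, None)
    if trace.retraction_index is not None:
        tr = t[trace.retraction_index]
        peak = (tr - t0) * rate_mm_s
        after = t > tr
        d_t[after] = np.clip(peak - (t[after] - tr) * rate_mm_s, 0.0, None)

    saturated = False
    if laser is not None:
        saturated = bool(np.any(d_c >= laser.range / 1e-3 - 1e-12))

    return ForceProfile(
        time=t,
        force=force,
        loadpoint_deflection=d_l,
        stage_displacement=d_t,
        dimpling=d_t - d_l,
        start_index=trace.start_index,
        retraction_index=trace.retraction_index,
        saturated=saturated,
    )


def detect_rupture(
    profile: ForceProfile, cfg: DetectionConfig = DetectionConfig()
) -> RuptureEvent | None:
    """First qualifying force drop before retraction, or ``None``.

    A drop qualifies when the force falls, within ``drop_window_s`` of a
    sample sitting at the running maximum (a fresh peak), by at least
    ``max(drop_fraction * running_max, min_drop_mn)``.  Requiring the fall
    to start from the running maximum and complete inside the short window
    separates rupture from the much slower breathing decline off a crest.
    The rupture force is that pre-drop maximum and the dimpling is read at
    the same sample.
    """
    stop = profile.retraction_index if profile.retraction_index is not None else profile.force.size
    seg = profile.force[profile.start_index : stop]
    if seg.size < 3:
        return None

    dt = profile.sample_period
    w = max(2, int(round(cfg.drop_window_s / dt)) + 1)
    running_max = np.maximum.accumulate(seg)

    if seg.size >= w:
        fwd_min = np.empty_like(seg)
        fwd_min[: seg.size - w + 1] = np.lib.stride_tricks.sliding_window_view(seg, w).min(axis=1)
        # tail windows are truncated at the segment end
        fwd_min[seg.size - w + 1 :] = np.minimum.accumulate(seg[seg.size - w + 1 :][::-1])[::-1]
    else:
        fwd_min = np.minimum.accumulate(seg[::-1])[::-1]

    # "fresh peak": at (or within sensor noise of) the running maximum
    at_peak = seg >= running_max - np.maximum(0.01 * running_max, 0.01)
    drop = seg - fwd_min
    threshold = np.maximum(cfg.drop_fraction * running_max, cfg.min_drop_mn)
    hits = np.nonzero(at_peak & (drop >= threshold))[0]
    if hits.size == 0:
        return None

    i0 = int(hits[0])
    # the rupture crest is the highest sample inside the triggering window
    peak_local = i0 + int(np.argmax(seg[i0 : i0 + w]))
    peak = profile.start_index + peak_local
    return RuptureEvent(
        index=peak,
        rupture_force=float(seg[peak_local]),
        dimpling_at_rupture=float(profile.dimpling[peak]),
        drop_magnitude=float(seg[peak_local] - fwd_min[i0]),
    )


def classify_outcome(
    profile: ForceProfile,
    wire: WireSpec,
    cfg: DetectionConfig = DetectionConfig(),
) -> tuple[Outcome, RuptureEvent | None, dict]:
    """Classify an insertion as penetrated / buckled / invalid.

    Penetrated when a rupture event is found.  Buckled when, instead of a
    drop, the force plateaus (fitted slope below ``plateau_slope_mn_s`` over
    the trailing ``plateau_window_s``) at a level within
    ``buckling_tolerance`` of the wire's Euler critical load — the force a
    buckled column can sustain.  Anything else is invalid, with the reason
    in the diagnostics dict.
    """
    event = detect_rupture(profile, cfg)
    if event is not None:
        return Outcome.PENETRATED, event, {}

    stop = profile.retraction_index if profile.retraction_index is not None else profile.force.size
    dt = profile.sample_period
    w = max(3, int(round(cfg.plateau_window_s / dt)))
    seg = profile.force[max(profile.start_index, stop - w) : stop]
    if seg.size < 3:
        return Outcome.INVALID, None, {"reason": "segment too short"}

    tseg = np.arange(seg.size) * dt
    slope = float(np.polyfit(tseg, seg, 1)[0])
    level = float(np.mean(seg))
    euler = critical_buckling_load(wire)
    diagnostics = {"plateau_slope_mn_s": slope, "plateau_level_mn": level, "euler_load_mn": euler}
    if abs(slope) <= cfg.plateau_slope_mn_s and abs(level - euler) <= cfg.buckling_tolerance * euler:
        return Outcome.BUCKLED, None, diagnostics
    diagnostics["reason"] = "no rupture drop and no plateau near the Euler load"
    return Outcome.INVALID, None, diagnostics


def extract_breathing(
    profile: ForceProfile, min_duration_s: float = 4.0
) -> BreathingEstimate | None:
    """Dominant breathing oscillation of the pre-rupture force segment.

    Returns the period (s) and amplitude (mN) of the strongest spectral
    component of the linearly detrended force between contact and rupture
    (or retraction), refined by harmonic least squares around the coarse
    periodogram peak.  ``None`` when the segment is shorter than
    ``min_duration_s``.
    """
    event = detect_rupture(profile)
    stop = event.index if event is not None else (
        profile.retraction_index if profile.retraction_index is not None else profile.force.size
    )
    seg = profile.force[profile.start_index : stop]
    dt = profile.sample_period
    if seg.size * dt < min_duration_s:
        return None

    detrended = signal.detrend(seg, type="linear")
    fs = 1.0 / dt
    freqs, power = signal.periodogram(detrended, fs=fs)
    band = (freqs >= 0.2) & (freqs <= 5.0)
    if not np.any(band):
        return None
    f0 = float(freqs[band][np.argmax(power[band])])

    # refine frequency and read amplitude by harmonic regression
    t = np.arange(seg.size) * dt
    df = freqs[1] - freqs[0]
    best = (np.inf, f0, 0.0)
    for f in np.linspace(max(f0 - df, 0.05), f0 + df, 41):
        design = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
        coef, res, *_ = np.linalg.lstsq(design, detrended, rcond=None)
        rss = float(res[0]) if res.size else float(np.sum((detrended - design @ coef) ** 2))
        if rss < best[0]:
            best = (rss, f, float(np.hypot(*coef)))
    _, f_hat, amplitude = best
    return BreathingEstimate(period=1.0 / f_hat, amplitude=amplitude)


def analyze_trace(
    trace: DisplacementTrace,
    calib: CalibrationMap,
    wire: WireSpec,
    membrane: Membrane,
    cfg: DetectionConfig = DetectionConfig(),
    laser: LaserSpec | None = None,
) -> InsertionTrial:
    """Full per-trace analysis: convert, detect, classify, summarize."""
    profile = convert_trace(trace, calib, laser=laser)
    outcome, event, diagnostics = classify_outcome(profile, wire, cfg)
    breathing = extract_breathing(profile)
    if breathing is not None:
        diagnostics["breathing_period_s"] = breathing.period
        diagnostics["breathing_amplitude_mn"] = breathing.amplitude
    if profile.saturated:
        diagnostics["saturated"] = True
    return InsertionTrial(
        wire=wire,
        membrane=membrane,
        beam_name=trace.beam_name,
        outcome=outcome,
        rupture=event,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# delimited-text trace files: "# key = value" header, then "time_s,d_c_mm"

_HEADER_KEYS = ("sample_period", "insertion_rate", "start_index", "retraction_index", "beam_name")


def write_trace(path, trace: DisplacementTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_period = {trace.sample_period}\n")
        fh.write(f"# insertion_rate = {trace.insertion_rate}\n")
        fh.write(f"# start_index = {trace.start_index}\n")
        if trace.retraction_index is not None:
            fh.write(f"# retraction_index = {trace.retraction_index}\n")
        if trace.beam_name is not None:
            fh.write(f"# beam_name = {trace.beam_name}\n")
        fh.write("time_s,d_c_mm\n")
        for t, d in zip(trace.time, trace.samples):
            fh.write(f"{t:.6f},{d:.9f}\n")


def read_trace(path) -> DisplacementTrace:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
    unknown = set(meta) - set(_HEADER_KEYS)
    if unknown:
        raise ValueError(f"unknown trace header keys: {sorted(unknown)}")
    return DisplacementTrace(
        samples=data[:, 1],
        sample_period=float(meta.get("sample_period", 0.002)),
        insertion_rate=float(meta.get("insertion_rate", 100.0)),
        start_index=int(meta.get("start_index", 0)),
        retraction_index=int(meta["retraction_index"]) if "retraction_index" in meta else None,
        beam_name=meta.get("beam_name"),
    )
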