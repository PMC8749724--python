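"""Synthetic mechatronic breathing platform.

Generates ground-truth abdominal breathing motion (triangular linear
displacement driven by a stepper with a finite step quantum), scheduled
apnea pauses (absence of motion), impulsive hammer-style vibration noise,
and renders everything through accelerometer / infrared sensor models into
a multichannel recording with a known truth timeline.

The geometry convention: the motion axis lies in the x-z plane at an angle
``theta`` (degrees) from the x axis, so ``theta = 90`` means motion purely
along z (supine analogue) and 45/135 split the energy across two axes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

G_MS2 = 9.80665  # m/s^2 per g

__all__ = [
    "BreathingProtocol",
    "NoiseModel",
    "SensorModel",
    "SimRecording",
    "breathing_displacement",
    "displacement_to_body_accel",
    "hammer_noise",
    "couple_noise",
    "accelerometer_read",
    "accelerometer_decode",
    "adc_sensitivity",
    "ir_read",
    "simulate_recording",
    "random_apnea_schedule",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BreathingProtocol:
    """Commanded motion: what the stepper is told to do.

    Parameters
    ----------
    amplitude_um : float
        Peak displacement of one breath cycle, micrometres. The platform's
        standard band is 500-1500 um.
    rate_bpm : float
        Breathing rate, breaths per minute (0 < rate <= 120).
    n_breaths : int
        Number of commanded breath cycles.
    apnea_events : list of (start_s, duration_s)
        Scheduled pauses (motion frozen), in recording time. Protocol-
        standard apnea events last at least 20 s.
    angle_deg : float
        Body-position angle of the motion axis in the x-z plane.
    step_resolution_um : float
        Stepper quantum; every displacement sample is an integer multiple.
    """

    amplitude_um: float = 1000.0
    rate_bpm: float = 40.0
    n_breaths: int = 100
    apnea_events: list[tuple[float, float]] = field(default_factory=list)
    angle_deg: float = 90.0
    step_resolution_um: float = 0.11

    def __post_init__(self) -> None:
        if not 0 < self.rate_bpm <= 120:
            raise ValueError(f"rate_bpm must be in (0, 120], got {self.rate_bpm}")
        if self.amplitude_um <= 0:
            raise ValueError("amplitude_um must be positive")
        if self.step_resolution_um <= 0:
            raise ValueError("step_resolution_um must be positive")
        if self.n_breaths < 0:
            raise ValueError("n_breaths must be non-negative")
        ev = sorted((float(s), float(d)) for s, d in self.apnea_events)
        for (s, d) in ev:
            if s < 0 or d <= 0:
                raise ValueError(f"invalid apnea event ({s}, {d})")
        for (s0, d0), (s1, _) in zip(ev, ev[1:]):
            if s0 + d0 > s1:
                raise ValueError("apnea events overlap")
        self.apnea_events = ev

    @property
    def breath_period_s(self) -> float:
        return 60.0 / self.rate_bpm

    @property
    def duration_s(self) -> float:
        """Total recording time: breathing time plus all pauses."""
        return self.n_breaths * self.breath_period_s + sum(
            d for _, d in self.apnea_events
        )


@dataclass
class NoiseModel:
    """Impulsive vibration source (servo hammer analogue) and its coupling.

    Strikes arrive as a Poisson process; each strike is a damped sinusoid
    with a log-normally distributed peak amplitude (median
    ``amplitude_scale_g``). The ceiling channel sees the source directly;
    bed and body channels receive linearly attenuated copies.
    """

    strike_rate_hz: float = 0.16
    amplitude_scale_g: float = 0.0068
    amplitude_sigma: float = 0.95
    ring_freq_hz: float = 45.0
    decay_tau_s: float = 0.12
    coupling_bed: float = 0.55
    coupling_body: float = 0.06

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_bed <= 1.0:
            raise ValueError("coupling_bed must be in [0, 1]")
        if not 0.0 <= self.coupling_body <= 1.0:
            raise ValueError("coupling_body must be in [0, 1]")
        for name in ("strike_rate_hz", "amplitude_scale_g", "amplitude_sigma",
                     "ring_freq_hz", "decay_tau_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SensorModel:
    """Acquisition chain: ADC quantizer plus the IR proximity transfer.

    The accelerometer is a uniform mid-tread quantizer mapping
    [-range_g, +range_g] onto [0, 2**adc_bits - 1]; zero g maps to the
    mid-scale code. The IR sensor follows the classic inverse-distance
    approximation V = gain / (d + offset) with additive Gaussian noise.
    """

    adc_bits: int = 12
    range_g: float = 3.0
    sample_rate_hz: float = 4000.0
    ir_gain_vcm: float = 12.0
    ir_offset_cm: float = 0.42
    ir_noise_sd_v: float = 0.004
    ir_base_distance_cm: float = 4.0
    include_gravity: bool = True
    damping_cutoff_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.adc_bits < 8:
            raise ValueError("adc_bits must be >= 8")
        if self.range_g <= 0:
            raise ValueError("range_g must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def lsb_g(self) -> float:
        """Width of one ADC code in g."""
        return 2.0 * self.range_g / 2 ** self.adc_bits

    @property
    def mid_code(self) -> int:
        return 2 ** (self.adc_bits - 1)


@dataclass
class SimRecording:
    """A multichannel sampled recording plus its ground-truth timeline.

    ``channels`` holds the six acquired series: body_x/y/z, bed_z,
    ceiling_z as integer ADC codes and ir as volts. ``breaths`` and
    ``apneas`` are (start_s, end_s) intervals in recording time.
    """

    sample_rate_hz: float
    channels: dict[str, np.ndarray]
    breaths: list[tuple[float, float]]
    apneas: list[tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time})
        for name, series in self.channels.items():
            df[name] = series
        return df

    def save(self, path: str | Path) -> None:
        """Write channels as CSV and the truth/metadata as a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "sample_rate_hz": self.sample_rate_hz,
            "breaths": self.breaths,
            "apneas": self.apneas,
            "metadata": self.metadata,
        }
        path.with_suffix(".truth.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SimRecording":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".truth.json").read_text())
        channels = {}
        for col in df.columns:
            if col == "time_s":
                continue
            series = df[col].to_numpy()
            if col != "ir":
                series = series.astype(np.int64)
            channels[col] = series
        return cls(
            sample_rate_hz=sidecar["sample_rate_hz"],
            channels=channels,
            breaths=[tuple(b) for b in sidecar["breaths"]],
            apneas=[tuple(a) for a in sidecar["apneas"]],
            metadata=sidecar["metadata"],
        )


# ---------------------------------------------------------------------------
# Motion synthesis
# ---------------------------------------------------------------------------

def random_apnea_schedule(
    n_events: int,
    event_duration_s: float,
    breathing_time_s: float,
    rng: np.random.Generator,
    margin_s: float = 5.0,
) -> list[tuple[float, float]]:
    """Draw ``n_events`` non-overlapping pause intervals.

    Starts are placed uniformly over the breathing portion of the
    recording, then spread out so that consecutive events do not overlap
    after earlier pauses shift later ones.
    """
    if n_events == 0:
        return []
    margin_s = min(margin_s, 0.25 * breathing_time_s)
    starts = np.sort(rng.uniform(margin_s, breathing_time_s - margin_s, n_events))
    events: list[tuple[float, float]] = []
    shift = 0.0
    for s in starts:
        start = float(s) + shift
        if events and start < events[-1][0] + events[-1][1]:
            start = events[-1][0] + events[-1][1] + margin_s
        events.append((start, float(event_duration_s)))
        shift += event_duration_s
    return events


def _motion_time(t: np.ndarray, apneas: Sequence[tuple[float, float]]) -> np.ndarray:
    """Map recording time to accumulated motion time (pauses removed)."""
    mt = t.astype(float).copy()
    # events do not overlap, so removed pause time is additive
    for start, dur in apneas:
        mt -= np.clip(t - start, 0.0, dur)
    return mt


def _recording_time(
    mt: float, apneas: Sequence[tuple[float, float]], inclusive: bool = False
) -> float:
    """Map a motion-time instant back to recording time.

    ``inclusive`` shifts an instant that coincides exactly with a pause
    start past the pause (a breath *starting* at that instant resumes
    after it; a breath *ending* there completed just before).
    """
    t = mt
    for start, dur in sorted(apneas):
        if t > start or (inclusive and t >= start):
            t += dur
    return t


def breathing_displacement(
    protocol: BreathingProtocol,
    duration_s: float | None = None,
    sample_rate_hz: float = 4000.0,
) -> np.ndarray:
    """Commanded displacement along the motion axis, micrometres.

    Each breath is a symmetric triangle 0 -> amplitude -> 0 (constant
    stepper speed per half-cycle); motion freezes inside scheduled apnea
    intervals; samples are quantized to the stepper's step resolution.
    """
    if duration_s is None:
        duration_s = protocol.duration_s
    needed = protocol.duration_s
    if duration_s + 1e-9 < needed:
        raise ValueError(
            f"duration {duration_s:.2f}s does not cover {protocol.n_breaths} "
            f"breaths plus apnea time ({needed:.2f}s)"
        )
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    mt = _motion_time(t, protocol.apnea_events)
    mt = np.clip(mt, 0.0, protocol.n_breaths * protocol.breath_period_s)
    phase = mt / protocol.breath_period_s  # cycles
    frac = phase - np.floor(phase)
    # completed commanded cycles sit exactly at zero displacement
    frac[phase >= protocol.n_breaths] = 0.0
    tri = np.where(frac < 0.5, 2.0 * frac, 2.0 * (1.0 - frac))
    disp = protocol.amplitude_um * tri
    step = protocol.step_resolution_um
    return np.round(disp / step) * step


def breath_boundaries(protocol: BreathingProtocol) -> list[tuple[float, float]]:
    """(start_s, end_s) of each commanded breath cycle in recording time."""
    bounds = []
    period = protocol.breath_period_s
    for k in range(protocol.n_breaths):
        t0 = _recording_time(k * period, protocol.apnea_events, inclusive=True)
        t1 = _recording_time((k + 1) * period, protocol.apnea_events)
        bounds.append((t0, t1))
    return bounds


def displacement_to_body_accel(
    displacement_um: np.ndarray,
    sample_rate_hz: float,
    angle_deg: float,
    damping_cutoff_hz: float = 10.0,
    include_gravity: bool = True,
) -> np.ndarray:
    """Render displacement into 3-axis body acceleration, in g.

    The motion acceleration (second derivative of displacement) is
    low-pass filtered by a 2nd-order Butterworth — the soft clothing /
    mattress layer — then projected onto the sensor axes by the unit
    vector (cos theta, 0, sin theta). With ``include_gravity`` a static
    1 g projection is added on the same axes.

    Returns an array of shape (3, n): x, y, z in g.
    """
    if damping_cutoff_hz <= 0:
        raise ValueError("damping_cutoff_hz must be positive")
    dt = 1.0 / sample_rate_hz
    disp_m = np.asarray(displacement_um, dtype=float) * 1e-6
    vel = np.gradient(disp_m, dt)
    acc = np.gradient(vel, dt) / G_MS2  # g
    sos = signal.butter(2, damping_cutoff_hz, fs=sample_rate_hz, output="sos")
    acc = signal.sosfiltfilt(sos, acc)
    theta = math.radians(angle_deg)
    u = np.array([math.cos(theta), 0.0, math.sin(theta)])
    axes = u[:, None] * acc[None, :]
    if include_gravity:
        axes = axes + u[:, None]
    return axes


# ---------------------------------------------------------------------------
# Noise synthesis and coupling
# ---------------------------------------------------------------------------

def hammer_noise(
    model: NoiseModel,
    duration_s: float,
    sample_rate_hz: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Ceiling-channel vibration, in g: damped sinusoid bursts at Poisson
    arrival times with log-normal peak amplitudes. Deterministic per seed."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    out = np.zeros(n)
    if model.strike_rate_hz == 0 or model.amplitude_scale_g == 0:
        return out
    n_strikes = rng.poisson(model.strike_rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, n_strikes))
    amps = model.amplitude_scale_g * rng.lognormal(0.0, model.amplitude_sigma, n_strikes)
    burst = strike_waveform(model, sample_rate_hz)
    ring_len = len(burst)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * sample_rate_hz))
        seg = min(ring_len, n - i0)
        if seg > 0:
            out[i0 : i0 + seg] += a * burst[:seg]
    return out


def strike_waveform(model: NoiseModel, sample_rate_hz: float) -> np.ndarray:
    """Unit-amplitude waveform of one hammer strike: a damped sinusoid
    truncated at six decay constants."""
    ring_len = int(round(6.0 * model.decay_tau_s * sample_rate_hz))
    t_rel = np.arange(ring_len) / sample_rate_hz
    return np.exp(-t_rel / model.decay_tau_s) * np.sin(
        2.0 * np.pi * model.ring_freq_hz * t_rel
    )


def couple_noise(
    ceiling: np.ndarray, model: NoiseModel
) -> tuple[np.ndarray, np.ndarray]:
    """Attenuated copies of the ceiling vibration on bed and body channels."""
    return model.coupling_bed * ceiling, model.coupling_body * ceiling


# ---------------------------------------------------------------------------
# Sensor models
# ---------------------------------------------------------------------------

def accelerometer_read(accel_g: np.ndarray, sensor: SensorModel) -> np.ndarray:
    """Quantize true acceleration (g) to integer ADC codes.

    Mid-tread uniform quantizer: 0 g -> mid-scale code; values outside
    +/-range_g clip to the rails.
    """
    codes = np.rint(np.asarray(accel_g, dtype=float) / sensor.lsb_g) + sensor.mid_code
    return np.clip(codes, 0, 2 ** sensor.adc_bits - 1).astype(np.int64)


def accelerometer_decode(codes: np.ndarray, sensor: SensorModel) -> np.ndarray:
    """Inverse of :func:`accelerometer_read` to within half a code."""
    return (np.asarray(codes, dtype=float) - sensor.mid_code) * sensor.lsb_g


def adc_sensitivity(adc_bits: int, range_g: float) -> tuple[int, float]:
    """Sensitivity (LSB/g) and scale factor (mg/LSB) of the quantizer.

    Both figures are truncated the way accelerometer datasheets print
    them: sensitivity to an integer count, scale factor to two decimals.
    For the 12-bit +/-3 g chain this gives (682, 1.46).
    """
    if adc_bits < 1:
        raise ValueError("adc_bits must be >= 1")
    if range_g <= 0:
        raise ValueError("range_g must be positive")
    lsb_per_g = int(2 ** adc_bits / (2.0 * range_g))
    scale_mg = math.trunc(2.0 * range_g * 1000.0 / 2 ** adc_bits * 100.0) / 100.0
    return lsb_per_g, scale_mg


def ir_read(
    distance_cm: np.ndarray,
    sensor: SensorModel,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """IR proximity voltage: V = gain / (d + offset) plus Gaussian noise.

    Monotone decreasing in distance when noise-free.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d <= -sensor.ir_offset_cm):
        raise ValueError("non-physical distance: d must exceed -ir_offset_cm")
    v = sensor.ir_gain_vcm / (d + sensor.ir_offset_cm)
    if sensor.ir_noise_sd_v > 0 and seed is not None:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        v = v + rng.normal(0.0, sensor.ir_noise_sd_v, v.shape)
    return v


# ---------------------------------------------------------------------------
# Full recording
# ---------------------------------------------------------------------------

def simulate_recording(
    condition: tuple[float, float],
    protocol: BreathingProtocol,
    noise: NoiseModel,
    sensor: SensorModel,
    seed: int,
) -> SimRecording:
    """Compose motion, noise, and sensor models into one recording.

    ``condition`` is (angle_deg, amplitude_um) and overrides the protocol's
    own angle/amplitude, so one protocol can sweep the 3 x 3 grid. The seed
    fully determines the recording.
    """
    angle_deg, amplitude_um = condition
    proto = BreathingProtocol(
        amplitude_um=float(amplitude_um),
        rate_bpm=protocol.rate_bpm,
        n_breaths=protocol.n_breaths,
        apnea_events=list(protocol.apnea_events),
        angle_deg=float(angle_deg),
        step_resolution_um=protocol.step_resolution_um,
    )
    fs = sensor.sample_rate_hz
    duration = proto.duration_s
    ss = np.random.SeedSequence(int(seed))
    rng_hammer, rng_ir = [np.random.default_rng(s) for s in ss.spawn(2)]

    disp = breathing_displacement(proto, duration, fs)
    body = displacement_to_body_accel(
        disp, fs, proto.angle_deg, sensor.damping_cutoff_hz, sensor.include_gravity
    )
    ceiling = hammer_noise(noise, duration, fs, rng_hammer)
    bed, body_add = couple_noise(ceiling, noise)
    body = body.copy()
    body[2] += body_add  # vibration couples into the vertical axis
    grav = 1.0 if sensor.include_gravity else 0.0
    channels = {
        "body_x": accelerometer_read(body[0], sensor),
        "body_y": accelerometer_read(body[1], sensor),
        "body_z": accelerometer_read(body[2], sensor),
        "bed_z": accelerometer_read(bed + grav, sensor),
        "ceiling_z": accelerometer_read(ceiling + grav, sensor),
        "ir": ir_read(sensor.ir_base_distance_cm - disp * 1e-4, sensor, rng_ir),
    }
    return SimRecording(
        sample_rate_hz=fs,
        channels=channels,
        breaths=breath_boundaries(proto),
        apneas=list(proto.apnea_events),
        metadata={
            "angle_deg": proto.angle_deg,
            "amplitude_um": proto.amplitude_um,
            "rate_bpm": proto.rate_bpm,
            "n_breaths": proto.n_breaths,
            "seed": int(seed),
            "temperature_c": None,
            "humidity_pct": None,
        },
    )
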