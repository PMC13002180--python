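"""Synthetic ground-truth recordings on a planar high-density probe.

Point-source neurons are placed near a planar multi-electrode array and
their spikes are rendered onto the channels with a monopole (1/d) amplitude
decay, per-spike amplitude modulation, and additive Gaussian noise.
Electrode degradation replaces a fraction of channels with pure noise.

Units are fixed package-wide: µm for space, µV for voltage, seconds for
time, Hz for rates.  The probe plane sits at z = 0 and neurons live at
z >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbeGeometry",
    "GroundTruthUnit",
    "Recording",
    "DegradationPlan",
    "make_probe",
    "sample_ground_truth",
    "spike_shape",
    "clean_template",
    "render_recording",
    "degrade",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeGeometry:
    """Planar electrode array: per-channel (x, y, z) positions in µm.

    All channels share the same z (the array plane); z is the axis
    orthogonal to the array.
    """

    channel_ids: np.ndarray  # (n,) int
    positions: np.ndarray  # (n, 3) float, µm
    name: str = "probe"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_ids", np.asarray(self.channel_ids, dtype=int))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if self.channel_ids.ndim != 1:
            raise ValueError("channel_ids must be 1-D")
        if self.positions.shape != (self.channel_ids.size, 3):
            raise ValueError("positions must have shape (n_channels, 3)")
        if np.unique(self.channel_ids).size != self.channel_ids.size:
            raise ValueError("channel_ids must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        z = self.positions[:, 2]
        if not np.allclose(z, z[0]):
            raise ValueError("probe must be planar: all channel z equal")

    @property
    def n_channels(self) -> int:
        return int(self.channel_ids.size)

    @property
    def plane_z(self) -> float:
        return float(self.positions[0, 2])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeGeometry):
            return NotImplemented
        return (
            np.array_equal(self.channel_ids, other.channel_ids)
            and np.array_equal(self.positions, other.positions)
        )


@dataclass(frozen=True)
class GroundTruthUnit:
    """A point-source neuron with known position and spike train."""

    unit_id: int
    position: tuple[float, float, float]  # µm
    base_amplitude: float  # ptp µV at the reference distance
    spike_times: np.ndarray  # seconds, strictly increasing
    # shape parameters of the canonical biphasic waveform
    trough_width_ms: float = 0.3
    peak_ratio: float = 0.35
    duration_ms: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "spike_times", np.asarray(self.spike_times, dtype=float))
        if self.position[2] < 0:
            raise ValueError("unit z must be >= 0 (one side of the planar probe)")
        st = self.spike_times
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("spike_times must be strictly increasing")


@dataclass
class Recording:
    """Channels x samples voltage traces in µV with probe geometry."""

    traces: np.ndarray  # (n_channels, n_samples) float32, µV
    sampling_rate: float  # Hz
    geometry: ProbeGeometry
    dead_mask: np.ndarray = None  # (n_channels,) bool, True = declared dead

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (channels x samples)")
        if self.traces.shape[0] != self.geometry.n_channels:
            raise ValueError("traces row count must equal geometry channel count")
        if self.dead_mask is None:
            self.dead_mask = np.zeros(self.traces.shape[0], dtype=bool)
        else:
            self.dead_mask = np.asarray(self.dead_mask, dtype=bool)
            if self.dead_mask.shape != (self.traces.shape[0],):
                raise ValueError("dead_mask length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class DegradationPlan:
    """Which channels were replaced by noise, and how."""

    fraction: float
    dead_channels: tuple[int, ...]  # channel ids
    noise_std: float  # µV
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Probe construction
# ---------------------------------------------------------------------------

#: default layout: staggered two-column array, Neuropixels-like
DEFAULT_PITCH_PLAN = {
    "layout": "staggered",
    "y_pitch_um": 20.0,
    "x_pitch_um": 32.0,
    "stagger_um": 16.0,
}


def make_probe(n_channels: int, pitch_plan: dict | None = None) -> ProbeGeometry:
    """Build a planar probe geometry.

    The default plan is a staggered two-column layout with 20 µm row pitch:
    384 channels span ~3.84 mm along y and under 60 µm along x.  A
    ``{"layout": "single_column", "pitch_um": ...}`` plan gives one column
    along y.

    Raises
    ------
    ValueError
        If ``n_channels < 4`` (triangulation needs at least 4 observations).
    """
    if n_channels < 4:
        raise ValueError("invalid geometry: need at least 4 channels")
    plan = dict(DEFAULT_PITCH_PLAN if pitch_plan is None else pitch_plan)
    layout = plan.get("layout", "staggered")
    ids = np.arange(n_channels)
    if layout == "single_column":
        pitch = float(plan.get("pitch_um", 20.0))
        pos = np.zeros((n_channels, 3))
        pos[:, 1] = ids * pitch
    elif layout == "staggered":
        y_pitch = float(plan.get("y_pitch_um", 20.0))
        x_pitch = float(plan.get("x_pitch_um", 32.0))
        stagger = float(plan.get("stagger_um", 16.0))
        pos = np.zeros((n_channels, 3))
        row = ids // 2
        col = ids % 2
        pos[:, 0] = col * x_pitch + (row % 2) * stagger
        pos[:, 1] = row * y_pitch
    else:
        raise ValueError(f"unknown probe layout: {layout!r}")
    return ProbeGeometry(channel_ids=ids, positions=pos, name=f"{layout}-{n_channels}")


# ---------------------------------------------------------------------------
# Ground truth units
# ---------------------------------------------------------------------------


def sample_ground_truth(
    geometry: ProbeGeometry,
    n_neurons: int,
    bounds: dict | None = None,
    rate_hz: float = 5.0,
    duration_s: float = 90.0,
    refractory_ms: float = 2.0,
    seed: int = 0,
    amplitude_median_uv: float = 100.0,
    amplitude_sigma: float = 0.3,
) -> list[GroundTruthUnit]:
    """Sample neurons near the probe with Poisson spike trains.

    Positions are uniform in a spatial box around the probe; the default
    box covers the probe's x-y extent padded by 30 µm, with z in
    [10, 100] µm.  Spike trains are homogeneous Poisson thinned by an
    absolute refractory period (the later spike is deleted).  Peak-to-peak
    amplitudes at the reference distance are lognormal.  Deterministic per
    seed.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if rate_hz <= 0 or duration_s < 0 or refractory_ms <= 0:
        raise ValueError("rate_hz and refractory_ms must be positive; duration_s >= 0")
    if bounds is None:
        p = geometry.positions
        pad = 30.0
        bounds = {
            "x": (p[:, 0].min() - pad, p[:, 0].max() + pad),
            "y": (p[:, 1].min() - pad, p[:, 1].max() + pad),
            "z": (10.0, 100.0),
        }
    for axis in ("x", "y", "z"):
        lo, hi = bounds[axis]
        if hi < lo:
            raise ValueError(f"empty bounds on axis {axis}")
    if bounds["z"][0] < 0:
        raise ValueError("z bounds must be nonnegative")

    rng = np.random.default_rng(seed)
    units = []
    for uid in range(n_neurons):
        x = rng.uniform(*bounds["x"])
        y = rng.uniform(*bounds["y"])
        z = rng.uniform(*bounds["z"])
        amp = amplitude_median_uv * np.exp(rng.normal(0.0, amplitude_sigma))
        n_expected = rng.poisson(rate_hz * duration_s) if duration_s > 0 else 0
        times = np.sort(rng.uniform(0.0, duration_s, size=n_expected))
        times = _thin_refractory(times, refractory_ms / 1000.0)
        # per-unit waveform shape variability
        trough_width = rng.uniform(0.2, 0.4)
        peak_ratio = rng.uniform(0.25, 0.5)
        units.append(
            GroundTruthUnit(
                unit_id=uid,
                position=(float(x), float(y), float(z)),
                base_amplitude=float(amp),
                spike_times=times,
                trough_width_ms=float(trough_width),
                peak_ratio=float(peak_ratio),
            )
        )
    return units


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Delete any spike closer than refractory_s to the previous kept spike."""
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] > refractory_s:
            kept.append(t)
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

#: reference distance at which base_amplitude is defined (µm)
D_REF_UM = 20.0


def spike_shape(
    sampling_rate: float,
    trough_width_ms: float = 0.3,
    peak_ratio: float = 0.35,
    duration_ms: float = 2.0,
) -> np.ndarray:
    """Canonical biphasic extracellular spike, unit peak-to-peak amplitude.

    A negative Gaussian trough followed by a smaller positive peak; total
    duration ``duration_ms``.  The trough sits at 1/3 of the window.
    """
    n = max(int(round(duration_ms / 1000.0 * sampling_rate)), 3)
    t = np.arange(n) / sampling_rate * 1000.0  # ms
    t_trough = duration_ms / 3.0
    t_peak = t_trough + 1.6 * trough_width_ms
    w = -np.exp(-0.5 * ((t - t_trough) / trough_width_ms) ** 2)
    w += peak_ratio * np.exp(-0.5 * ((t - t_peak) / (1.8 * trough_width_ms)) ** 2)
    return w / (w.max() - w.min())


def _channel_gains(
    unit: GroundTruthUnit,
    geometry: ProbeGeometry,
    decay_exponent: float,
    d_ref_um: float,
) -> np.ndarray:
    """Per-channel ptp of the unit's clean template (monopole-style decay)."""
    d = np.linalg.norm(geometry.positions - np.asarray(unit.position), axis=1)
    if np.any(d == 0):
        raise ValueError(
            f"unit {unit.unit_id} coincides with an electrode (distance 0): singular decay"
        )
    return unit.base_amplitude * (d_ref_um / d) ** decay_exponent


def clean_template(
    unit: GroundTruthUnit,
    geometry: ProbeGeometry,
    sampling_rate: float = 30000.0,
    decay_exponent: float = 1.0,
    d_ref_um: float = D_REF_UM,
) -> np.ndarray:
    """Noise-free channels x samples template of a unit (the oracle waveform)."""
    shape = spike_shape(
        sampling_rate, unit.trough_width_ms, unit.peak_ratio, unit.duration_ms
    )
    gains = _channel_gains(unit, geometry, decay_exponent, d_ref_um)
    return gains[:, None] * shape[None, :]


def render_recording(
    units: list[GroundTruthUnit],
    geometry: ProbeGeometry,
    duration_s: float | None = None,
    noise_std: float = 10.0,
    sampling_rate: float = 30000.0,
    amp_modulation_cv: float = 0.05,
    seed: int = 0,
    decay_exponent: float = 1.0,
    d_ref_um: float = D_REF_UM,
    dtype=np.float32,
) -> Recording:
    """Render units onto the probe: templates convolved with spike trains.

    Each spike adds the unit's clean template scaled by a per-spike
    lognormal modulation factor of coefficient of variation
    ``amp_modulation_cv`` (mean 1).  I.i.d. Gaussian noise of ``noise_std``
    µV is added to every sample.

    ``duration_s`` defaults to the last spike time plus the waveform
    length (or 1 s for noise-only renders).
    """
    if duration_s is None:
        last = max((u.spike_times[-1] for u in units if u.spike_times.size), default=0.0)
        duration_s = last + 0.005 if last > 0 else 1.0
    n_samples = int(round(duration_s * sampling_rate))
    rng = np.random.default_rng(seed)
    if noise_std > 0:
        traces = rng.standard_normal((geometry.n_channels, n_samples), dtype=np.float32)
        traces *= noise_std
        traces = traces.astype(dtype, copy=False)
    else:
        traces = np.zeros((geometry.n_channels, n_samples), dtype=dtype)

    if amp_modulation_cv > 0:
        # lognormal with mean 1 and sd = cv
        sigma2 = np.log(1.0 + amp_modulation_cv**2)
        mu, sigma = -sigma2 / 2.0, np.sqrt(sigma2)
    for unit in units:
        template = clean_template(
            unit, geometry, sampling_rate, decay_exponent, d_ref_um
        ).astype(dtype)
        wlen = template.shape[1]
        for t in unit.spike_times:
            start = int(round(t * sampling_rate))
            stop = min(start + wlen, n_samples)
            if start >= n_samples:
                continue
            mod = float(np.exp(rng.normal(mu, sigma))) if amp_modulation_cv > 0 else 1.0
            traces[:, start:stop] += mod * template[:, : stop - start]
    return Recording(traces=traces, sampling_rate=sampling_rate, geometry=geometry)


# ---------------------------------------------------------------------------
# Electrode degradation
# ---------------------------------------------------------------------------


def degrade(
    recording: Recording,
    fraction: float,
    noise_std: float = 50.0,
    seed: int = 0,
    cumulative: bool = False,
) -> tuple[Recording, DegradationPlan]:
    """Replace a random fraction of channels with Gaussian noise.

    ``round(fraction * n_channels)`` channels are drawn by a seeded
    permutation, so plans with the same seed are nested across levels
    (level k's dead set is a subset of level k+1's).  The input recording
    is not modified.

    With ``cumulative=True`` channels already marked dead stay dead and
    count toward the fraction; otherwise the input must have an all-false
    dead mask.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not cumulative and recording.dead_mask.any():
        raise ValueError("input already has dead channels; pass cumulative=True")
    n = recording.n_channels
    n_dead = int(round(fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    dead_idx = order[:n_dead]
    dead_ids = tuple(sorted(int(recording.geometry.channel_ids[i]) for i in dead_idx))
    plan = DegradationPlan(
        fraction=fraction, dead_channels=dead_ids, noise_std=noise_std, seed=seed
    )
    traces = recording.traces.copy()
    mask = recording.dead_mask.copy()
    if n_dead:
        noise_rng = np.random.default_rng(seed + 1)
        noise = noise_rng.standard_normal((n_dead, recording.n_samples), dtype=np.float32)
        noise *= noise_std
        traces[dead_idx] = noise.astype(traces.dtype, copy=False)
        mask[dead_idx] = True
    degraded = Recording(
        traces=traces,
        sampling_rate=recording.sampling_rate,
        geometry=recording.geometry,
        dead_mask=mask,
    )
    return degraded, plan
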