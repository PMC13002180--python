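"""Denoising and anomalous-channel detection.

The chain is a causal Butterworth bandpass, common median referencing,
and a two-test bad-channel detector: a neighbor-coherence test (a healthy
channel correlates with at least one nearby channel) and a band-power
outlier test (robust z-score of log high-frequency power).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import Recording

__all__ = [
    "ChannelStatus",
    "bandpass",
    "common_median_reference",
    "detect_anomalous_channels",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)

GOOD = "good"
ANOMALOUS_COHERENCE = "anomalous_coherence"
ANOMALOUS_POWER = "anomalous_power"
DECLARED_DEAD = "declared_dead"

_LABELS = (GOOD, ANOMALOUS_COHERENCE, ANOMALOUS_POWER, DECLARED_DEAD)


@dataclass
class ChannelStatus:
    """One label per channel."""

    channel_ids: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if len(self.labels) != self.channel_ids.size:
            raise ValueError("one label per channel required")
        for lab in self.labels:
            if lab not in _LABELS:
                raise ValueError(f"unknown channel label {lab!r}")

    @property
    def good_mask(self) -> np.ndarray:
        return np.array([lab == GOOD for lab in self.labels], dtype=bool)

    @property
    def bad_mask(self) -> np.ndarray:
        return ~self.good_mask


def butter_sos(
    low_hz: float, high_hz: float, sampling_rate: float, order: int = 5
) -> np.ndarray:
    """Design the band-pass filter in second-order sections."""
    nyq = sampling_rate / 2.0
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq} Hz)")
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(
    recording: Recording,
    low_hz: float = 300.0,
    high_hz: float = 3000.0,
    order: int = 5,
    causal: bool = True,
) -> Recording:
    """Butterworth band-pass, forward-only (causal) by default."""
    sos = butter_sos(low_hz, high_hz, recording.sampling_rate, order)
    filt = signal.sosfilt if causal else signal.sosfiltfilt
    traces = filt(sos, recording.traces, axis=1).astype(recording.traces.dtype)
    return Recording(
        traces=traces,
        sampling_rate=recording.sampling_rate,
        geometry=recording.geometry,
        dead_mask=recording.dead_mask.copy(),
    )


def common_median_reference(recording: Recording) -> Recording:
    """Subtract the per-sample median across channels from every channel."""
    if recording.n_channels < 2:
        raise ValueError("common median reference needs >= 2 channels")
    med = np.median(recording.traces, axis=0, keepdims=True)
    traces = (recording.traces - med).astype(recording.traces.dtype)
    return Recording(
        traces=traces,
        sampling_rate=recording.sampling_rate,
        geometry=recording.geometry,
        dead_mask=recording.dead_mask.copy(),
    )


def detect_anomalous_channels(
    recording: Recording,
    coherence_threshold: float = 0.2,
    n_neighbors: int = 4,
    psd_band: tuple[float, float] = (300.0, 3000.0),
    psd_z_threshold: float = 4.0,
    psd_min_scale: float = 0.25,
    chunk_s: float = 1.0,
) -> ChannelStatus:
    """Flag channels that decorrelate from their neighbors or whose band
    power is a robust outlier.

    A channel is ``anomalous_coherence`` when its maximum Pearson
    correlation with its ``n_neighbors`` nearest geometric neighbors falls
    below ``coherence_threshold`` while those neighbors do correlate among
    themselves (median pairwise correlation at or above the threshold) —
    i.e. the local tissue signal is coherent but this channel misses it.
    The gate keeps quiet array regions, where nearby channels share no
    signal to begin with, from being flagged wholesale.

    A channel is ``anomalous_power`` when the robust z-score of its log
    band power in ``psd_band`` exceeds ``psd_z_threshold`` in magnitude;
    the MAD-based scale is floored at ``psd_min_scale`` (log units) so a
    tightly clustered power distribution does not turn ordinary signal
    variation into outliers.

    Everything is evaluated on a band-passed chunk of ``chunk_s`` seconds.
    Channels already in the recording's dead mask come back
    ``declared_dead``.  Both tests are invariant to a global gain.
    """
    n = recording.n_channels
    n_chunk = int(round(chunk_s * recording.sampling_rate))
    if recording.n_samples < n_chunk:
        logger.warning(
            "recording shorter than analysis window (%d < %d samples); all channels good",
            recording.n_samples,
            n_chunk,
        )
        return ChannelStatus(recording.geometry.channel_ids, [GOOD] * n)

    chunk = np.asarray(recording.traces[:, :n_chunk], dtype=np.float64)
    sos = butter_sos(*psd_band, recording.sampling_rate)
    chunk = signal.sosfilt(sos, chunk, axis=1)

    # neighbor coherence: correlation matrix of unit-normalized channels
    pos = recording.geometry.positions
    centered = chunk - chunk.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    unit = centered / norms[:, None]
    corr = unit @ unit.T
    max_corr = np.full(n, np.inf)
    local_coherent = np.zeros(n, dtype=bool)
    k = min(n_neighbors, n - 1)
    for j in range(n):
        d = np.linalg.norm(pos - pos[j], axis=1)
        d[j] = np.inf
        if k < 1:
            continue
        nbrs = np.argpartition(d, k - 1)[:k]
        max_corr[j] = float(np.max(corr[nbrs, j]))
        if nbrs.size >= 2:
            pair = corr[np.ix_(nbrs, nbrs)][np.triu_indices(nbrs.size, 1)]
            local_coherent[j] = bool(np.median(pair) >= coherence_threshold)

    # band-power outlier: robust z of log power
    power = np.mean(chunk**2, axis=1)
    logp = np.log(np.maximum(power, 1e-30))
    med = np.median(logp)
    scale = max(1.4826 * np.median(np.abs(logp - med)), psd_min_scale)
    zscores = (logp - med) / scale

    labels = []
    for j in range(n):
        if recording.dead_mask[j]:
            labels.append(DECLARED_DEAD)
        elif local_coherent[j] and max_corr[j] < coherence_threshold:
            labels.append(ANOMALOUS_COHERENCE)
        elif abs(zscores[j]) > psd_z_threshold:
            labels.append(ANOMALOUS_POWER)
        else:
            labels.append(GOOD)
    return ChannelStatus(recording.geometry.channel_ids, labels)


def preprocess_recording(
    recording: Recording,
    low_hz: float = 300.0,
    high_hz: float = 3000.0,
    order: int = 5,
    detect: bool = False,
    **detect_kwargs,
) -> tuple[Recording, ChannelStatus | None]:
    """Bandpass + common median reference, optionally followed by detection."""
    out = common_median_reference(bandpass(recording, low_hz, high_hz, order))
    status = detect_anomalous_channels(out, **detect_kwargs) if detect else None
    return out, status
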