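"""Spike snippet extraction, alignment, templates and ptp amplitudes.

Ground-truth spike trains are required inputs by design: extraction never
detects spikes, it cuts a fixed temporal window around each known spike
time.  Channels marked dead or anomalous are carried as *absent* (NaN) in
ptp vectors, the single convention consumed by every localizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import Recording

__all__ = [
    "WaveformSet",
    "Template",
    "extract_snippets",
    "align_to_trough",
    "compute_template",
    "ptp_vector",
]

logger = logging.getLogger(__name__)


@dataclass
class WaveformSet:
    """Per-spike snippets of one unit: spikes x channels x samples (µV)."""

    unit_id: int
    snippets: np.ndarray
    window_ms: tuple[float, float]  # (pre_ms, post_ms)
    alignment_sample: int
    sampling_rate: float
    channel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.snippets = np.asarray(self.snippets, dtype=float)
        if self.snippets.ndim != 3:
            raise ValueError("snippets must be spikes x channels x samples")
        if not 0 <= self.alignment_sample < max(self.snippets.shape[2], 1):
            if self.snippets.shape[0]:
                raise ValueError("alignment_sample outside window")
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.snippets.shape[0] and self.snippets.shape[1] != self.channel_ids.size:
            raise ValueError("snippet channel axis must match channel_ids")

    @property
    def n_spikes(self) -> int:
        return self.snippets.shape[0]


@dataclass
class Template:
    """Median waveform of one unit and its per-channel ptp amplitudes."""

    unit_id: int
    waveform: np.ndarray  # channels x samples, µV
    ptp: np.ndarray  # per-channel, NaN where absent
    peak_channel: int  # channel id of argmax ptp (ties -> lowest id)
    channel_ids: np.ndarray


def extract_snippets(
    recording: Recording,
    spike_times: np.ndarray,
    unit_id: int = -1,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
) -> WaveformSet:
    """Cut one snippet per spike time; spikes too close to the edges are
    dropped (the drop count is logged)."""
    fs = recording.sampling_rate
    n_pre = int(round(pre_ms / 1000.0 * fs))
    n_post = int(round(post_ms / 1000.0 * fs))
    wlen = n_pre + n_post
    times = np.asarray(spike_times, dtype=float)
    snippets = []
    dropped = 0
    for t in times:
        center = int(round(t * fs))
        start, stop = center - n_pre, center + n_post
        if start < 0 or stop > recording.n_samples:
            dropped += 1
            continue
        snippets.append(recording.traces[:, start:stop].astype(float))
    if dropped:
        logger.info("dropped %d/%d spikes too close to recording edges", dropped, times.size)
    arr = (
        np.stack(snippets)
        if snippets
        else np.empty((0, recording.n_channels, wlen))
    )
    return WaveformSet(
        unit_id=unit_id,
        snippets=arr,
        window_ms=(pre_ms, post_ms),
        alignment_sample=n_pre,
        sampling_rate=fs,
        channel_ids=recording.geometry.channel_ids.copy(),
    )


def _peak_channel_index(waveform: np.ndarray) -> int:
    """Index of the channel with the largest ptp; ties -> lowest index."""
    ptp = waveform.max(axis=1) - waveform.min(axis=1)
    return int(np.argmax(ptp))


def align_to_trough(
    ws: WaveformSet, max_jitter_ms: float = 0.5, mode: str = "extremum"
) -> WaveformSet:
    """Shift each snippet so its global extremum on the peak channel sits at
    the alignment sample.

    The peak channel comes from a preliminary mean template across
    snippets.  ``mode`` selects the aligned feature: ``"extremum"``
    (largest |amplitude|, the default — extracellular spikes are
    trough-dominated), ``"trough"`` or ``"peak"``.  Shifts are integer
    samples bounded by ``max_jitter_ms``; vacated samples are zero-padded.
    Idempotent.
    """
    if ws.n_spikes == 0:
        return ws
    max_shift = int(round(max_jitter_ms / 1000.0 * ws.sampling_rate))
    chan = _peak_channel_index(ws.snippets.mean(axis=0))
    target = ws.alignment_sample
    n_samples = ws.snippets.shape[2]
    lo = max(target - max_shift, 0)
    hi = min(target + max_shift + 1, n_samples)
    out = np.zeros_like(ws.snippets)
    for i, snip in enumerate(ws.snippets):
        seg = snip[chan, lo:hi]
        if mode == "trough":
            idx = lo + int(np.argmin(seg))
        elif mode == "peak":
            idx = lo + int(np.argmax(seg))
        else:
            idx = lo + int(np.argmax(np.abs(seg)))
        shift = target - idx
        if shift == 0:
            out[i] = snip
        elif shift > 0:
            out[i, :, shift:] = snip[:, :-shift]
        else:
            out[i, :, :shift] = snip[:, -shift:]
    return WaveformSet(
        unit_id=ws.unit_id,
        snippets=out,
        window_ms=ws.window_ms,
        alignment_sample=ws.alignment_sample,
        sampling_rate=ws.sampling_rate,
        channel_ids=ws.channel_ids.copy(),
    )


def compute_template(ws: WaveformSet, absent_mask: np.ndarray | None = None) -> Template:
    """Element-wise median over spikes, with ptp and peak channel.

    ``absent_mask`` marks channels (dead or anomalous) whose ptp is
    reported as NaN rather than a number.
    """
    if ws.n_spikes == 0:
        raise ValueError("cannot compute a template from an empty WaveformSet")
    waveform = np.median(ws.snippets, axis=0)
    ptp = ptp_vector(waveform, absent_mask)
    if np.all(np.isnan(ptp)):
        peak = -1
    else:
        peak = int(ws.channel_ids[np.nanargmax(ptp)])
    return Template(
        unit_id=ws.unit_id,
        waveform=waveform,
        ptp=ptp,
        peak_channel=peak,
        channel_ids=ws.channel_ids.copy(),
    )


def ptp_vector(waveform: np.ndarray, absent_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-channel peak-to-peak amplitude max_t - min_t; absent channels NaN."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 2 or waveform.shape[1] < 1:
        raise ValueError("waveform must be channels x samples with >= 1 sample")
    ptp = waveform.max(axis=1) - waveform.min(axis=1)
    if absent_mask is not None:
        ptp = ptp.copy()
        ptp[np.asarray(absent_mask, dtype=bool)] = np.nan
    return ptp
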