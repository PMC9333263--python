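"""From raw voltage to stimulus-locked, baseline-normalized high-gamma activity.

Stages (in order): common average reference, epoching around stimulus onsets,
pooled-prestimulus z-normalization, an 8-band Butterworth/Hilbert filter bank
over 70–150 Hz whose per-band analytic amplitudes are z-scored against a
pooled baseline and averaged into a single broadband HGA trace, down-sampling
to 100 Hz, and per-stimulus averaging over presentations.

Conventions: sample indices are 0-based; time axes are in ms relative to
stimulus onset; every window is half-open ``[start, end)``.  At 100 Hz each
HGA sample is labelled by the start of its 10 ms bin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .config import AnalysisConfig, POST_OFFSET_MS
from .data_model import (
    ChannelInfo,
    ConsistencyError,
    DegenerateDataError,
    Recording,
)


@dataclass
class EpochedVoltage:
    """Trials × channels × time voltage epochs at the acquisition rate."""

    data: np.ndarray
    times_ms: np.ndarray
    sample_rate_hz: float
    channels: list[ChannelInfo]
    trial_stimulus_ids: list[str]
    task: str
    duration_ms: float


@dataclass
class EpochedHGA:
    """Trials × channels × time broadband HGA in baseline-z units at 100 Hz."""

    data: np.ndarray
    times_ms: np.ndarray
    rate_hz: float
    channels: list[ChannelInfo]
    trial_stimulus_ids: list[str]
    task: str
    duration_ms: float
    bands: list[tuple[float, float, int]]

    def channel_index(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise KeyError(channel_id)


@dataclass
class StimulusResponse:
    """Per-stimulus mean HGA (stimuli × channels × time) with presentation counts."""

    data: np.ndarray
    times_ms: np.ndarray
    rate_hz: float
    channels: list[ChannelInfo]
    stimulus_ids: list[str]
    presentation_counts: np.ndarray
    task: str
    duration_ms: float


# ---------------------------------------------------------------------------
# re-referencing and epoching
# ---------------------------------------------------------------------------

def apply_car(rec: Recording) -> Recording:
    """Common average reference: subtract the instantaneous across-channel mean.

    Removes noise shared across contacts; after CAR the across-channel mean is
    zero at every sample, and applying CAR twice is a no-op.
    """
    if rec.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    referenced = rec.voltage - rec.voltage.mean(axis=0, keepdims=True)
    return Recording(sample_rate_hz=rec.sample_rate_hz, voltage=referenced,
                     channels=list(rec.channels))


def epoch_voltage(
    rec: Recording,
    trials: pd.DataFrame,
    stimuli: pd.DataFrame,
    cfg: AnalysisConfig,
) -> EpochedVoltage:
    """Cut per-trial epochs from 1,000 ms before onset to the task-specific
    post-offset pad (1,450 ms for VL, 1,000 ms for NatS)."""
    tasks = stimuli["task"].unique()
    if len(tasks) != 1:
        raise ConsistencyError("stimulus table must describe a single task")
    task = str(tasks[0])
    duration_ms = float(stimuli["duration_ms"].iloc[0])
    post_ms = cfg.epoch_post_ms(task, duration_ms)

    fs = rec.sample_rate_hz
    pre = int(round(cfg.epoch_pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    onsets = trials["onset_sample"].to_numpy(dtype=int)

    bad = [
        int(tid)
        for tid, onset in zip(trials["trial_id"], onsets)
        if onset - pre < 0 or onset + post > rec.n_samples
    ]
    if bad:
        raise IndexError(f"epochs overrun the recording for trial ids {bad}")

    n_samples = pre + post
    data = np.empty((len(onsets), rec.n_channels, n_samples))
    for i, onset in enumerate(onsets):
        data[i] = rec.voltage[:, onset - pre : onset + post]
    times = (np.arange(n_samples) - pre) * 1000.0 / fs
    return EpochedVoltage(
        data=data,
        times_ms=times,
        sample_rate_hz=fs,
        channels=list(rec.channels),
        trial_stimulus_ids=list(trials["stimulus_id"]),
        task=task,
        duration_ms=duration_ms,
    )


def normalize_epochs(ep: EpochedVoltage, cfg: AnalysisConfig) -> EpochedVoltage:
    """Z-score each channel against its prestimulus period pooled across trials."""
    pre_mask = ep.times_ms < 0
    if not pre_mask.any():
        raise ValueError("epochs contain no prestimulus samples")
    baseline = ep.data[:, :, pre_mask]  # trials × channels × pre-samples
    mean = baseline.mean(axis=(0, 2))
    sd = baseline.std(axis=(0, 2))
    degenerate = [ep.channels[i].channel_id for i in np.flatnonzero(sd == 0)]
    if degenerate:
        raise DegenerateDataError(f"zero prestimulus variance in channels {degenerate}")
    data = (ep.data - mean[None, :, None]) / sd[None, :, None]
    return replace(ep, data=data)


# ---------------------------------------------------------------------------
# high-gamma extraction
# ---------------------------------------------------------------------------

def make_filter_bank(cfg: AnalysisConfig, sample_rate_hz: float = 1000.0,
                     ) -> list[tuple[float, float, int]]:
    """Log-spaced bandpass bank: centers 70→150 Hz, bandwidths 16→64 Hz.

    Both progressions are geometric over ``n_bands`` points, endpoints
    inclusive; band *i* spans ``center ± bandwidth/2``.
    """
    n = cfg.n_bands
    if n < 2:
        raise ValueError("n_bands must be >= 2")
    i = np.arange(n)
    centers = cfg.hga_low_hz * (cfg.hga_high_hz / cfg.hga_low_hz) ** (i / (n - 1))
    widths = cfg.bandwidth_low_hz * (cfg.bandwidth_high_hz / cfg.bandwidth_low_hz) ** (i / (n - 1))
    nyquist = sample_rate_hz / 2.0
    bank = []
    for c, w in zip(centers, widths):
        if c + w / 2.0 >= nyquist:
            raise ValueError(f"band edge {c + w / 2.0:.1f} Hz at or above Nyquist {nyquist} Hz")
        bank.append((float(c), float(w), cfg.filter_order))
    return bank


def extract_hga(ep: EpochedVoltage, cfg: AnalysisConfig) -> EpochedHGA:
    """Filter-bank Hilbert estimate of broadband high-gamma activity.

    Per band: zero-phase (forward–reverse) Butterworth bandpass, analytic
    amplitude, then a z-transform against the pooled baseline of all trials.
    The baseline excludes the earliest 100 ms of the prestimulus span (filter
    edge effects) and the 100 ms immediately before onset (low-latency
    responses).  HGA is the mean of the 8 normalized bands, averaged into
    10 ms bins (100 Hz) and clipped to ``[-900, offset + 900)`` ms.
    """
    fs = ep.sample_rate_hz
    bank = make_filter_bank(cfg, fs)
    n_trials, n_channels, n_time = ep.data.shape
    warmup_ms = cfg.baseline_edge_discard_ms + 50.0
    if cfg.epoch_pre_ms < warmup_ms:
        raise ValueError("epoch prestimulus span too short for filter warm-up")

    base_lo = -cfg.epoch_pre_ms + cfg.baseline_edge_discard_ms
    base_hi = -cfg.baseline_edge_discard_ms
    base_mask = (ep.times_ms >= base_lo) & (ep.times_ms < base_hi)

    flat = ep.data.reshape(n_trials * n_channels, n_time)
    hga = np.zeros((n_trials, n_channels, n_time))
    for center, width, order in bank:
        sos = signal.butter(
            order, [center - width / 2.0, center + width / 2.0],
            btype="bandpass", fs=fs, output="sos",
        )
        filtered = signal.sosfiltfilt(sos, flat, axis=-1)
        amplitude = np.abs(signal.hilbert(filtered, axis=-1))
        amplitude = amplitude.reshape(n_trials, n_channels, n_time)
        baseline = amplitude[:, :, base_mask]
        mu = baseline.mean(axis=(0, 2))
        sd = baseline.std(axis=(0, 2))
        if np.any(sd == 0):
            raise DegenerateDataError("zero baseline variance in a band amplitude")
        hga += (amplitude - mu[None, :, None]) / sd[None, :, None]
    hga /= len(bank)

    # down-sample by averaging non-overlapping bins
    factor = int(round(fs / cfg.hga_output_rate_hz))
    n_bins = n_time // factor
    binned = hga[:, :, : n_bins * factor].reshape(n_trials, n_channels, n_bins, factor)
    binned = binned.mean(axis=-1)
    bin_ms = 1000.0 / cfg.hga_output_rate_hz
    bin_starts = ep.times_ms[np.arange(n_bins) * factor]

    # keep bins whose start lies in [-900, offset+900]; the closed upper edge
    # keeps one bin at exactly offset+900 so the last decoding window of the
    # published grid is populated
    clip_lo = -cfg.hga_clip_pre_ms
    clip_hi = ep.duration_ms + cfg.hga_clip_post_offset_ms
    keep = (bin_starts >= clip_lo - 1e-9) & (bin_starts <= clip_hi + 1e-9)
    return EpochedHGA(
        data=binned[:, :, keep],
        times_ms=bin_starts[keep],
        rate_hz=cfg.hga_output_rate_hz,
        channels=list(ep.channels),
        trial_stimulus_ids=list(ep.trial_stimulus_ids),
        task=ep.task,
        duration_ms=ep.duration_ms,
        bands=bank,
    )


def average_stimulus_responses(
    hga: EpochedHGA,
    trials: pd.DataFrame,
    stimuli: pd.DataFrame,
) -> StimulusResponse:
    """Average HGA across all presentations of each stimulus."""
    trial_ids = np.asarray(hga.trial_stimulus_ids)
    stim_ids = list(stimuli["stimulus_id"])
    counts = np.zeros(len(stim_ids), dtype=int)
    data = np.zeros((len(stim_ids), hga.data.shape[1], hga.data.shape[2]))
    for i, sid in enumerate(stim_ids):
        mask = trial_ids == sid
        counts[i] = int(mask.sum())
        if counts[i] == 0:
            raise ConsistencyError(f"stimulus {sid!r} has no presentations")
        data[i] = hga.data[mask].mean(axis=0)
    return StimulusResponse(
        data=data,
        times_ms=hga.times_ms,
        rate_hz=hga.rate_hz,
        channels=list(hga.channels),
        stimulus_ids=stim_ids,
        presentation_counts=counts,
        task=hga.task,
        duration_ms=hga.duration_ms,
    )


# ---------------------------------------------------------------------------
# container I/O (used by the CLI stages)
# ---------------------------------------------------------------------------

def _write_channels(grp: h5py.Group, channels: list[ChannelInfo]) -> None:
    enc = h5py.string_dtype(encoding="utf-8")
    grp.create_dataset("channel_id", data=[c.channel_id for c in channels], dtype=enc)
    grp.create_dataset("roi", data=[c.roi for c in channels], dtype=enc)
    grp.create_dataset("hemisphere", data=[c.hemisphere for c in channels], dtype=enc)
    grp.create_dataset("dist_to_cortex_mm", data=[c.dist_to_cortex_mm for c in channels])


def _read_channels(grp: h5py.Group) -> list[ChannelInfo]:
    dec = lambda s: s.decode() if isinstance(s, bytes) else str(s)
    return [
        ChannelInfo(dec(cid), dec(roi), dec(hemi), float(d))
        for cid, roi, hemi, d in zip(
            grp["channel_id"][()], grp["roi"][()], grp["hemisphere"][()],
            grp["dist_to_cortex_mm"][()],
        )
    ]


def write_epoched_hga(path: str | Path, hga: EpochedHGA) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=hga.data)
        f.create_dataset("times_ms", data=hga.times_ms)
        enc = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("trial_stimulus_ids", data=hga.trial_stimulus_ids, dtype=enc)
        f.create_dataset("bands", data=np.asarray(hga.bands))
        f.attrs["rate_hz"] = hga.rate_hz
        f.attrs["task"] = hga.task
        f.attrs["duration_ms"] = hga.duration_ms
        _write_channels(f.create_group("channels"), hga.channels)


def read_epoched_hga(path: str | Path) -> EpochedHGA:
    with h5py.File(path, "r") as f:
        return EpochedHGA(
            data=f["data"][()],
            times_ms=f["times_ms"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            channels=_read_channels(f["channels"]),
            trial_stimulus_ids=[s.decode() for s in f["trial_stimulus_ids"][()]],
            task=str(f.attrs["task"]),
            duration_ms=float(f.attrs["duration_ms"]),
            bands=[(float(c), float(w), int(o)) for c, w, o in f["bands"][()]],
        )


def write_stimulus_response(path: str | Path, resp: StimulusResponse) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=resp.data)
        f.create_dataset("times_ms", data=resp.times_ms)
        enc = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("stimulus_ids", data=resp.stimulus_ids, dtype=enc)
        f.create_dataset("presentation_counts", data=resp.presentation_counts)
        f.attrs["rate_hz"] = resp.rate_hz
        f.attrs["task"] = resp.task
        f.attrs["duration_ms"] = resp.duration_ms
        _write_channels(f.create_group("channels"), resp.channels)


def read_stimulus_response(path: str | Path) -> StimulusResponse:
    with h5py.File(path, "r") as f:
        return StimulusResponse(
            data=f["data"][()],
            times_ms=f["times_ms"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            channels=_read_channels(f["channels"]),
            stimulus_ids=[s.decode() for s in f["stimulus_ids"][()]],
            presentation_counts=f["presentation_counts"][()],
            task=str(f.attrs["task"]),
            duration_ms=float(f.attrs["duration_ms"]),
        )
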