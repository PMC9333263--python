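"""Synthetic sEEG generator with known ground truth.

Emulates the phenomenology the pipeline is built to measure: each channel is
a 1/f background plus a 70–150 Hz band-limited carrier whose amplitude
envelope rises — category-dependently — during the onset (0–500 ms) and
sustained (500 ms–offset) windows of each trial, optionally on top of shared
common-mode noise (to exercise re-referencing) and a sinusoidal line
component.  Trial schedules use uniform inter-stimulus intervals and 1-back
repeats realized as immediate re-presentations; acoustic feature tables have
a low-rank latent structure partially confounded with the vocal category.

Channel gains are expressed in baseline-SD units of the carrier envelope.
Because the downstream HGA estimator z-scores each band against its own
baseline, the designed vocal/nonvocal gain pair maps onto the estimated HGA
ratio through the same (V − NV)/(V + NV) formula used by the pipeline, which
is what makes parameter recovery testable.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning (one child per channel / stage), so
fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .channel_analysis import hga_ratio
from .data_model import ChannelInfo, Recording, validate_trial_table

ROLES = ("category_encoder", "acoustic_encoder", "nonresponsive")


@dataclass
class ChannelSpec:
    """Generative parameters for one synthetic channel.

    The default ``category_encoder`` mirrors a voice-selective lateral
    temporal site: both categories evoke an onset response, but only vocal
    stimuli sustain it (nonvocal sustained gain ~0).
    """

    role: str = "category_encoder"
    onset_gain_v: float = 3.0
    onset_gain_nv: float = 2.0
    sustained_gain_v: float = 3.0
    sustained_gain_nv: float = 0.0
    latency_ms: float = 100.0
    acoustic_weights: np.ndarray | None = None
    noise_sd: float = 1.0
    channel_id: str = ""
    roi: str = "other"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        gains = (self.onset_gain_v, self.onset_gain_nv,
                 self.sustained_gain_v, self.sustained_gain_nv)
        if any(g < 0 for g in gains):
            raise ValueError("gains must be nonnegative")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.role == "nonresponsive" and any(g != 0 for g in gains):
            raise ValueError("nonresponsive channels must have all gains 0")


@dataclass
class GroundTruth:
    """What the generator planted, in the pipeline's own terms."""

    specs: list[ChannelSpec]
    true_hga_ratio_onset: np.ndarray
    true_hga_ratio_sustained: np.ndarray
    latent_factors: pd.DataFrame | None = None
    seed: int = 0
    isi_bounds_ms: tuple[float, float] = (1000.0, 2000.0)
    repeat_fraction: float = 0.16


def make_trial_schedule(
    stimuli: pd.DataFrame,
    n_presentations: int = 3,
    repeat_fraction: float = 0.16,
    isi_bounds_ms: tuple[float, float] = (1000.0, 2000.0),
    seed: int = 0,
    sample_rate_hz: float = 1000.0,
    start_pad_ms: float = 2000.0,
) -> pd.DataFrame:
    """Randomized 1-back presentation schedule.

    Every stimulus appears at least ``n_presentations`` times; inserted
    immediate re-presentations (the 1-back repeats, roughly 16% of trials in
    the published task) are flagged ``is_repeat``.  Inter-stimulus intervals
    are uniform within ``isi_bounds_ms``, so consecutive onsets are separated
    by at least the stimulus duration plus the lower ISI bound.
    """
    if len(stimuli) == 0:
        raise ValueError("stimulus table is empty")
    if not 0.0 <= repeat_fraction < 1.0:
        raise ValueError("repeat_fraction must lie in [0, 1)")
    lo, hi = isi_bounds_ms
    if lo >= hi:
        raise ValueError("isi lower bound must be below upper bound")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    base = np.repeat(stimuli["stimulus_id"].to_numpy(), n_presentations)
    base = rng.permutation(base)
    # break up accidental immediate duplicates so is_repeat flags stay exact
    for _ in range(100):
        dup = np.flatnonzero(base[1:] == base[:-1])
        if dup.size == 0:
            break
        swap = rng.integers(0, len(base), size=dup.size)
        for d, s in zip(dup + 1, swap):
            base[d], base[s] = base[s], base[d]

    n_repeats = int(round(len(base) * repeat_fraction / (1.0 - repeat_fraction)))
    sequence = list(base)
    flags = [False] * len(sequence)
    for _ in range(n_repeats):
        pos = int(rng.integers(1, len(sequence) + 1))
        sequence.insert(pos, sequence[pos - 1])
        flags.insert(pos, True)

    durations = stimuli.set_index("stimulus_id")["duration_ms"]
    onsets = []
    t_ms = start_pad_ms
    for sid in sequence:
        onsets.append(int(round(t_ms * sample_rate_hz / 1000.0)))
        t_ms += float(durations.loc[sid]) + rng.uniform(lo, hi)

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(len(sequence)),
            "stimulus_id": sequence,
            "onset_sample": onsets,
            "is_repeat": flags,
        }
    )
    return validate_trial_table(trials, stimuli, min_isi_ms=lo, sample_rate_hz=sample_rate_hz)


def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with a 1/f power spectrum, by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    shaped = np.fft.irfft(spectrum * scale, n)
    return shaped / shaped.std()


def _band_limited_carrier(n: int, rng: np.random.Generator, sample_rate_hz: float,
                          low_hz: float = 70.0, high_hz: float = 150.0) -> np.ndarray:
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=sample_rate_hz,
                        output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return carrier / carrier.std()


def _gain_envelope(
    spec: ChannelSpec,
    trials: pd.DataFrame,
    stimuli: pd.DataFrame,
    n_samples: int,
    sample_rate_hz: float,
    ramp_ms: float = 50.0,
    latent: pd.DataFrame | None = None,
) -> np.ndarray:
    """Designed multiplicative gain trace with 50 ms linear ramps.

    When the spec carries ``acoustic_weights`` and per-stimulus latent factors
    are supplied, each trial's gain is additionally modulated by
    ``weights · latent`` (clipped at 0), making the channel an acoustic
    encoder whose response tracks stimulus acoustics rather than category.
    """
    vocal = stimuli.set_index("stimulus_id")["vocal"]
    durations = stimuli.set_index("stimulus_id")["duration_ms"]
    ms = sample_rate_hz / 1000.0
    target = np.zeros(n_samples)
    lat = int(round(spec.latency_ms * ms))
    for sid, onset in zip(trials["stimulus_id"], trials["onset_sample"]):
        is_v = bool(vocal.loc[sid])
        dur = int(round(float(durations.loc[sid]) * ms))
        g_on = spec.onset_gain_v if is_v else spec.onset_gain_nv
        g_sus = spec.sustained_gain_v if is_v else spec.sustained_gain_nv
        if spec.acoustic_weights is not None and latent is not None:
            bump = float(np.dot(spec.acoustic_weights, latent.loc[sid].to_numpy()))
            g_on = max(g_on + bump, 0.0)
            g_sus = max(g_sus + bump, 0.0)
        a = onset + lat
        b = min(a + int(round(500 * ms)), n_samples)
        c = min(onset + lat + dur, n_samples)
        target[a:b] = g_on
        target[b:c] = g_sus
    ramp = int(round(ramp_ms * ms))
    if ramp > 1:
        kernel = np.ones(ramp) / ramp  # moving average converts steps to linear ramps
        target = np.convolve(target, kernel, mode="same")
    return target


def synthesize_recording(
    specs: Sequence[ChannelSpec],
    trials: pd.DataFrame,
    stimuli: pd.DataFrame,
    common_noise_sd: float = 0.0,
    line_hz: float | None = None,
    seed: int = 0,
    sample_rate_hz: float = 1000.0,
    tail_pad_ms: float = 3000.0,
    latent_factors: pd.DataFrame | None = None,
) -> tuple[Recording, GroundTruth]:
    """Render a voltage recording for the given channel specs and schedule.

    ``latent_factors`` (index = stimulus id) feeds channels with
    ``acoustic_weights``; pass the ground-truth frame returned by
    :func:`make_acoustic_features` to couple neural gains to the acoustic
    feature table.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one channel spec is required")
    durations = stimuli.set_index("stimulus_id")["duration_ms"]
    last = trials.iloc[-1]
    n_samples = int(
        last["onset_sample"]
        + (float(durations.loc[last["stimulus_id"]]) + tail_pad_ms) * sample_rate_hz / 1000.0
    )

    children = np.random.SeedSequence(seed).spawn(2 * len(specs) + 1)
    common_rng = np.random.default_rng(children[-1])
    common = (
        common_noise_sd * _one_over_f_noise(n_samples, common_rng)
        if common_noise_sd > 0
        else 0.0
    )

    voltage = np.empty((len(specs), n_samples))
    infos = []
    for i, spec in enumerate(specs):
        bg_rng = np.random.default_rng(children[2 * i])
        carrier_rng = np.random.default_rng(children[2 * i + 1])
        bg = spec.noise_sd * _one_over_f_noise(n_samples, bg_rng)
        carrier = _band_limited_carrier(n_samples, carrier_rng, sample_rate_hz)
        env = _gain_envelope(spec, trials, stimuli, n_samples, sample_rate_hz,
                             latent=latent_factors)
        chan = bg + carrier * (1.0 + env)
        if common_noise_sd > 0:
            chan = chan + common
        if line_hz is not None:
            t = np.arange(n_samples) / sample_rate_hz
            chan = chan + spec.noise_sd * np.sin(2 * np.pi * line_hz * t)
        voltage[i] = chan
        infos.append(
            ChannelInfo(
                channel_id=spec.channel_id or f"sim{i:02d}",
                roi=spec.roi,
                hemisphere=spec.hemisphere,
            )
        )

    truth = GroundTruth(
        latent_factors=latent_factors,
        specs=specs,
        true_hga_ratio_onset=np.array(
            [hga_ratio(s.onset_gain_v, s.onset_gain_nv) for s in specs]
        ),
        true_hga_ratio_sustained=np.array(
            [hga_ratio(s.sustained_gain_v, s.sustained_gain_nv) for s in specs]
        ),
        seed=seed,
    )
    return Recording(sample_rate_hz=sample_rate_hz, voltage=voltage, channels=infos), truth


def example_channel_specs() -> list[ChannelSpec]:
    """A small mixed cohort covering the response types the pipeline targets.

    Two category encoders in lateral temporal cortex (sustained response only
    to vocal sounds), two acoustic encoders on the supratemporal plane
    (responses of equal size to both categories), one weakly selective PT
    channel and one nonresponsive control.
    """
    return [
        ChannelSpec(role="category_encoder", channel_id="sts0", roi="STS",
                    onset_gain_v=3.0, onset_gain_nv=2.0,
                    sustained_gain_v=3.0, sustained_gain_nv=0.0, latency_ms=150.0),
        ChannelSpec(role="category_encoder", channel_id="stg0", roi="STG",
                    onset_gain_v=3.0, onset_gain_nv=1.5,
                    sustained_gain_v=2.5, sustained_gain_nv=0.0, latency_ms=150.0),
        ChannelSpec(role="acoustic_encoder", channel_id="hg0", roi="HG",
                    onset_gain_v=4.0, onset_gain_nv=4.0,
                    sustained_gain_v=3.0, sustained_gain_nv=3.0, latency_ms=80.0),
        ChannelSpec(role="acoustic_encoder", channel_id="pt0", roi="PT",
                    onset_gain_v=3.5, onset_gain_nv=3.5,
                    sustained_gain_v=2.5, sustained_gain_nv=2.5, latency_ms=100.0),
        ChannelSpec(role="acoustic_encoder", channel_id="pt1", roi="PT",
                    onset_gain_v=3.0, onset_gain_nv=2.5,
                    sustained_gain_v=2.5, sustained_gain_nv=2.0, latency_ms=100.0),
        ChannelSpec(role="nonresponsive", channel_id="wm0", roi="other",
                    onset_gain_v=0.0, onset_gain_nv=0.0,
                    sustained_gain_v=0.0, sustained_gain_nv=0.0),
    ]


def make_acoustic_features(
    stimuli: pd.DataFrame,
    n_features: int = 88,
    n_latent: int = 5,
    category_shift: np.ndarray | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Low-rank acoustic feature table: ``features = latent @ loadings' + noise``.

    Latent factor means differ between vocal and nonvocal stimuli by
    ``category_shift`` (length ``n_latent``), so the category is partially —
    not fully — recoverable from acoustics, as with real summary features.
    The default width (88 columns) matches a standard "functionals" summary
    feature set, and the small default ``noise_sd`` keeps the table strongly
    collinear, as real summary features are, so a 99.99%-variance PCA cut
    lands near the latent rank.  Returns the feature table and the latent
    ground truth.
    """
    if n_latent < 1 or n_features < n_latent:
        raise ValueError("need n_features >= n_latent >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = len(stimuli)
    shift = np.zeros(n_latent) if category_shift is None else np.asarray(category_shift, float)
    if shift.shape != (n_latent,):
        raise ValueError("category_shift must have length n_latent")
    vocal = stimuli["vocal"].to_numpy(dtype=bool)
    latent = rng.standard_normal((n, n_latent)) + np.outer(vocal, shift)
    loadings = rng.standard_normal((n_features, n_latent))
    features = latent @ loadings.T + noise_sd * rng.standard_normal((n, n_features))
    ids = stimuli["stimulus_id"].to_numpy()
    table = pd.DataFrame(features, index=pd.Index(ids, name="stimulus_id"),
                         columns=[f"feat_{j:03d}" for j in range(n_features)])
    truth = pd.DataFrame(latent, index=table.index,
                         columns=[f"latent_{j}" for j in range(n_latent)])
    return table, truth
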