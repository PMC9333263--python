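"""Single-channel statistics: responsiveness, separability, category preference.

A channel is *auditory responsive* when mean HGA in the 500 ms after onset
exceeds the −600..−100 ms baseline (two-sample t across trials, BH-FDR over
channels).  *V–NV separability* is the summed mass of all significant
(p < 0.001) clusters of the time-resolved vocal-vs-nonvocal t-series.  The
*HGA ratio* (V − NV)/(V + NV), computed on onset- and sustained-window means
with negative means clipped to zero, measures how exclusively a channel
responds to vocal sounds: 1 means vocal-only, 0 means no preference, −1
nonvocal-only.  Scale invariance is the point of the normalization — doubling
a channel's overall response does not change its ratio.

Per-channel results are carried in a pandas DataFrame with columns
``channel_id, roi, super_roi, hemisphere, auditory_t, auditory_p,
auditory_p_fdr, responsive, separability, separability_onset_ms, v_onset,
nv_onset, v_sustained, nv_sustained, hga_ratio_onset, hga_ratio_sustained``.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster_stats import (
    ClusterResult,
    bh_fdr,
    permutation_cluster_test,
    sum_cluster_mass,
    tstat_series,
)
from .config import AnalysisConfig
from .data_model import DegenerateDataError
from .preprocessing import EpochedHGA, StimulusResponse


def hga_ratio(hga_v: float, hga_nv: float) -> float:
    """Vocal category preference strength in [−1, 1].

    Negative window means (responses dipping below baseline) are clipped to 0
    before the ratio so the bound holds; a fully silent channel (0/0) is
    defined to have no preference (0).
    """
    if not (np.isfinite(hga_v) and np.isfinite(hga_nv)):
        raise ValueError("HGA means must be finite")
    v = max(float(hga_v), 0.0)
    nv = max(float(hga_nv), 0.0)
    total = v + nv
    if total == 0.0:
        return 0.0
    return (v - nv) / total


def _window_mask(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (times_ms >= lo - 1e-9) & (times_ms < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}) ms contains no samples")
    return mask


def trial_vocal_labels(hga: EpochedHGA, stimuli: pd.DataFrame) -> np.ndarray:
    vocal = stimuli.set_index("stimulus_id")["vocal"]
    return np.array([bool(vocal.loc[sid]) for sid in hga.trial_stimulus_ids])


def auditory_responsiveness(hga: EpochedHGA, cfg: AnalysisConfig) -> pd.DataFrame:
    """Two-sample t of onset-window vs baseline mean HGA, FDR over channels."""
    if hga.data.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    onset = _window_mask(hga.times_ms, cfg.onset_window_ms)
    base = _window_mask(hga.times_ms, cfg.baseline_window_ms)
    onset_means = hga.data[:, :, onset].mean(axis=2)  # trials × channels
    base_means = hga.data[:, :, base].mean(axis=2)
    if np.allclose(hga.data, 0.0):
        raise DegenerateDataError("all-zero HGA")
    t, p = sps.ttest_ind(onset_means, base_means, axis=0, equal_var=True)
    rejected, adjusted = bh_fdr(p, cfg.responsiveness_alpha)
    return pd.DataFrame(
        {
            "channel_id": [c.channel_id for c in hga.channels],
            "auditory_t": t,
            "auditory_p": p,
            "auditory_p_fdr": adjusted,
            "responsive": rejected,
        }
    )


def vnv_separability(
    channel_hga: np.ndarray,
    labels: np.ndarray,
    cfg: AnalysisConfig,
    times_ms: np.ndarray | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> tuple[float, ClusterResult]:
    """Sum cluster mass of the vocal-vs-nonvocal t-series for one channel.

    ``channel_hga`` is trials × time (single-trial responses).  Two-sided
    clustering: positive and negative clusters are formed separately against
    the signed tails of the permutation null at ``cluster_window_alpha``;
    separability sums |mass| over clusters with p < ``cluster_alpha``.
    """
    result = permutation_cluster_test(
        lambda data, lab: tstat_series(data, lab),
        channel_hga,
        labels,
        n_perm=n_perm if n_perm is not None else cfg.n_perm_single_channel,
        window_alpha=cfg.cluster_window_alpha,
        seed=cfg.seed if seed is None else seed,
        tail="two",
        window_centers_ms=times_ms,
    )
    return sum_cluster_mass(result, cfg.cluster_alpha), result


def window_means(
    resp: StimulusResponse,
    stimuli: pd.DataFrame,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Mean HGA per channel × category × window (onset / sustained).

    Time samples are averaged within the window first, then across the
    stimuli of each category (stimulus responses, i.e. presentation means).
    """
    vocal = stimuli.set_index("stimulus_id")["vocal"]
    labels = np.array([bool(vocal.loc[sid]) for sid in resp.stimulus_ids])
    if labels.all() or not labels.any():
        raise ValueError("both vocal and nonvocal stimuli are required")
    out = {}
    for name, window in (("onset", cfg.onset_window_ms), ("sustained", cfg.sustained_window_ms)):
        mask = _window_mask(resp.times_ms, window)
        per_stim = resp.data[:, :, mask].mean(axis=2)  # stimuli × channels
        out[f"v_{name}"] = per_stim[labels].mean(axis=0)
        out[f"nv_{name}"] = per_stim[~labels].mean(axis=0)
    out["channel_id"] = [c.channel_id for c in resp.channels]
    frame = pd.DataFrame(out)[["channel_id", "v_onset", "nv_onset", "v_sustained", "nv_sustained"]]
    frame["hga_ratio_onset"] = [
        hga_ratio(v, nv) for v, nv in zip(frame["v_onset"], frame["nv_onset"])
    ]
    frame["hga_ratio_sustained"] = [
        hga_ratio(v, nv) for v, nv in zip(frame["v_sustained"], frame["nv_sustained"])
    ]
    return frame


def analyze_channels(
    hga: EpochedHGA,
    stimuli: pd.DataFrame,
    resp: StimulusResponse,
    cfg: AnalysisConfig,
    n_perm: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full per-channel statistics table (see module docstring for columns).

    Separability runs on single-trial responses; window means and HGA ratios
    on stimulus responses.  Separability onset is the start time of the
    earliest significant cluster (NaN when none).
    """
    labels = trial_vocal_labels(hga, stimuli)
    responsiveness = auditory_responsiveness(hga, cfg)
    means = window_means(resp, stimuli, cfg)

    seps, onsets = [], []
    for ch in range(hga.data.shape[1]):
        sep, result = vnv_separability(
            hga.data[:, ch, :], labels, cfg, times_ms=hga.times_ms,
            n_perm=n_perm, seed=seed,
        )
        seps.append(sep)
        sig = [c for c in result.clusters if c.p < cfg.cluster_alpha]
        onsets.append(min(c.start_ms for c in sig) if sig else np.nan)

    frame = responsiveness.merge(means, on="channel_id")
    frame.insert(1, "roi", [c.roi for c in hga.channels])
    frame.insert(2, "super_roi", [c.super_roi for c in hga.channels])
    frame.insert(3, "hemisphere", [c.hemisphere for c in hga.channels])
    frame["separability"] = seps
    frame["separability_onset_ms"] = onsets
    return frame


def separability_onset(stats: pd.DataFrame, roi: str) -> float | None:
    """Median separability onset over the 50% most separable channels of an ROI.

    Onset estimates are noise-sensitive in weakly separable channels, hence
    the restriction to the top half (``ceil(n/2)`` channels, ties broken by
    channel id).  Returns None when the ROI has no separable channel.
    """
    grp = stats[(stats["super_roi"] == roi) & (stats["separability"] > 0)]
    grp = grp.dropna(subset=["separability_onset_ms"])
    if len(grp) == 0:
        return None
    if len(grp) == 1:
        warnings.warn(f"only one separable channel in {roi}; onset is that channel's")
        return float(grp["separability_onset_ms"].iloc[0])
    k = math.ceil(len(grp) / 2)
    top = grp.sort_values(["separability", "channel_id"], ascending=[False, True]).head(k)
    return float(top["separability_onset_ms"].median())


def roi_compare(
    stats: pd.DataFrame,
    metric: str,
    grouping: str = "stp_vs_stgsts",
) -> tuple[float, float]:
    """Group contrasts used in the ROI analyses.

    ``stp_vs_stgsts`` / ``left_vs_right``: two-sided Wilcoxon rank-sum of the
    metric between unpaired channel groups.  ``onset_vs_sustained``: paired
    sign-rank between ``<metric>_onset`` and ``<metric>_sustained`` within
    channels.  ``proportion_separable``: Fisher exact test on the 2×2 table of
    separable vs non-separable channel counts per super-ROI (pooled across
    patients).
    """
    if grouping in ("stp_vs_stgsts", "left_vs_right"):
        col, a_val, b_val = (
            ("super_roi", "STP", "STG/STS") if grouping == "stp_vs_stgsts"
            else ("hemisphere", "left", "right")
        )
        a = stats.loc[stats[col] == a_val, metric].dropna().to_numpy()
        b = stats.loc[stats[col] == b_val, metric].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        res = sps.ranksums(a, b)
        return float(res.statistic), float(res.pvalue)
    if grouping == "onset_vs_sustained":
        a = stats[f"{metric}_onset"].to_numpy()
        b = stats[f"{metric}_sustained"].to_numpy()
        if len(a) < 2:
            raise ValueError("need at least 2 paired observations")
        if np.allclose(a, b):
            return 0.0, 1.0
        res = sps.wilcoxon(b, a)
        return float(res.statistic), float(res.pvalue)
    if grouping == "proportion_separable":
        table = []
        for roi in ("STP", "STG/STS"):
            grp = stats[stats["super_roi"] == roi]
            if len(grp) < 2:
                raise ValueError("need at least 2 channels per super-ROI")
            n_sep = int((grp["separability"] > 0).sum())
            table.append([n_sep, len(grp) - n_sep])
        res = sps.fisher_exact(table)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown grouping {grouping!r}")
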