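"""Shared fixtures: small synthetic cohorts run once through the pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import voicegate as vg


@pytest.fixture(scope="session")
def cfg() -> vg.AnalysisConfig:
    return vg.AnalysisConfig()


@pytest.fixture(scope="session")
def nats_stimuli() -> pd.DataFrame:
    return vg.make_nats_stimulus_table()


@pytest.fixture(scope="session")
def small_stimuli(nats_stimuli) -> pd.DataFrame:
    """8 vocal + 8 nonvocal NatS stimuli — a desk-scale stimulus set."""
    vocal = nats_stimuli[nats_stimuli["vocal"]].head(8)
    nonvocal = nats_stimuli[~nats_stimuli["vocal"]].head(8)
    return pd.concat([vocal, nonvocal], ignore_index=True)


def run_pipeline(specs, stimuli, cfg, seed, n_presentations=2, car=False,
                 common_noise_sd=0.0, latent_factors=None):
    """Synthesize a recording and run it to HGA + stimulus responses."""
    trials = vg.make_trial_schedule(stimuli, n_presentations=n_presentations, seed=seed)
    rec, truth = vg.synthesize_recording(
        specs, trials, stimuli, common_noise_sd=common_noise_sd, seed=seed,
        latent_factors=latent_factors,
    )
    if car:
        rec = vg.apply_car(rec)
    ep = vg.normalize_epochs(vg.epoch_voltage(rec, trials, stimuli, cfg), cfg)
    hga = vg.extract_hga(ep, cfg)
    resp = vg.average_stimulus_responses(hga, trials, stimuli)
    return trials, truth, hga, resp


@pytest.fixture(scope="session")
def cohort_pipeline(small_stimuli, cfg):
    """The mixed example cohort (category / acoustic / nonresponsive channels)
    run once through preprocessing; reused by channel-level tests."""
    specs = vg.example_channel_specs()
    trials, truth, hga, resp = run_pipeline(specs, small_stimuli, cfg, seed=7)
    return {"specs": specs, "trials": trials, "truth": truth, "hga": hga,
            "resp": resp, "stimuli": small_stimuli}


@pytest.fixture(scope="session")
def cohort_stats(cohort_pipeline, cfg):
    """Per-channel statistics for the shared cohort (reduced permutations)."""
    return vg.analyze_channels(
        cohort_pipeline["hga"],
        cohort_pipeline["stimuli"],
        cohort_pipeline["resp"],
        cfg,
        n_perm=400,
        seed=11,
    )
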