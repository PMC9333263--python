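"""Encoding models: PCA reduction, LOOCV R², permutation p, category LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import voicegate as vg
from voicegate.encoding import per_stimulus_window_means
from voicegate.preprocessing import StimulusResponse


@pytest.fixture(scope="module")
def design_and_latent(nats_stimuli, cfg):
    features, latent = vg.make_acoustic_features(
        nats_stimuli, n_latent=4, category_shift=np.array([1.0, 0, 0, 0]), seed=0,
    )
    design = vg.reduce_features(features, nats_stimuli, cfg)
    return design, latent


class TestReduceFeatures:
    def test_noiseless_rank_recovered(self, small_stimuli, cfg):
        features, _ = vg.make_acoustic_features(small_stimuli, n_latent=3,
                                                noise_sd=1e-10, seed=1)
        design = vg.reduce_features(features, small_stimuli, cfg)
        assert design.k == 3
        assert design.explained_variance >= cfg.pca_variance_target

    def test_minimality_of_k(self, nats_stimuli, cfg, design_and_latent):
        design, _ = design_and_latent
        features, _ = vg.make_acoustic_features(
            nats_stimuli, n_latent=4, category_shift=np.array([1.0, 0, 0, 0]), seed=0,
        )
        X = features.to_numpy()
        Xz = (X - X.mean(0)) / X.std(0)
        s = np.linalg.svd(Xz - Xz.mean(0), compute_uv=False)
        ratio = np.cumsum(s**2) / np.sum(s**2)
        # oracle: eigenvalue scan for the smallest k reaching the target
        k_oracle = int(np.flatnonzero(ratio >= cfg.pca_variance_target - 1e-12)[0] + 1)
        assert design.k == k_oracle
        assert ratio[design.k - 1] >= cfg.pca_variance_target - 1e-12
        if design.k > 1:
            assert ratio[design.k - 2] < cfg.pca_variance_target

    def test_rescaling_invariance(self, small_stimuli, cfg):
        features, _ = vg.make_acoustic_features(small_stimuli, n_latent=3, seed=2)
        scaled = features * 1000.0
        a = vg.reduce_features(features, small_stimuli, cfg)
        b = vg.reduce_features(scaled, small_stimuli, cfg)
        assert a.k == b.k
        np.testing.assert_allclose(np.abs(a.components), np.abs(b.components), atol=1e-8)

    def test_excluded_stimuli_dropped(self, small_stimuli, cfg):
        features, _ = vg.make_acoustic_features(small_stimuli, seed=3)
        sid = small_stimuli["stimulus_id"].iloc[0]
        design = vg.reduce_features(features, small_stimuli, cfg, exclude_ids=[sid])
        assert sid not in design.stimulus_ids
        assert len(design.stimulus_ids) == len(small_stimuli) - 1

    def test_constant_column_rejected(self, small_stimuli, cfg):
        features, _ = vg.make_acoustic_features(small_stimuli, seed=4)
        features.iloc[:, 0] = 5.0
        with pytest.raises(vg.DegenerateDataError):
            vg.reduce_features(features, small_stimuli, cfg)

    def test_indicator_not_in_pca(self, design_and_latent):
        design, _ = design_and_latent
        # components orthogonal; indicator binary and separate
        gram = design.components.T @ design.components
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
        assert set(np.unique(design.vocal)) <= {0, 1, False, True}


class TestLoocvR2:
    def test_exact_linear_fit_scores_one(self, design_and_latent):
        design, _ = design_and_latent
        rng = np.random.default_rng(5)
        beta = rng.standard_normal(design.k + 2)
        y = design.matrix(True) @ beta
        assert vg.loocv_r2(design, y) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_scores_at_or_below_zero(self, design_and_latent):
        design, _ = design_and_latent
        rng = np.random.default_rng(6)
        scores = [vg.loocv_r2(design, rng.standard_normal(len(design.vocal)))
                  for _ in range(10)]
        assert np.mean(scores) < 0.0

    def test_matches_explicit_refit_oracle(self):
        rng = np.random.default_rng(7)
        n, p = 25, 4
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        y = X @ rng.standard_normal(p + 1) + rng.standard_normal(n)
        press = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            press += (y[i] - X[i] @ beta) ** 2
        expected = 1.0 - press / np.sum((y - y.mean()) ** 2)
        assert vg.loocv_r2(X, y) == pytest.approx(expected, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
        with pytest.raises(np.linalg.LinAlgError):
            vg.loocv_r2(X, np.random.default_rng(8).standard_normal(20))

    def test_too_few_observations_rejected(self, design_and_latent):
        design, _ = design_and_latent
        X = design.matrix(True)[: design.k + 2]
        with pytest.raises(ValueError):
            vg.loocv_r2(X, np.zeros(design.k + 2))


class TestR2Significance:
    def test_strong_dependence_reaches_floor(self, design_and_latent):
        design, latent = design_and_latent
        rows = latent.loc[design.stimulus_ids]
        y = rows["latent_0"].to_numpy() + 0.1 * np.random.default_rng(9).standard_normal(len(rows))
        r2, p, p_bonf = vg.r2_significance(design, y, n_perm=200, seed=0)
        assert r2 > 0.5
        assert p == pytest.approx(1.0 / 201.0)

    def test_bonferroni_caps_at_one(self, design_and_latent):
        design, _ = design_and_latent
        y = np.random.default_rng(10).standard_normal(len(design.vocal))
        _, p, p_bonf = vg.r2_significance(design, y, n_perm=100, seed=1, n_tests=10000)
        assert p_bonf == 1.0
        assert p_bonf >= p


class TestLrtCategory:
    def test_matches_rss_ratio_oracle(self, design_and_latent):
        design, _ = design_and_latent
        rng = np.random.default_rng(11)
        y = design.vocal * 0.8 + rng.standard_normal(len(design.vocal))
        chi2, p = vg.lrt_category(design, y)
        X_full, X_nested = design.matrix(True), design.matrix(False)
        rss = []
        for X in (X_nested, X_full):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss.append(float(np.sum((y - X @ beta) ** 2)))
        expected = len(y) * np.log(rss[0] / rss[1])
        assert chi2 == pytest.approx(expected, abs=1e-8)
        assert p == pytest.approx(float(sps.chi2.sf(expected, 1)), abs=1e-12)

    def test_category_step_detected(self, design_and_latent):
        design, _ = design_and_latent
        rng = np.random.default_rng(12)
        y = 2.0 * design.vocal + 0.5 * rng.standard_normal(len(design.vocal))
        chi2, p = vg.lrt_category(design, y)
        assert chi2 > 50.0
        assert p < 1e-10

    def test_chi2_grows_linearly_with_n(self, nats_stimuli, cfg):
        chis = {}
        for reps in (1, 2):
            stim = pd.concat([nats_stimuli] * reps, ignore_index=True)
            stim["stimulus_id"] = [f"s{i}" for i in range(len(stim))]
            features, _ = vg.make_acoustic_features(stim, n_latent=3, seed=13)
            design = vg.reduce_features(features, stim, cfg)
            rng = np.random.default_rng(14)
            y = 1.0 * design.vocal + 1.0 * rng.standard_normal(len(design.vocal))
            chis[reps], _ = vg.lrt_category(design, y)
        assert 1.4 <= chis[2] / chis[1] <= 2.8

    def test_acoustic_only_response_keeps_r2_gap_small(self, design_and_latent):
        design, latent = design_and_latent
        rng = np.random.default_rng(15)
        rows = latent.loc[design.stimulus_ids]
        y = rows.to_numpy() @ np.array([1.0, 0.5, 0.0, 0.0]) + 0.3 * rng.standard_normal(len(rows))
        r2_full = vg.loocv_r2(design, y, include_category=True)
        r2_acoustic = vg.loocv_r2(design, y, include_category=False)
        assert r2_acoustic > 0.8
        assert abs(r2_full - r2_acoustic) < 0.05
        chi2, p = vg.lrt_category(design, y)
        assert p > 0.001

    def test_exact_fit_is_degenerate(self, design_and_latent):
        design, _ = design_and_latent
        y = design.matrix(True) @ np.ones(design.k + 2)
        with pytest.raises(vg.DegenerateDataError):
            vg.lrt_category(design, y)


@pytest.fixture(scope="module")
def mixed_fits(nats_stimuli, cfg):
    """Category encoders vs acoustic encoders, fit at the window-mean level."""
    features, latent = vg.make_acoustic_features(nats_stimuli, n_latent=4, seed=16)
    design = vg.reduce_features(features, nats_stimuli, cfg)
    rows = latent.loc[design.stimulus_ids].to_numpy()
    rng = np.random.default_rng(17)
    records = []
    for i in range(6):
        y = 2.0 * design.vocal + 0.5 * rng.standard_normal(len(design.vocal))
        records.append(("STG/STS", "category", y))
    for i in range(6):
        w = rng.standard_normal(4)
        y = rows @ w + 0.5 * rng.standard_normal(len(rows))
        records.append(("STP", "acoustic", y))
    fits = []
    for j, (roi, kind, y) in enumerate(records):
        chi2, lrt_p = vg.lrt_category(design, y)
        fits.append(
            {"channel_id": f"c{j}", "super_roi": roi, "window": "sustained",
             "kind": kind, "lrt_chi2": chi2, "lrt_p": lrt_p,
             "r2_full": vg.loocv_r2(design, y, True),
             "r2_acoustic": vg.loocv_r2(design, y, False)}
        )
    return pd.DataFrame(fits)


class TestCohortClassification:
    def test_chi2_separates_planted_classes(self, mixed_fits):
        cat = mixed_fits[mixed_fits["kind"] == "category"]["lrt_chi2"]
        aco = mixed_fits[mixed_fits["kind"] == "acoustic"]["lrt_chi2"]
        assert cat.min() > aco.max()  # a chi2 threshold cleanly separates groups

    def test_roi_contrast_rejects_in_designed_direction(self, mixed_fits):
        contrasts = vg.classify_channels(mixed_fits).set_index("metric")
        chi2_row = contrasts.loc["lrt_chi2"]
        assert chi2_row["statistic"] > 0  # STG/STS larger
        assert chi2_row["p"] < 0.01
        aco_row = contrasts.loc["r2_acoustic"]
        assert aco_row["statistic"] < 0  # acoustics explain STP better

    def test_identical_groups_not_rejected(self, mixed_fits):
        both = pd.concat([mixed_fits, mixed_fits], ignore_index=True)
        both.loc[: len(mixed_fits) - 1, "super_roi"] = "STP"
        both.loc[len(mixed_fits):, "super_roi"] = "STG/STS"
        contrasts = vg.classify_channels(both)
        assert (contrasts["p"] > 0.9).all()


class TestFitEncodingModels:
    def test_end_to_end_table(self, small_stimuli, cfg):
        features, latent = vg.make_acoustic_features(small_stimuli, n_latent=2, seed=18)
        rng = np.random.default_rng(19)
        n_stim = len(small_stimuli)
        times = np.arange(-900.0, 2901.0, 10.0)
        vocal = small_stimuli["vocal"].to_numpy(dtype=float)
        acoustic = latent.to_numpy() @ np.array([1.0, -1.0])
        data = np.zeros((n_stim, 2, len(times)))
        data[:, 0, :] = vocal[:, None] * 2.0 + 0.2 * rng.standard_normal((n_stim, len(times)))
        data[:, 1, :] = acoustic[:, None] + 0.2 * rng.standard_normal((n_stim, len(times)))
        resp = StimulusResponse(
            data=data, times_ms=times, rate_hz=100.0,
            channels=[vg.ChannelInfo("cat", roi="STS"), vg.ChannelInfo("aco", roi="HG")],
            stimulus_ids=list(small_stimuli["stimulus_id"]),
            presentation_counts=np.full(n_stim, 2), task="NatS", duration_ms=2000.0,
        )
        design = vg.reduce_features(features, small_stimuli, cfg)
        fits = vg.fit_encoding_models(design, resp, cfg, n_perm=200, seed=0)
        assert set(fits["window"]) == {"onset", "sustained"}
        assert len(fits) == 4
        by = fits.set_index(["channel_id", "window"])
        assert by.loc[("cat", "sustained"), "lrt_chi2"] > by.loc[("aco", "sustained"), "lrt_chi2"]
        assert by.loc[("aco", "sustained"), "r2_acoustic"] > 0.8
        assert (fits["r2_full"] <= 1.0).all()

    def test_window_means_shape(self, small_stimuli, cfg):
        rng = np.random.default_rng(20)
        times = np.arange(-900.0, 2901.0, 10.0)
        resp = StimulusResponse(
            data=rng.standard_normal((4, 3, len(times))), times_ms=times, rate_hz=100.0,
            channels=[vg.ChannelInfo(f"c{i}") for i in range(3)],
            stimulus_ids=[f"s{i}" for i in range(4)],
            presentation_counts=np.full(4, 2), task="NatS", duration_ms=2000.0,
        )
        means = per_stimulus_window_means(resp, cfg)
        assert means["onset"].shape == (4, 3)
        assert means["sustained"].shape == (4, 3)
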