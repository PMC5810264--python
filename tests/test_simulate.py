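"""Ground-truth generator: design fidelity, signal construction, behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialwise import (
    ComponentSpec,
    GroundTruth,
    detect_artifacts,
    simulate_behavior,
    simulate_design,
    simulate_epochs,
    simulate_session,
)
from trialwise.montage import N2_ROI, standard_layout
from trialwise.preprocessing import PreprocessConfig

from conftest import DESK_CHANNELS


class TestDesign:
    def test_defaults_match_study_design(self):
        tables = simulate_design(GroundTruth(n_participants=2), seed=0)
        assert len(tables) == 2
        for df in tables:
            assert len(df) == 1920
            assert sorted(df["block"].unique()) == [1, 2, 3, 4, 5]
            assert (df["block"].value_counts() == 384).all()

    def test_small_design_balanced_within_participant(self):
        gt = GroundTruth(n_participants=2, n_trials=8, n_blocks=2, n_items=4)
        tables = simulate_design(gt, seed=1)
        assert sum(len(t) for t in tables) == 16
        for df in tables:
            counts = df.groupby(
                ["perceptual_certainty", "deviant_position"], observed=True
            ).size()
            assert (counts == 1).all()
            assert df["trial_index"].is_monotonic_increasing

    def test_indivisible_trial_count_suggests_nearest(self):
        gt = GroundTruth(n_trials=50)
        with pytest.raises(ValueError, match="48"):
            simulate_design(gt, seed=0)

    def test_same_seed_identical(self):
        gt = GroundTruth(n_participants=2, n_trials=16)
        a = simulate_design(gt, seed=9)
        b = simulate_design(gt, seed=9)
        for x, y in zip(a, b):
            assert x.equals(y)


class TestEpochs:
    def test_zero_noise_component_amplitude_exact(self, layout):
        gt = GroundTruth(
            n_participants=1, n_trials=8, n_blocks=2, n_items=4,
            sampling_rate=100.0, noise_sd=0.0,
            components=[
                ComponentSpec(
                    name="N2", roi=N2_ROI, window_ms=(250, 350),
                    amplitude=-3.0,
                )
            ],
        )
        design = simulate_design(gt, seed=2)[0]
        ep, amps, _ = simulate_epochs(
            design, gt, layout=layout, channels=DESK_CHANNELS, seed=3
        )
        mask = (ep.time_ms >= 250) & (ep.time_ms < 350)
        idx = [ep.channel_labels.index(c) for c in N2_ROI]
        roi_mean = ep.data[np.ix_(idx, np.nonzero(mask)[0])].mean(axis=(0, 1))
        assert np.allclose(roi_mean, -3.0, atol=1e-6)
        assert np.allclose(amps["N2"], -3.0)

    def test_artifact_rate_within_binomial_bounds(self, layout):
        gt = GroundTruth(
            n_participants=1, n_trials=1000, n_blocks=2, n_items=4,
            sampling_rate=100.0, noise_sd=1.0, artifact_rate=0.1,
        )
        design = simulate_design(gt, seed=4)[0]
        ep, _, injected = simulate_epochs(
            design, gt, layout=layout, channels=DESK_CHANNELS[:8], seed=5
        )
        valid = detect_artifacts(ep, PreprocessConfig())
        lo, hi = stats.binom.interval(0.99, 1000, 0.1)
        assert lo <= (~valid).sum() <= hi
        assert injected[~valid].sum() >= injected.sum() * 0.95

    def test_noise_only_averages_near_zero(self, layout):
        gt = GroundTruth(
            n_participants=1, n_trials=64, n_blocks=2, n_items=4,
            sampling_rate=100.0, noise_sd=1.0,
            components=[],
        )
        design = simulate_design(gt, seed=6)[0]
        ep, _, _ = simulate_epochs(
            design, gt, layout=layout, channels=DESK_CHANNELS[:6], seed=7
        )
        grand = ep.data.mean(axis=2)
        se = ep.data.std(axis=2, ddof=1) / np.sqrt(ep.n_trials)
        assert np.all(np.abs(grand) < 4 * se + 1e-12)

    def test_component_window_outside_epoch_rejected(self, layout):
        gt = GroundTruth(
            n_participants=1, n_trials=8, n_blocks=2, n_items=4,
            epoch_window_ms=(-100, 400),
            components=[
                ComponentSpec(name="X", roi=("Cz",), window_ms=(300, 500),
                              amplitude=1.0)
            ],
        )
        design = simulate_design(gt, seed=8)[0]
        with pytest.raises(ValueError, match="outside epoch"):
            simulate_epochs(design, gt, layout=layout,
                            channels=["Cz"], seed=9)


class TestBehavior:
    def test_rt_slope_on_amplitude_recovered_by_lmm(self):
        # reference-magnitude brain-behavior regime: -32 ms per 10 uV of P3b
        from trialwise import ModelSpec, fit_model, rescale_amplitudes

        gt = GroundTruth(n_participants=20, n_trials=96, n_blocks=2,
                         n_items=4)
        gt.behavior.rt_component_slopes = {"P3b": -3.2}  # ms per uV
        rng = np.random.default_rng(10)
        designs = simulate_design(gt, rng)
        frames = []
        for design in designs:
            amps = {
                "P3b": rng.normal(4.2, 3.0, len(design)),
                "N2": np.zeros(len(design)),
            }
            beh = simulate_behavior(design, amps, gt, seed=rng)
            beh["p3b"] = amps["P3b"]
            frames.append(beh)
        df = pd.concat(frames, ignore_index=True)
        df = df[df["response"] != "miss"]
        df = rescale_amplitudes(df, "p3b", 10.0)
        fit = fit_model(
            ModelSpec(
                response="rt_ms", fixed=["p3b"],
                random={"participant_id": ["1"]},
            ),
            df,
        )
        row = fit.fixed_effects.loc["p3b"]
        assert abs(row["b"] - (-32.0)) <= 3 * row["se"]

    def test_zero_coefficients_leave_rt_independent(self):
        gt = GroundTruth(n_participants=8, n_trials=64, n_blocks=2, n_items=4)
        rng = np.random.default_rng(11)
        designs = simulate_design(gt, rng)
        rts, amps_all = [], []
        for design in designs:
            amps = {"N2": rng.normal(size=len(design)),
                    "P3b": rng.normal(size=len(design))}
            beh = simulate_behavior(design, amps, gt, seed=rng)
            keep = beh["response"] != "miss"
            rts.append(beh.loc[keep, "rt_ms"].to_numpy())
            amps_all.append(amps["P3b"][keep.to_numpy()])
        rt = np.concatenate(rts)
        amp = np.concatenate(amps_all)
        r = np.corrcoef(rt, amp)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(rt))

    def test_timeout_rate_matches_normal_tail(self):
        gt = GroundTruth(n_participants=1, n_trials=1920, n_blocks=5,
                         n_items=4)
        gt.behavior.rt_intercept = 1800.0
        gt.behavior.rt_certainty_effect = 0.0
        gt.behavior.rt_subject_intercept_sd = 0.0
        gt.behavior.rt_subject_slope_sd = 0.0
        gt.behavior.rt_item_intercept_sd = 0.0
        gt.behavior.rt_residual_sd = 100.0
        design = simulate_design(gt, seed=12)[0]
        beh = simulate_behavior(
            design, {"N2": np.zeros(1920), "P3b": np.zeros(1920)}, gt, seed=13
        )
        expected = stats.norm.sf(2000.0, loc=1800.0, scale=100.0)
        observed = (beh["response"] == "miss").mean()
        se = np.sqrt(expected * (1 - expected) / 1920)
        assert abs(observed - expected) <= 4 * se


class TestSession:
    def test_deterministic_under_seed(self, layout):
        gt = GroundTruth(n_participants=2, n_trials=16, n_blocks=2,
                         n_items=4, sampling_rate=100.0, noise_sd=1.0)
        a = simulate_session(gt, seed=14, layout=layout, channels=["Cz", "Pz"])
        b = simulate_session(gt, seed=14, layout=layout, channels=["Cz", "Pz"])
        for ea, eb in zip(a.epochs, b.epochs):
            assert np.array_equal(ea.data, eb.data)
        for ba, bb in zip(a.behavior, b.behavior):
            assert ba.equals(bb)

    def test_truth_amplitudes_align_with_trials(self, desk_gt, layout):
        sess = simulate_session(desk_gt, seed=15, layout=layout,
                                channels=DESK_CHANNELS)
        n_total = desk_gt.n_participants * desk_gt.n_trials
        for comp in desk_gt.components:
            assert sess.truth["component_amplitudes"][comp.name].shape == (
                n_total,
            )
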