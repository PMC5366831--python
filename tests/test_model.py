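"""Model assembly, initialization, training loop, batch equivalence."""

import numpy as np
import pytest

from avwgmm import TrainingConfig, train, train_replications
from avwgmm.batch import _HAVE_NUMBA
from avwgmm.data import CUES
from avwgmm.model import (Checkpoint, initialize_model, rep_rng, train_trial)

BACKENDS = ["numpy"] + (["numba"] if _HAVE_NUMBA else [])


class TestConfigValidation:
    def test_checkpoints_must_lie_within_training(self):
        with pytest.raises(ValueError):
            TrainingConfig(n_trials=100, checkpoints=(100, 200))
        cfg = TrainingConfig(n_trials=100, checkpoints=(100,))
        assert cfg.checkpoints == (100,)

    def test_checkpoints_are_sorted(self):
        cfg = TrainingConfig(n_trials=500, checkpoints=(500, 10))
        assert cfg.checkpoints == (10, 500)

    def test_default_developmental_test_times(self):
        assert TrainingConfig().checkpoints == (100, 1000, 10_000, 100_000,
                                                150_000)

    def test_missing_rates_rejected(self):
        with pytest.raises(ValueError, match="F3"):
            TrainingConfig(rates={"MH": TrainingConfig().rates["MH"]})


class TestInitialization:
    def test_published_initial_state(self, bd):
        cfg = TrainingConfig()
        model = initialize_model(bd, cfg, rep_rng(0, 0))
        f2 = model.cue_mixtures["F2"]
        # every F2 sigma starts at the mean of the two prototype SDs
        np.testing.assert_allclose(f2.sigma, (155.70 + 232.80) / 2)
        for cue in CUES:
            np.testing.assert_allclose(model.cue_mixtures[cue].phi, 1 / cfg.K)
        np.testing.assert_allclose(model.integrated.phi, 1 / cfg.K)
        assert model.signs.tolist() == [-1, -1, 1, 1]  # MH MW flip, F2 F3 keep

    def test_initial_f2_locations_center_on_prototype_midpoint(self, bd):
        cfg = TrainingConfig()
        mus = [initialize_model(bd, cfg, rep_rng(0, i)).cue_mixtures["F2"].mu
               for i in range(40)]
        grand = np.concatenate(mus)
        # midpoint 1157.5 Hz, spread 250 Hz: mean within 4 standard errors
        assert abs(grand.mean() - 1157.5) < 4 * 250 / np.sqrt(grand.size)


class TestTrainTrial:
    def test_invariants_and_counter_after_trials(self, bd):
        cfg = TrainingConfig()
        rng = rep_rng(3, 0)
        model = initialize_model(bd, cfg, rng)
        from avwgmm.data import sample_tokens

        values, _ = sample_tokens(bd, 50, rng)
        for row in values:
            model, w = train_trial(model, row)
        assert model.trial_counter == 50
        for mix in (*model.cue_mixtures.values(), model.integrated):
            assert mix.phi.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(mix.sigma >= mix.sigma_floor)
            assert np.all(mix.phi >= mix.phi_floor * 0.99)
        assert w.normalized.sum() == pytest.approx(1.0)

    def test_rejects_nonfinite_token(self, bd):
        model = initialize_model(bd, TrainingConfig(), rep_rng(3, 0))
        with pytest.raises(ValueError, match="non-finite"):
            train_trial(model, [np.nan, 1.0, 2.0, 3.0])

    def test_converged_model_orders_prototype_inputs(self, trained_model, bd):
        u_b = trained_model.integrated_input(bd.category_a.mean_vector())
        u_d = trained_model.integrated_input(bd.category_b.mean_vector())
        assert u_b < 0 < u_d


class TestDeterminism:
    def test_identical_seeds_reproduce_training_bit_exactly(self, bd):
        cfg = TrainingConfig(n_trials=300, checkpoints=(300,), n_reps=1,
                             base_seed=5)
        a = train(bd, cfg, rep_index=0)[0]
        b = train(bd, cfg, rep_index=0)[0]
        for cue in CUES:
            np.testing.assert_array_equal(a.model.cue_mixtures[cue].mu,
                                          b.model.cue_mixtures[cue].mu)
        np.testing.assert_array_equal(a.model.integrated.phi,
                                      b.model.integrated.phi)

    def test_rep_subsets_match_slices_of_larger_runs(self, bd):
        cfg = TrainingConfig(n_trials=200, checkpoints=(200,), n_reps=3,
                             base_seed=5)
        full = train_replications(bd, cfg, backend="numpy")
        solo = train_replications(bd, cfg, reps=[2], backend="numpy")
        np.testing.assert_array_equal(full.snapshots[200].cue_mu[2],
                                      solo.snapshots[200].cue_mu[0])

    def test_parallel_workers_do_not_change_results(self, bd):
        cfg = TrainingConfig(n_trials=200, checkpoints=(200,), n_reps=4,
                             base_seed=5)
        serial = train_replications(bd, cfg, backend="numpy", n_jobs=1)
        parallel = train_replications(bd, cfg, backend="numpy", n_jobs=2)
        np.testing.assert_array_equal(serial.snapshots[200].int_mu,
                                      parallel.snapshots[200].int_mu)
        np.testing.assert_array_equal(serial.snapshots[200].weights_norm,
                                      parallel.snapshots[200].weights_norm)


class TestBatchEquivalence:
    @pytest.mark.parametrize("backend", BACKENDS)
    def test_batch_trainer_matches_per_trial_reference(self, bd, backend):
        """The vectorized trainers replay the reference loop exactly
        (token-identical streams; float agreement to 1e-9 relative)."""
        cfg = TrainingConfig(n_trials=400, checkpoints=(150, 400), n_reps=2,
                             base_seed=17)
        ref = {c.trial: c for c in train(bd, cfg, rep_index=1)}
        res = train_replications(bd, cfg, backend=backend)
        for trial in (150, 400):
            model = res.model(trial, 1)
            for cue in CUES:
                for attr in ("mu", "sigma", "phi"):
                    np.testing.assert_allclose(
                        getattr(model.cue_mixtures[cue], attr),
                        getattr(ref[trial].model.cue_mixtures[cue], attr),
                        rtol=1e-9, err_msg=f"{backend}/{cue}/{attr}@{trial}")
            np.testing.assert_allclose(model.integrated.mu,
                                       ref[trial].model.integrated.mu,
                                       rtol=1e-9)
            np.testing.assert_allclose(
                res.snapshots[trial].weights_norm[1],
                ref[trial].weights.normalized, rtol=1e-9)

    def test_independent_checkpoint_mode_reseeds_each_duration(self, bd):
        cfg = TrainingConfig(n_trials=200, checkpoints=(100, 200), n_reps=2,
                             base_seed=5, checkpoint_mode="independent")
        res = train_replications(bd, cfg, backend="numpy")
        cont = train_replications(bd, cfg.with_updates(
            checkpoint_mode="continuous"), backend="numpy")
        assert sorted(res.snapshots) == [100, 200]
        # sub-streams differ from the continuous run's stream
        assert not np.array_equal(res.snapshots[100].cue_mu,
                                  cont.snapshots[100].cue_mu)


class TestSerialization:
    def test_checkpoint_roundtrip_is_lossless(self, small_result, tmp_path):
        ck = small_result.checkpoint(2000, 1)
        path = tmp_path / "ck.json"
        ck.to_json(path)
        back = Checkpoint.from_json(path)
        assert back.rep == ck.rep and back.trial == ck.trial
        for cue in CUES:
            for attr in ("mu", "sigma", "phi"):
                np.testing.assert_array_equal(
                    getattr(back.model.cue_mixtures[cue], attr),
                    getattr(ck.model.cue_mixtures[cue], attr))
        np.testing.assert_array_equal(back.model.integrated.mu,
                                      ck.model.integrated.mu)
        np.testing.assert_array_equal(back.weights.normalized,
                                      ck.weights.normalized)

    def test_resume_from_checkpoint_matches_unpaused_run(self, bd):
        cfg = TrainingConfig(n_trials=400, checkpoints=(150, 400), n_reps=1,
                             base_seed=21)
        straight = {c.trial: c for c in train(bd, cfg, rep_index=0)}
        resumed = train(bd, cfg, rep_index=0,
                        resume_from=straight[150])[-1]
        np.testing.assert_array_equal(resumed.model.integrated.mu,
                                      straight[400].model.integrated.mu)
        for cue in CUES:
            np.testing.assert_array_equal(
                resumed.model.cue_mixtures[cue].phi,
                straight[400].model.cue_mixtures[cue].phi)
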