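"""HRF convolution, orthogonalization, high-pass basis, design assembly."""

import numpy as np
import pandas as pd
import pytest

from seqreg.design_builder import (
    HRFSpec,
    assemble_design,
    build_condition_contrast,
    build_event_regressor,
    highpass_dct,
    repetition_labels,
    serial_orthogonalize,
)
from seqreg.info_measures import randomness_table
from seqreg.sequence_sim import (
    ExperimentConfig,
    Session,
    Trial,
    generate_session,
    permitted_actions,
)

TR = 2.0


class TestHRF:
    def test_kernel_positive_integral_and_unit_sum(self):
        h = HRFSpec().kernel(dt=TR / 16)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)
        assert h[np.argmax(h)] > 0

    def test_matches_reference_canonical_shape(self):
        """Double-gamma agrees with nilearn's SPM canonical HRF up to scale."""
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        mine = HRFSpec().kernel(dt=TR / 16)
        ref = spm_hrf(TR, oversampling=16, time_length=32.0)
        m = min(len(mine), len(ref))
        r = np.corrcoef(mine[:m], ref[:m])[0, 1]
        assert r > 0.999


class TestEventRegressor:
    def test_zero_amplitudes_give_zero_column(self):
        col = build_event_regressor([10.0, 20.0], [0.0, 0.0], TR, 50)
        assert np.all(col == 0.0)

    def test_single_impulse_reproduces_sampled_kernel(self):
        spec = HRFSpec()
        col = build_event_regressor([0.0], [1.0], TR, 30, spec)
        kernel = spec.kernel(TR / spec.microtime_bins_per_TR)
        expected = kernel[spec.reference_bin() :: spec.microtime_bins_per_TR][:30]
        np.testing.assert_allclose(col[: len(expected)], expected, atol=1e-15)

    def test_superposition(self):
        a = build_event_regressor([8.0], [1.5], TR, 60)
        b = build_event_regressor([30.0], [-2.0], TR, 60)
        both = build_event_regressor([8.0, 30.0], [1.5, -2.0], TR, 60)
        np.testing.assert_allclose(both, a + b, atol=1e-12)

    def test_time_invariance_shift_by_whole_trs(self):
        k = 5
        a = build_event_regressor([10.0], [1.0], TR, 100)
        b = build_event_regressor([10.0 + k * TR], [1.0], TR, 100)
        np.testing.assert_allclose(b[k:], a[:-k], atol=1e-15)

    def test_event_after_scan_end_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_event_regressor([120.0], [1.0], TR, 50)


class TestConditionContrast:
    def _toy_session(self, conditions, errors=None):
        errors = errors or [False] * len(conditions)
        trials = []
        for i, (cond, err) in enumerate(zip(conditions, errors)):
            stim = "a" if cond == "chosen" else "e"
            trials.append(
                Trial(
                    index=i,
                    condition=cond,
                    stimulus=stim,
                    permitted=permitted_actions(stim),
                    action=None if err else permitted_actions(stim)[0],
                    onset=i * 2400.0,
                    error=err,
                )
            )
        return Session(trials=trials, config=ExperimentConfig(n_trials=4))

    def test_all_chosen_gives_plus_ones(self):
        _, amps = build_condition_contrast(self._toy_session(["chosen"] * 5))
        assert np.all(amps == 1.0)

    def test_alternating_conditions_alternate_signs(self):
        _, amps = build_condition_contrast(
            self._toy_session(["chosen", "specified"] * 3)
        )
        np.testing.assert_array_equal(amps, [1, -1, 1, -1, 1, -1])

    def test_error_trials_excluded(self):
        onsets, amps = build_condition_contrast(
            self._toy_session(["chosen", "specified", "chosen"], [False, True, False])
        )
        assert len(amps) == 2
        assert onsets.tolist() == [0.0, 4.8]


class TestSerialOrthogonalize:
    def test_column_against_itself_raises_zero_norm(self):
        v = np.random.default_rng(0).normal(size=50)
        with pytest.raises(ValueError, match="zero norm"):
            serial_orthogonalize(np.column_stack([v, v]))

    def test_already_orthogonal_column_unchanged(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=100)
        v = rng.normal(size=100)
        v -= u * (u @ v) / (u @ u)
        out = serial_orthogonalize(np.column_stack([u, v]))
        np.testing.assert_allclose(out[:, 1], v, atol=1e-12)

    def test_matches_least_squares_residual_oracle(self, rng):
        X = rng.normal(size=(200, 4))
        out = serial_orthogonalize(X)
        for j in range(1, 4):
            prior = X[:, :j]
            beta, *_ = np.linalg.lstsq(prior, X[:, j], rcond=None)
            expected = X[:, j] - prior @ beta
            np.testing.assert_allclose(out[:, j], expected, atol=1e-8)
        for i in range(4):
            for j in range(i + 1, 4):
                dot = abs(out[:, i] @ out[:, j])
                assert dot < 1e-8 * np.linalg.norm(out[:, i]) * np.linalg.norm(out[:, j])

    def test_protected_columns_pass_through(self, rng):
        X = rng.normal(size=(80, 3))
        out = serial_orthogonalize(X, n_protected=2)
        np.testing.assert_array_equal(out[:, :2], X[:, :2])


class TestHighpassDCT:
    def test_column_count_convention(self):
        basis = highpass_dct(1294, TR, 400.0)
        assert basis.shape == (1294, int(np.floor(2 * 1294 * TR / 400)) + 1)

    def test_long_cutoff_leaves_intercept_only(self):
        basis = highpass_dct(100, TR, cutoff_s=2 * 100 * TR)
        assert basis.shape[1] == 2  # constant + the single fitting cosine
        basis = highpass_dct(100, TR, cutoff_s=2 * 100 * TR + 1)
        assert basis.shape[1] == 1
        np.testing.assert_allclose(basis[:, 0], 1.0)

    def test_columns_mutually_orthogonal(self):
        basis = highpass_dct(500, TR, 400.0)
        gram = basis.T @ basis
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_grid_frequency_cosine_removed_exactly(self):
        n = 1294
        basis = highpass_dct(n, TR, 400.0)
        t = np.arange(n)
        k = basis.shape[1] - 1  # highest DCT frequency below the cutoff
        target = np.cos(np.pi * k * (2 * t + 1) / (2 * n))
        beta, *_ = np.linalg.lstsq(basis, target, rcond=None)
        resid = target - basis @ beta
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(target)

    def test_off_grid_slow_cosine_strongly_attenuated(self):
        n = 1294
        basis = highpass_dct(n, TR, 400.0)
        t = np.arange(n) * TR
        target = np.cos(2 * np.pi * t / 800.0)
        beta, *_ = np.linalg.lstsq(basis, target, rcond=None)
        resid = target - basis @ beta
        assert np.linalg.norm(resid) < 0.1 * np.linalg.norm(target)

    def test_degenerate_cutoff_rejected(self):
        with pytest.raises(ValueError):
            highpass_dct(100, TR, cutoff_s=TR)


@pytest.fixture(scope="module")
def session():
    return generate_session(ExperimentConfig(n_trials=300), seed=21)


@pytest.fixture(scope="module")
def design(session):
    return assemble_design(
        session, randomness_table(session, 25), tr=TR, n_volumes=380
    )


class TestAssembleDesign:
    def test_trim_starts_at_first_full_window(self, session, design):
        first_valid_onset = session.task_trials[24].onset / 1000.0
        retained_times = design.frame.index.to_numpy() * TR
        assert retained_times.min() >= first_valid_onset
        assert (np.flatnonzero(~design.trim_mask) * TR < first_valid_onset).all()

    def test_modulators_mean_centered_over_retained(self, design):
        for name in ("TE", "SUP", "SE", "rt"):
            assert abs(design.frame[name].mean()) < 1e-10

    def test_serial_orthogonality_chain(self, design):
        X = design.matrix
        chain = ["onset", "condition", "TE", "SUP", "SE"]
        idx = [design.columns.index(c) for c in chain]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                u, v = X[:, idx[a]], X[:, idx[b]]
                assert abs(u @ v) < 1e-8 * np.linalg.norm(u) * np.linalg.norm(v)

    def test_projection_identity_span_preserved(self, session):
        """Orthogonalization re-expresses, never discards, modulator variance."""
        raw = assemble_design(
            session, randomness_table(session, 25), tr=TR, n_volumes=380,
            serial_orth=False,
        )
        orth = assemble_design(
            session, randomness_table(session, 25), tr=TR, n_volumes=380,
            serial_orth=True,
        )
        chain = ["onset", "condition", "TE", "SUP", "SE"]
        A = raw.frame[chain].to_numpy()
        B = orth.frame[chain].to_numpy()
        # every raw chain column lies in the span of the orthogonalized chain
        beta, *_ = np.linalg.lstsq(B, A, rcond=None)
        resid = A - B @ beta
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(A)

    def test_variant_without_serial_orthogonalization(self, session):
        design = assemble_design(
            session, randomness_table(session, 25), tr=TR, n_volumes=380,
            serial_orth=False,
        )
        X = design.frame
        onset = X["onset"].to_numpy()
        for name in ("TE", "SUP", "SE"):
            v = X[name].to_numpy()
            assert abs(onset @ v) < 1e-8 * np.linalg.norm(onset) * np.linalg.norm(v)
        te, sup = X["TE"].to_numpy(), X["SUP"].to_numpy()
        # the modulators keep their shared variance in this variant
        assert abs(te @ sup) > 1e-6 * np.linalg.norm(te) * np.linalg.norm(sup)

    def test_all_columns_finite(self, design):
        assert np.all(np.isfinite(design.matrix))

    def test_round_trip_through_tsv(self, design, tmp_path):
        path = design.write(tmp_path / "design.tsv")
        from seqreg.design_builder import read_design

        back = read_design(path)
        assert back.columns == design.columns
        np.testing.assert_allclose(back.matrix, design.matrix, atol=1e-10)
        assert back.provenance["serial_orthogonalization"] is True


class TestRepetitionLabels:
    def _session(self, stims, actions, conditions=None):
        trials = []
        onset = 0.0
        for i, (s, a) in enumerate(zip(stims, actions)):
            if s is None:
                trials.append(Trial(index=i, condition="null", onset=onset))
            else:
                cond = "chosen" if s in "abcd" else "specified"
                trials.append(
                    Trial(
                        index=i,
                        condition=cond,
                        stimulus=s,
                        permitted=permitted_actions(s),
                        action=a,
                        onset=onset,
                    )
                )
            onset += 2400.0
        return Session(trials=trials, config=ExperimentConfig(n_trials=4))

    def test_stimulus_repeat_and_switch(self):
        labels = repetition_labels(self._session(["a", "a", "b"], [2, 3, 3]))
        assert labels["stim_label"].tolist() == [None, "repeat", "switch"]

    def test_action_repeat_and_switch(self):
        labels = repetition_labels(self._session(["a", "b", "c"], [2, 3, 3]))
        assert labels["act_label"].tolist() == [None, "switch", "repeat"]

    def test_invariant_to_interleaved_nulls(self):
        with_nulls = self._session(
            ["a", None, "a", None, None, "b"], [2, None, 2, None, None, 4]
        )
        without = self._session(["a", "a", "b"], [2, 2, 4])
        a = repetition_labels(with_nulls)[["stim_label", "act_label"]]
        b = repetition_labels(without)[["stim_label", "act_label"]]
        assert a.values.tolist() == b.values.tolist()
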