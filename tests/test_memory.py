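"""Memory-test analyses: clip presence, the activation GLM, association
and coactivation matrices, and the phase comparison."""
import numpy as np
import pandas as pd
import pytest

from popdecode.memory import (association_matrix, clip_presence,
                              coactivation_matrix,
                              compare_phase_coactivation,
                              correlate_association_coactivation,
                              glm_activation, mtl_knockout_memory_glm,
                              phase_activated, session_activations,
                              summed_activation)
from popdecode.synthetic import (MemorySessionSpec, TimelineConfig,
                                 generate_character_timeline,
                                 generate_memory_session)


@pytest.fixture(scope="session")
def mtl_setup(movie_data):
    """A decoder that leans on character-selective hippocampal "concept
    cells" (gain 4) next to weaker cortical regions (gain 2.2), plus a
    recognition session with the reinstatement effect planted in the
    hippocampus."""
    from popdecode.decoding import DecoderSpec, train_decoder
    from popdecode.labeling import (build_frame_labels, make_fold_plan,
                                    make_window_samples)
    from popdecode.preprocess import bin_and_resample, filter_low_rate_units
    from popdecode.synthetic import UnitSpec, make_population, simulate_spikes

    timeline = movie_data["timeline"]
    pop = make_population(
        ["occipital", "superior_temporal", "frontal", "parietal"],
        {"occipital": 0, "superior_temporal": 1, "frontal": 2,
         "parietal": 3},
        n_electrodes=8, units_per_electrode=1, baseline_hz=2.0, gain=2.2)
    uid = len(pop.units)
    for el in range(8):
        gains = np.ones(4)
        gains[el % 4] = 4.0
        for _ in range(2):
            pop.units.append(UnitSpec(uid, "hippocampus", "L", el, 2.5,
                                      gains.copy()))
            uid += 1
    spikes = filter_low_rate_units(simulate_spikes(timeline, pop, seed=2))
    samples = make_window_samples(bin_and_resample(spikes),
                                  build_frame_labels(timeline))
    plan = make_fold_plan(samples.n_samples, seed=0)
    spec = DecoderSpec(architecture="lstm", hidden=24, fc_hidden=24,
                       max_epochs=7, batch_size=256, learning_rate=3e-3,
                       seed=1)
    decoder = train_decoder(samples, spec, plan, folds=[0])
    lure = generate_character_timeline(
        TimelineConfig(prevalence=0.15, duration_s=600.0), seed=99)
    mspec = MemorySessionSpec(n_clips=300, clip_len_s=3.0,
                              response_len_s=2.0, gap_s=0.5,
                              reinstatement_gain=1.0,
                              presence_threshold=0.05,
                              mtl_regions=("hippocampus",))
    session = generate_memory_session(mspec, timeline, lure, pop, seed=21)
    return {"decoder": decoder, "session": session, "samples": samples,
            "plan": plan, "pop": pop, "lure": lure, "timeline": timeline}


@pytest.fixture(scope="session")
def session_acts(mtl_setup):
    return session_activations(mtl_setup["decoder"], mtl_setup["session"])


class TestClipPresence:
    def _clips(self):
        return pd.DataFrame({
            "presence_frac_0": [0.6, 0.1], "presence_frac_1": [0.0, 0.05],
            "max_size_0": [0.3, 0.2], "max_size_1": [0.0, 0.1]})

    def test_threshold_rule(self):
        out = clip_presence(self._clips(), 0.5, 0.0)
        assert out[0, 0] and not out[1, 0] and not out[0, 1]

    def test_zero_thresholds_mean_any_occurrence(self):
        out = clip_presence(self._clips(), 0.0, 0.0)
        assert out.all()        # frac >= 0 always holds

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            clip_presence(self._clips(), 1.5, 0.0)


class TestAssociation:
    def test_hand_worked_example(self):
        scenes = pd.DataFrame({
            "duration_s": [10.0, 10.0, 20.0],
            "char_0": [True, True, False],
            "char_1": [True, False, True]})
        a = association_matrix(scenes)
        assert a[0, 1] == pytest.approx(10 / 30)
        assert a[1, 0] == pytest.approx(10 / 20)
        assert a[0, 0] == a[1, 1] == 1.0

    def test_loner_character_off_diagonal_zero(self):
        scenes = pd.DataFrame({
            "duration_s": [5.0, 5.0],
            "char_0": [True, False], "char_1": [False, True]})
        a = association_matrix(scenes)
        assert a[0, 1] == a[1, 0] == 0.0

    def test_absent_character_is_nan(self):
        scenes = pd.DataFrame({"duration_s": [5.0],
                               "char_0": [True], "char_1": [False]})
        a = association_matrix(scenes)
        assert np.isnan(a[:, 1]).all()

    def test_planted_cooccurrence_recovered(self):
        tl = generate_character_timeline(
            TimelineConfig(prevalence=0.15, duration_s=2520.0), seed=4)
        a = association_matrix(tl.scene_table())
        assert np.nanmax(np.abs(a - tl.planted_conditionals)) <= 0.05


class TestCoactivation:
    def _toy(self):
        clips = pd.DataFrame({
            "clip_id": range(10),
            "onset_s": np.arange(10) * 10.0,
            "offset_s": np.arange(10) * 10.0 + 4.0,
            "response_onset_s": np.arange(10) * 10.0 + 4.0,
            "response_offset_s": np.arange(10) * 10.0 + 8.0})
        times = np.arange(0.0, 100.0, 0.5)
        acts = np.zeros((len(times), 2))
        return clips, times, acts

    def test_counting_example(self):
        clips, times, acts = self._toy()
        # c1 active in 4 clips, both active in 3 of them
        for k in range(4):
            sel = (times >= 10 * k) & (times < 10 * k + 4)
            acts[sel, 1] = 0.9
            if k < 3:
                acts[sel, 0] = 0.9
        cm = coactivation_matrix(times, acts, clips, "clip")
        assert cm[0, 1] == pytest.approx(0.75)
        assert cm[1, 1] == 1.0

    def test_never_active_is_nan(self):
        clips, times, acts = self._toy()
        cm = coactivation_matrix(times, acts, clips, "clip")
        assert np.isnan(cm).all()

    def test_identical_patterns_give_ones(self):
        clips, times, acts = self._toy()
        acts[:, :] = 0.9
        cm = coactivation_matrix(times, acts, clips, "response")
        assert np.all(cm == 1.0)

    def test_invalid_phase(self):
        clips, times, acts = self._toy()
        with pytest.raises(ValueError):
            phase_activated(times, acts, clips, "recall")


class TestCorrelation:
    def test_monotone_transform_perfect_rank(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 4))
        r, p = correlate_association_coactivation(a, a ** 2 + 0.1)
        assert r == pytest.approx(1.0)

    def test_twelve_off_diagonal_pairs(self):
        a = np.arange(16, dtype=float).reshape(4, 4)
        r, p = correlate_association_coactivation(a, a)
        # perfect correlation over exactly 12 = 16 - 4 entries
        assert r == 1.0

    def test_nan_pairs_dropped(self):
        a = np.random.default_rng(1).random((4, 4))
        b = a.copy()
        b[0, 1] = np.nan
        r, p = correlate_association_coactivation(a, b)
        assert np.isfinite(r)


class TestPhaseComparison:
    def test_uniform_shift_detected(self):
        rng = np.random.default_rng(2)
        clip = rng.random((4, 4)) * 0.5
        p, med = compare_phase_coactivation(clip, clip + 0.1)
        assert p < 0.01
        assert med == pytest.approx(0.1)

    def test_identical_matrices_p_one(self):
        clip = np.full((4, 4), 0.3)
        p, med = compare_phase_coactivation(clip, clip)
        assert p == 1.0 and med == 0.0

    def test_few_pairs_warns(self):
        a = np.full((4, 4), np.nan)
        a[0, 0] = 0.2
        b = a + 0.1
        with pytest.warns(UserWarning):
            compare_phase_coactivation(a, b)


class TestGLM:
    @staticmethod
    def _planted(seed, n_clips=200, seen_coef=0.24):
        rng = np.random.default_rng(seed)
        presence = rng.random((n_clips, 4)) < 0.3
        clips = pd.DataFrame({"clip_id": range(n_clips),
                              "response_seen": rng.random(n_clips) < 0.5,
                              "is_target": rng.random(n_clips) < 0.5})
        seen = np.repeat(clips.response_seen.to_numpy(float), 4)
        act = (0.39 * presence.astype(float).ravel() + seen_coef * seen
               + rng.normal(0, 0.3, 4 * n_clips)).reshape(n_clips, 4)
        return act, clips, presence

    def test_planted_coefficients_recovered(self):
        act, clips, presence = self._planted(0)
        res = glm_activation(act, clips, presence)
        lo, hi = res.conf_int.loc["presence"]
        assert lo <= 0.39 <= hi
        lo, hi = res.conf_int.loc["seen"]
        assert lo <= 0.24 <= hi
        assert res.pvalues["presence"] < 1e-4

    def test_interaction_term_available(self):
        act, clips, presence = self._planted(1)
        res = glm_activation(act, clips, presence, interaction=True)
        assert "presence_x_seen" in res.terms

    def test_too_few_clips_rejected(self):
        act, clips, presence = self._planted(2, n_clips=20)
        with pytest.raises(ValueError):
            glm_activation(act, clips, presence)

    def test_constant_presence_rejected(self):
        act, clips, _ = self._planted(3)
        with pytest.raises(ValueError, match="constant|degenerate"):
            glm_activation(act, clips, np.ones((200, 4), dtype=bool))

    def test_summed_activation_window(self):
        clips = pd.DataFrame({
            "clip_id": [0], "onset_s": [10.0], "offset_s": [13.0],
            "response_onset_s": [13.0], "response_offset_s": [15.0]})
        times = np.arange(0, 20, 0.5)
        acts = np.ones((len(times), 1))
        out = summed_activation(times, acts, clips)      # [10, 12): 4 samples
        assert out[0, 0] == 4.0
        out2 = summed_activation(times, acts, clips, anchor="pre_response")
        assert out2[0, 0] == 4.0


class TestEndToEndMemory:
    def test_seen_effect_via_mtl_reinstatement(self, mtl_setup):
        """The planted MTL reinstatement makes the subjective 'seen'
        response a significant predictor of model activation; zeroing
        the MTL units removes the effect while presence survives."""
        pre, post = mtl_knockout_memory_glm(
            mtl_setup["decoder"], mtl_setup["session"], ("hippocampus",))
        assert pre.pvalues["seen"] < 0.05
        assert pre.params["seen"] > 0
        assert post.pvalues["presence"] < 0.05
        assert post.pvalues["seen"] > pre.pvalues["seen"]

    def test_empty_mtl_set_gives_identical_glms(self, mtl_setup):
        with pytest.warns(UserWarning):
            pre, post = mtl_knockout_memory_glm(
                mtl_setup["decoder"], mtl_setup["session"], ("amygdala",))
        assert np.allclose(pre.params, post.params)

    def test_decoder_worse_on_clips_than_movie(self, mtl_setup,
                                               session_acts):
        """Context change: held-out movie accuracy bounds memory-clip
        accuracy for matched signal strength."""
        from popdecode.decoding import evaluate_metrics, fold_metrics
        from popdecode.labeling import NO, YES
        times, acts = session_acts
        session = mtl_setup["session"]
        pres = clip_presence(session.clips)
        act = phase_activated(times, acts, session.clips, "clip")
        truth = np.where(pres, YES, NO).astype(np.int8)
        clip_rep = evaluate_metrics(act, truth)
        movie_rep = fold_metrics(mtl_setup["decoder"],
                                 mtl_setup["samples"],
                                 mtl_setup["plan"])[0]
        assert clip_rep.macro["accuracy"] <= movie_rep.macro["accuracy"]

    def test_accuracy_rises_with_prominence_thresholds(self, mtl_setup,
                                                       session_acts):
        """Clip-decoding accuracy is non-decreasing as the presence and
        size thresholds defining 'character in clip' are raised: more
        prominent characters are easier to decode."""
        from popdecode.decoding import evaluate_metrics
        from popdecode.labeling import NO, YES
        from scipy import stats
        times, acts = session_acts
        session = mtl_setup["session"]
        # clip-level detection: time-averaged activation above 0.5 (the
        # phase-maximum rule is reserved for coactivation counting)
        det = np.zeros((len(session.clips), acts.shape[1]), dtype=bool)
        for i, row in session.clips.iterrows():
            sel = (times >= row.onset_s) & (times < row.offset_s)
            det[i] = acts[sel].mean(axis=0) > 0.5

        def accuracy(prev_t, size_t):
            pres = clip_presence(session.clips, prev_t, size_t)
            truth = np.where(pres, YES, NO).astype(np.int8)
            return evaluate_metrics(det, truth).macro["accuracy"]

        prev_sweep = [accuracy(t, 0.0) for t in (0.1, 0.2, 0.3, 0.4, 0.5)]
        size_sweep = [accuracy(0.1, t) for t in (0.0, 0.05, 0.1, 0.15)]
        assert stats.spearmanr(range(5), prev_sweep).statistic >= 0
        assert stats.spearmanr(range(4), size_sweep).statistic >= 0

    def test_response_phase_coactivation_with_assoc_drive(self, mtl_setup):
        spec = MemorySessionSpec(n_clips=100, clip_len_s=3.0,
                                 response_len_s=2.0, gap_s=0.5,
                                 reinstatement_gain=0.8, assoc_drive=2.0,
                                 mtl_regions=("hippocampus",
                                              "superior_temporal",
                                              "occipital", "frontal",
                                              "parietal"))
        ses = generate_memory_session(spec, mtl_setup["timeline"],
                                      mtl_setup["lure"],
                                      mtl_setup["pop"], seed=31)
        times, acts = session_activations(mtl_setup["decoder"], ses)
        cm_clip = coactivation_matrix(times, acts, ses.clips, "clip")
        cm_resp = coactivation_matrix(times, acts, ses.clips, "response")
        p, med = compare_phase_coactivation(cm_clip, cm_resp)
        assert med > 0
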