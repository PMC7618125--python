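"""Synthetic generators: trial sequences, planted geometry, BOLD, audio,
behavior and group simulation."""

import numpy as np
import pytest

import voicersa as v
from voicersa import acoustics
from voicersa.simulate import run_length_scans


class TestTrialSequence:
    def test_default_design_counts(self):
        seq = v.make_trial_sequence(v.StudyDesign(), seed=0)
        assert seq.n_experimental == 72
        assert seq.n_null == 24
        assert seq.n_trials == 96

    def test_degenerate_single_trial_design(self):
        d = v.StudyDesign(n_identities=1, n_clips_per_identity=1,
                          n_reps_per_clip=1, n_null=0)
        seq = v.make_trial_sequence(d, seed=0)
        assert seq.n_trials == 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            v.StudyDesign(n_identities=0)
        with pytest.raises(ValueError):
            v.StudyDesign(stim_dur_range_s=(3.0, 2.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_each_item_repeats_exactly_n_reps(self, seed):
        d = v.StudyDesign()
        seq = v.make_trial_sequence(d, seed=seed)
        exp = seq.frame[seq.frame["kind"] == "experimental"]
        counts = exp.groupby(["identity", "clip"]).size()
        assert (counts == d.n_reps_per_clip).all()
        assert len(counts) == 24

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_no_item_repeats_back_to_back(self, seed):
        seq = v.make_trial_sequence(v.StudyDesign(), seed=seed)
        rows = list(seq.frame[["kind", "identity", "clip"]].itertuples(index=False))
        for a, b in zip(rows, rows[1:]):
            if a.kind == b.kind == "experimental":
                assert (a.identity, a.clip) != (b.identity, b.clip)

    def test_onsets_strictly_increasing_and_durations_in_range(self):
        d = v.StudyDesign()
        seq = v.make_trial_sequence(d, seed=9)
        assert (np.diff(seq.frame["onset_s"]) > 0).all()
        exp = seq.frame[seq.frame["kind"] == "experimental"]
        assert exp["duration_s"].between(*d.stim_dur_range_s).all()

    def test_deterministic_given_seed(self):
        a = v.make_trial_sequence(v.StudyDesign(), run_index=1, seed=5)
        b = v.make_trial_sequence(v.StudyDesign(), run_index=1, seed=5)
        c = v.make_trial_sequence(v.StudyDesign(), run_index=2, seed=5)
        assert a.frame.equals(b.frame)
        assert not a.frame.equals(c.frame)

    def test_timeout_response_placed_at_prompt_plus_mean_rt(self):
        seq = v.make_trial_sequence(v.StudyDesign(), seed=3, p_timeout=0.3)
        f = seq.frame
        exp = f[f["kind"] == "experimental"]
        responded = exp[~exp["timeout"]]
        mean_rt = (responded["response_event_s"]
                   - responded["response_prompt_s"]).mean()
        timed_out = exp[exp["timeout"]]
        assert len(timed_out) > 0
        np.testing.assert_allclose(
            timed_out["response_event_s"],
            timed_out["response_prompt_s"] + mean_rt)

    def test_csv_roundtrip(self, tmp_path):
        seq = v.make_trial_sequence(v.StudyDesign(), seed=1)
        seq.to_csv(tmp_path / "seq.csv")
        back = v.simulate.TrialSequence.from_csv(tmp_path / "seq.csv")
        assert back.n_trials == seq.n_trials
        np.testing.assert_allclose(back.frame["onset_s"], seq.frame["onset_s"])


class TestPlantPatterns:
    def test_zero_geometry_gives_identical_patterns(self, labels24):
        geom = v.PlantedGeometry({i: 0.0 for i in ("Familiar", "Lab", "New")},
                                 between=0.0, n_signal_voxels=500)
        pats = v.plant_patterns(geom, labels24, seed=0)
        d = v.compute_ondm(pats, labels24).vector()
        assert np.nanmax(np.abs(d)) < 0.05

    def test_target_one_gives_independent_patterns(self):
        labels = [("Familiar", 0), ("Familiar", 1)]
        geom = v.PlantedGeometry({"Familiar": 1.0}, n_signal_voxels=10_000)
        pats = v.plant_patterns(geom, labels, seed=1)
        d = v.compute_ondm(pats, labels).values[0, 1]
        assert abs(d - 1.0) < 0.05

    def test_familiar_exceeds_lab_by_planted_gap(self, labels24):
        """Monte-Carlo over 100 seeds: within-class means track targets."""
        geom = v.PlantedGeometry({"Familiar": 0.8, "Lab": 0.4, "New": 0.4},
                                 1.0, n_signal_voxels=400)
        classes = None
        diffs = []
        for seed in range(100):
            pats = v.plant_patterns(geom, labels24, seed=seed)
            rdm = v.compute_ondm(pats, labels24)
            vec = rdm.vector()
            if classes is None:
                classes = rdm.pair_classes()
            wf = vec[[c == ("Familiar", "Familiar") for c in classes]].mean()
            wl = vec[[c == ("Lab", "Lab") for c in classes]].mean()
            diffs.append(wf - wl)
        assert np.mean(diffs) == pytest.approx(0.4, abs=0.05)

    def test_geometry_fidelity_noise_free(self, labels24):
        """Planted and empirical ONDM cells agree within 0.05 (20 seeds)."""
        geom = v.PlantedGeometry({"Familiar": 0.8, "Lab": 0.4, "New": 0.4},
                                 1.2, n_signal_voxels=5000)
        target = geom.target_matrix(labels24)
        i, j = np.triu_indices(24, k=1)
        acc = np.zeros(len(i))
        n_seeds = 20
        for seed in range(n_seeds):
            pats = v.plant_patterns(geom, labels24, seed=1000 + seed)
            acc += v.compute_ondm(pats, labels24).vector()
        assert np.abs(acc / n_seeds - target[i, j]).max() < 0.05

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            v.PlantedGeometry({"Familiar": 2.5})

    def test_unrepairable_geometry_rejected(self):
        # three mutually anticorrelated identities cannot coexist
        labels = [("Familiar", 0), ("Lab", 0), ("New", 0)]
        geom = v.PlantedGeometry({i: 0.0 for i in ("Familiar", "Lab", "New")},
                                 between=2.0)
        with pytest.raises(ValueError, match="positive semidefinite"):
            v.plant_patterns(geom, labels, seed=0)

    def test_noise_attenuates_correlation(self, labels24):
        geom = v.PlantedGeometry({i: 0.0 for i in ("Familiar", "Lab", "New")},
                                 0.0, n_signal_voxels=2000, noise_sd=1.0)
        pats = v.plant_patterns(geom, labels24, seed=3)
        d = v.compute_ondm(pats, labels24).vector()
        # unit signal + unit noise: expected 1 - 1/(1+1) = 0.5
        assert np.mean(d) == pytest.approx(0.5, abs=0.05)


class TestSimulateBold:
    def test_zero_patterns_give_pure_noise(self, small_design):
        labels = small_design.item_labels()
        seq = v.make_trial_sequence(small_design, seed=2)
        bold, _ = v.simulate_bold_run(np.zeros((len(labels), 200)), seq,
                                      small_design, noise_sd=1.5, seed=0,
                                      item_labels=labels)
        assert bold.std() == pytest.approx(1.5, rel=0.05)
        assert bold.shape[0] == run_length_scans(seq, small_design)

    def test_run_covers_last_event_plus_hrf_tail(self, small_design):
        seq = v.make_trial_sequence(small_design, seed=2)
        n = run_length_scans(seq, small_design)
        assert n >= seq.end_s + 30 - 1
        assert (n - 1) * small_design.tr_s < seq.end_s + 31

    def test_item_mismatch_rejected(self, small_design):
        seq = v.make_trial_sequence(small_design, seed=2)
        with pytest.raises(ValueError, match="without patterns"):
            v.simulate_bold_run(np.zeros((2, 10)), seq, small_design,
                                item_labels=[("Familiar", 0), ("Familiar", 1)])

    def test_forward_inverse_rdm_recovery(self, small_design, rng):
        """BOLD round trip preserves the planted geometry (rank corr > 0.9)."""
        from scipy.stats import spearmanr

        design = v.StudyDesign(n_clips_per_identity=4, n_reps_per_clip=2,
                               n_null=8, n_runs=2)
        labels = design.item_labels()
        geom = v.PlantedGeometry({"Familiar": 0.8, "Lab": 0.4, "New": 0.4},
                                 1.0, n_signal_voxels=150)
        pats = v.plant_patterns(geom, labels, seed=rng)
        runs, dms = [], []
        for r in range(design.n_runs):
            seq = v.make_trial_sequence(design, r, seed=21)
            bold, dm = v.simulate_bold_run(pats, seq, design, noise_sd=1.0,
                                           seed=100 + r, item_labels=labels)
            runs.append(bold)
            dms.append(dm)
        tmap = v.fit_item_tmaps(runs, dms)
        true_vec = v.compute_ondm(pats, labels).vector()
        rec_vec = v.compute_ondm(tmap.t, labels).vector()
        assert spearmanr(true_vec, rec_vec).statistic > 0.9


class TestAudio:
    def test_identical_recipes_are_acoustically_identical(self):
        r = v.ClipRecipe((300.0, 900.0), (1.0, 0.4), duration_s=1.0)
        clips = v.simulate_audio_clips([r, r], seed=0, sample_rate=8000)
        ltas = [acoustics.compute_ltas(c, 8000, 512, 128) for c in clips]
        rdm = acoustics.acoustic_rdm(ltas, [("A", 0), ("A", 1)])
        assert rdm.values[0, 1] < 1e-6

    def test_disjoint_bands_are_nearly_orthogonal(self):
        clips = v.simulate_audio_clips(
            [v.ClipRecipe((300.0,), (1.0,), 1.0),
             v.ClipRecipe((3300.0,), (1.0,), 1.0)], seed=0, sample_rate=8000)
        ltas = [acoustics.compute_ltas(c, 8000, 512, 128) for c in clips]
        rdm = acoustics.acoustic_rdm(ltas, [("A", 0), ("B", 0)])
        assert rdm.values[0, 1] > 0.99

    def test_amplitude_scaling_is_invisible(self):
        clip = v.simulate_audio_clips([v.ClipRecipe((440.0,), (0.9,), 1.0)],
                                      seed=0, sample_rate=8000)[0]
        ltas = [acoustics.compute_ltas(c, 8000, 512, 128)
                for c in (clip, 0.25 * clip)]
        rdm = acoustics.acoustic_rdm(ltas, [("A", 0), ("A", 1)])
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        r = [v.ClipRecipe((500.0,), (1.0,), 0.5, noise_sd=0.1)]
        a = v.simulate_audio_clips(r, seed=4, sample_rate=8000)[0]
        b = v.simulate_audio_clips(r, seed=4, sample_rate=8000)[0]
        np.testing.assert_array_equal(a, b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            v.ClipRecipe((100.0,), (1.0,), duration_s=0.0)
        with pytest.raises(ValueError):
            v.simulate_audio_clips([v.ClipRecipe((100.0,), (1.0,))],
                                   sample_rate=0)

    def test_wav_roundtrip(self, tmp_path):
        clip = v.simulate_audio_clips([v.ClipRecipe((440.0,), (0.9,), 0.25)],
                                      seed=0, sample_rate=8000)[0]
        v.simulate.write_wav(tmp_path / "c.wav", clip, 8000)
        back, sr = acoustics.read_audio(tmp_path / "c.wav")
        assert sr == 8000
        assert np.corrcoef(back, clip)[0, 1] > 0.999


class TestSimulateBehavior:
    def test_identity_matrix_gives_perfect_hu(self):
        trials = v.simulate_behavior(np.eye(3), 40, seed=0)
        table = v.confusion_table(trials)
        for cat in table.categories:
            assert v.unbiased_hit_rate(table, cat).hu == 1.0

    def test_uniform_confusion_hu_expectation(self):
        # Hu of the expected-count table under uniform 1/3 responding is 1/9
        import pandas as pd

        from voicersa.behavior import ConfusionTable
        counts = pd.DataFrame(np.full((3, 3), 100.0),
                              index=list("abc"), columns=list("abc"))
        table = ConfusionTable(counts, pd.Series(0.0, index=list("abc")))
        for cat in "abc":
            assert v.unbiased_hit_rate(table, cat).hu == pytest.approx(1 / 9)
        # empirical draw converges toward the same value
        trials = v.simulate_behavior(np.full((3, 3), 1 / 3), 3000, seed=1)
        emp = v.confusion_table(trials)
        hus = [v.unbiased_hit_rate(emp, c).hu for c in emp.categories]
        np.testing.assert_allclose(hus, 1 / 9, atol=0.02)

    def test_never_chosen_category_has_zero_hu(self):
        probs = np.array([[0.0, 0.5, 0.5], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        trials = v.simulate_behavior(probs, 30, seed=2)
        table = v.confusion_table(trials)
        assert v.unbiased_hit_rate(table, table.categories[0]).hu == 0.0

    def test_timeout_mass_generates_timeouts(self):
        probs = np.full((3, 3), 0.2)  # rows sum to 0.6 -> 40% timeouts
        trials = v.simulate_behavior(probs, 500, seed=3)
        assert trials["timeout"].mean() == pytest.approx(0.4, abs=0.05)

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError, match="at most 1"):
            v.simulate_behavior(np.full((2, 2), 0.8), 10)
        with pytest.raises(ValueError, match="nonnegative"):
            v.simulate_behavior(np.array([[1.2, -0.2], [0.5, 0.5]]), 10)


class TestSimulateGroup:
    def test_reproducible_from_master_seed(self):
        d = v.StudyDesign(n_clips_per_identity=3)
        geom = v.PlantedGeometry({"Familiar": 0.8, "Lab": 0.4, "New": 0.4})
        spec = v.MaskSpec(shape=(10, 4, 3), signal_box=((0, 4), (0, 4), (0, 3)),
                          null_box=((6, 10), (0, 4), (0, 3)))
        a = v.simulate_group(d, geom, 3, spec, seed=11)
        b = v.simulate_group(d, geom, 3, spec, seed=11)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.patterns, sb.patterns)
        for ra, rb in zip(a.acoustic, b.acoustic):
            np.testing.assert_array_equal(ra.vector(), rb.vector())

    def test_subjects_have_independent_noise(self):
        d = v.StudyDesign(n_clips_per_identity=3)
        geom = v.PlantedGeometry.null()
        sim = v.simulate_group(d, geom, 2, v.MaskSpec(
            shape=(6, 4, 3), signal_box=((0, 6), (0, 4), (0, 3)),
            null_box=None), seed=0)
        assert not np.allclose(sim.subjects[0].patterns,
                               sim.subjects[1].patterns)

    def test_empty_mask_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            v.MaskSpec(shape=(4, 4, 4), signal_box=((2, 2), (0, 4), (0, 4)),
                       null_box=None).build()

    def test_signal_and_null_indices_partition_mask(self):
        spec = v.MaskSpec(shape=(10, 4, 3), signal_box=((0, 4), (0, 4), (0, 3)),
                          null_box=((6, 10), (0, 4), (0, 3)))
        sim = v.simulate_group(v.StudyDesign(n_clips_per_identity=2),
                               v.PlantedGeometry.null(), 1, spec, seed=0)
        sig, nul = sim.signal_indices(), sim.null_indices()
        assert len(sig) + len(nul) == sim.mask.n_voxels
        assert not set(sig) & set(nul)

    def test_via_bold_path_preserves_geometry(self):
        from scipy.stats import spearmanr

        d = v.StudyDesign(n_clips_per_identity=2, n_reps_per_clip=2, n_null=6,
                          n_runs=2)
        geom = v.PlantedGeometry({"Familiar": 0.9, "Lab": 0.3, "New": 0.3}, 1.0)
        spec = v.MaskSpec(shape=(5, 5, 4), signal_box=((0, 5), (0, 5), (0, 4)),
                          null_box=None)
        sim = v.simulate_group(d, geom, 1, spec, seed=5, via_bold=True,
                               bold_noise_sd=0.5)
        labels = d.item_labels()
        truth = geom.target_matrix(labels)
        i, j = np.triu_indices(len(labels), k=1)
        rec = v.compute_ondm(sim.subjects[0].patterns, labels).vector()
        assert spearmanr(truth[i, j], rec).statistic > 0.5
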