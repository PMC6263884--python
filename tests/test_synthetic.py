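import numpy as np
import pytest

import skitech as sk
from skitech.io import TECHNIQUES, ValidationError
from skitech import synthetic as syn


class TestTemplates:
    def test_eight_templates_with_correct_styles(self, templates):
        assert sorted(templates) == list(range(1, 9))
        for code, tpl in templates.items():
            assert tpl.style == TECHNIQUES[code][1]
            assert tpl.amps.shape == (51, syn.N_HARMONICS)

    def test_pelvis_amplitudes_below_limb_amplitudes(self, templates):
        pelvis = [i for i, c in enumerate(syn._CHANNELS) if c.startswith("pelvis")]
        for tpl in templates.values():
            assert tpl.amps[pelvis].max() <= tpl.amps[syn._LIMB_COLS].max()

    def test_limb_channels_discriminate_classes(self, templates):
        """Every pair of same-style templates differs on extremity channels."""
        n = 200
        for a in range(1, 9):
            for b in range(a + 1, 9):
                if TECHNIQUES[a][1] != TECHNIQUES[b][1]:
                    continue
                wa = templates[a].waveform(n)[:, syn._LIMB_COLS]
                wb = templates[b].waveform(n)[:, syn._LIMB_COLS]
                assert np.abs(wa - wb).max() > 0.1

    def test_reference_channel_peaks_at_cycle_start(self, templates):
        for tpl in templates.values():
            w = tpl.channel_waveform(syn.REFERENCE_CHANNEL, 333)
            assert np.argmax(w) in (0, 332)


class TestConfusablePair:
    def test_similarity_one_is_identical(self, templates):
        twin = syn.make_confusable_pair(templates[4], 1.0, code=2)
        np.testing.assert_allclose(twin.waveform(100), templates[4].waveform(100), atol=1e-12)

    def test_similarity_zero_is_independent(self, templates):
        rng = np.random.default_rng(11)
        corrs = []
        for _ in range(10):
            indep = syn.make_confusable_pair(templates[4], 0.0, code=2, rng=rng)
            wa, wb = templates[4].waveform(300), indep.waveform(300)
            for c in range(51):
                if wa[:, c].std() > 0 and wb[:, c].std() > 0:
                    corrs.append(np.corrcoef(wa[:, c], wb[:, c])[0, 1])
        assert abs(np.mean(corrs)) < 0.3

    def test_nonextremity_channels_shared(self, templates):
        pair = templates[2]
        assert pair.confusable_with == 4
        shared = [i for i in range(51) if i not in syn._LIMB_COLS and i != syn._REF_COL]
        np.testing.assert_allclose(pair.amps[shared], templates[4].amps[shared], atol=1e-12)

    def test_similarity_validated(self, templates):
        with pytest.raises(ValidationError):
            syn.make_confusable_pair(templates[4], 1.5, code=2)


class TestGenerateRecording:
    def test_deterministic_same_seed(self, templates):
        plan = syn.default_plan(1, 3)
        a = syn.generate_dataset(plan, seed=9)
        b = syn.generate_dataset(plan, seed=9)
        for (ra, ta, ba), (rb, tb, bb) in zip(a, b):
            np.testing.assert_array_equal(ra.values, rb.values)
            assert ta.intervals == tb.intervals
            np.testing.assert_array_equal(ba, bb)

    def test_different_seed_differs(self):
        plan = syn.default_plan(1, 3)
        a = syn.generate_dataset(plan, seed=9)[0][0]
        b = syn.generate_dataset(plan, seed=10)[0][0]
        assert not np.array_equal(a.values, b.values)

    def test_zero_jitter_zero_noise_exact_length(self, templates):
        profile = syn.SubjectProfile("S1", {t: 1.0 for t in sk.TRACKERS},
                                     tempo_mean=300, tempo_jitter=0.0, noise_sigma=0.0)
        recipe = syn.FileRecipe("S1", "flat", "classical", ((1, 10),))
        rec, track, bounds = syn.generate_recording(recipe, templates, profile, seed=0)
        n = int(round(300 * templates[1].tempo_factor))
        (s, e, lab), = track.technique_intervals()
        assert e - s == 10 * n
        assert len(bounds) == 10
        np.testing.assert_array_equal(np.diff(bounds), n)

    def test_recording_passes_io_validation_and_round_trips(self, templates, tmp_path):
        plan = syn.SimPlan((syn.FileRecipe("S1", "natural", "skating", ((5, 3), (7, 3))),))
        rec, track, _ = syn.generate_dataset(plan, seed=2)[0]
        assert rec.n_channels == 51
        labs = [lab for _, _, lab in track.intervals]
        assert 9 in labs and "TURN" not in labs  # descents, not turns, on natural
        sk.write_recording(rec, tmp_path / "r.csv")
        sk.write_labels(track, tmp_path / "r.labels.csv")
        back = sk.read_recording(tmp_path / "r.csv", subject_id="S1", course="natural")
        assert sk.read_labels(tmp_path / "r.labels.csv", back).intervals == track.intervals

    def test_style_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="not classical"):
            syn.FileRecipe("S1", "flat", "classical", ((5, 3),))

    def test_flat_files_use_turn_noise(self, templates):
        plan = syn.SimPlan((syn.FileRecipe("S1", "flat", "classical", ((1, 3), (3, 3))),))
        _, track, _ = syn.generate_dataset(plan, seed=2)[0]
        assert any(lab == "TURN" for _, _, lab in track.intervals)


class TestPlans:
    def test_default_plan_structure(self):
        plan = syn.default_plan(3, 12)
        assert len(plan.files) == 12
        assert plan.subjects == ["S1", "S2", "S3"]
        natural = [f for f in plan.files if f.course == "natural"]
        codes = {c for f in natural for c, _ in f.blocks}
        assert 8 not in codes and 2 not in codes  # imbalance: no FS/P-Off analogs

    def test_fixture_plan_bookkeeping(self):
        plan = syn.fixture_plan()
        assert len(plan.files) == 24
        rendered = sum(n for f in plan.files for _, n in f.blocks)
        printed = sum(v for row in syn.FIXTURE_CYCLE_COUNTS.values() for v in row.values())
        assert printed == 2067
        assert rendered == 2067 + 2 * 24  # two partial cycles per file
        assert sum(v for v in syn.FIXTURE_CYCLE_COUNTS["skier1"].values()) == 960


class TestConfusabilityMonotonicity:
    """More similar templates must confuse the classifier more."""

    @staticmethod
    def pair_confusion(similarity, seed):
        import skitech as sk
        from skitech.evaluation import confusion

        templates = syn.default_templates()
        # codes 5 and 8 share a tempo factor, so no length cue separates them
        templates[8] = syn.make_confusable_pair(templates[5], similarity, code=8)
        plan = syn.SimPlan(tuple(
            syn.FileRecipe(sid, "flat", "skating", ((5, 12), (8, 12)))
            for sid in ("S1", "S2")))
        cs = syn.build_cycles(plan, seed, templates=templates)
        cs = cs.select_channels(sk.PRESETS["sports_biomechanics"])
        subj = cs.provenance["subject"].to_numpy()
        train, test = cs.subset(subj == "S1"), cs.subset(subj == "S2")
        with pytest.warns(UserWarning, match="missing classes"):
            model = sk.CNNLSTMClassifier(sk.ModelSpec()).fit(train, seed=seed)
        pred, _ = model.predict(test)
        mat = confusion(test.labels, pred)
        return int(mat[4, 7] + mat[7, 4])

    def test_high_similarity_confuses_more_than_low(self):
        confusions = {s: sum(self.pair_confusion(s, seed) for seed in (1, 2, 3))
                      for s in (0.9, 0.1)}
        assert confusions[0.9] > confusions[0.1]
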