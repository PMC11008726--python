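"""Segmentation stage: GFP, filtering, peak picking, AAHC, alignment,
backfitting, and explained variance — each against closed forms or
brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mstate_bold.microstates import (
    EEGRecording,
    GFPSeries,
    LabelSequence,
    MicrostateTemplateSet,
    SimilarityMatrix,
    aahc_cluster,
    align_and_average_templates,
    assign_labels,
    bandpass_filter,
    compute_gfp,
    compute_similarity,
    detect_gfp_peaks,
    explained_variance,
    sample_peaks,
)
from mstate_bold.synthetic import generate_eeg, generate_templates

from conftest import make_truth


def _matched_abs_corr(recovered: np.ndarray, planted: np.ndarray) -> np.ndarray:
    """Optimal one-to-one |cosine| matching between template sets."""
    corr = np.abs(recovered @ planted.T)
    r, c = linear_sum_assignment(-corr)
    return corr[r, c]


class TestBandpass:
    def _sine(self, freq, sfreq=250.0, dur=10.0, p=4):
        t = np.arange(0, dur, 1 / sfreq)
        data = np.vstack([np.sin(2 * np.pi * freq * t + i) for i in range(p)])
        return EEGRecording(data=data, sfreq=sfreq)

    def test_passband_amplitude_preserved(self):
        eeg = self._sine(10.0)
        out = bandpass_filter(eeg, 2.0, 20.0)
        mid = slice(500, 2000)  # avoid filter edges
        ratio = out.data[0, mid].std() / eeg.data[0, mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuated_20db(self):
        eeg = self._sine(50.0)
        out = bandpass_filter(eeg, 2.0, 20.0)
        mid = slice(500, 2000)
        atten = 20 * np.log10(eeg.data[0, mid].std() / out.data[0, mid].std())
        assert atten >= 20.0

    def test_dc_removed(self):
        eeg = EEGRecording(data=np.full((4, 2500), 3.0), sfreq=250.0)
        out = bandpass_filter(eeg, 2.0, 20.0)
        assert abs(out.data.mean()) < 1e-6

    def test_band_above_nyquist_rejected(self):
        eeg = self._sine(10.0)
        with pytest.raises(ValueError):
            bandpass_filter(eeg, 2.0, 130.0)


class TestGFP:
    def test_closed_forms(self):
        const = EEGRecording(data=np.full((5, 10), 2.0), sfreq=1.0)
        np.testing.assert_allclose(compute_gfp(const).values, 0.0)
        pair = EEGRecording(data=np.array([[1.0], [-1.0]]), sfreq=1.0)
        np.testing.assert_allclose(compute_gfp(pair).values, [1.0])

    def test_matches_per_sample_formula(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((32, 100))
        eeg = EEGRecording(data=data, sfreq=250.0)
        gfp = compute_gfp(eeg).values
        for t in range(100):
            v = data[:, t]
            expected = np.sqrt(np.sum((v - v.mean()) ** 2) / 32)
            assert abs(gfp[t] - expected) < 1e-12

    def test_zero_iff_spatially_constant(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 50))
        data[:, 10] = 5.0
        gfp = compute_gfp(EEGRecording(data=data, sfreq=1.0)).values
        assert gfp[10] == 0.0
        assert (np.delete(gfp, 10) > 0).all()


class TestPeaks:
    def test_monotone_series_has_no_peaks(self):
        gfp = GFPSeries(values=np.arange(100.0), sfreq=250.0)
        assert detect_gfp_peaks(gfp).size == 0

    def test_triangular_pulse_single_peak(self):
        v = np.zeros(101)
        v[40:61] = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        peaks = detect_gfp_peaks(GFPSeries(values=v, sfreq=250.0))
        assert peaks.tolist() == [50]

    def test_noisy_sinusoid_peak_count(self):
        # 5 Hz oscillation over 10 s -> ~50 GFP maxima despite jitter
        rng = np.random.default_rng(0)
        t = np.arange(0, 10, 1 / 250)
        v = 1 + 0.5 * np.sin(2 * np.pi * 5 * t) + 0.02 * rng.standard_normal(t.size)
        peaks = detect_gfp_peaks(GFPSeries(values=v, sfreq=250.0))
        assert abs(peaks.size - 50) <= 5

    def test_bad_intervals_excluded(self):
        t = np.arange(0, 10, 1 / 250)
        v = np.sin(2 * np.pi * 5 * t) ** 2
        all_peaks = detect_gfp_peaks(GFPSeries(values=v, sfreq=250.0))
        masked = detect_gfp_peaks(
            GFPSeries(values=v, sfreq=250.0), bad_intervals=[(0, 1250)]
        )
        assert masked.size < all_peaks.size
        assert (masked >= 1250).all()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_gfp_peaks(GFPSeries(values=np.ones(3), sfreq=1.0))

    def test_subsampling_contract(self):
        few = np.arange(500)
        np.testing.assert_array_equal(sample_peaks(few, 10000, seed=0), few)
        many = np.arange(20000)
        sub = sample_peaks(many, 10000, seed=1)
        assert sub.size == 10000 and np.unique(sub).size == 10000
        np.testing.assert_array_equal(sub, sample_peaks(many, 10000, seed=1))


class TestAAHC:
    def test_exact_recovery_of_separable_clusters(self):
        templates = generate_templates(32, 4, 0.0, seed=2)
        rng = np.random.default_rng(3)
        idx = rng.integers(0, 4, 200)
        signs = rng.choice([-1.0, 1.0], 200)
        maps = signs[:, None] * templates[idx]
        tset = aahc_cluster(maps, 4)
        assert (_matched_abs_corr(tset.templates, templates) > 1 - 1e-9).all()

    def test_recovery_on_noisy_fixture(self, default_truth, default_eeg):
        gfp = compute_gfp(default_eeg)
        peaks = sample_peaks(detect_gfp_peaks(gfp), 10000, seed=0)
        tset = aahc_cluster(default_eeg.data[:, peaks].T, 4)
        assert (_matched_abs_corr(tset.templates, default_truth.templates) >= 0.95).all()

    def test_single_cluster_is_first_principal_direction(self):
        rng = np.random.default_rng(4)
        maps = rng.standard_normal((30, 8))
        tset = aahc_cluster(maps, 1)
        centered = maps - maps.mean(axis=1, keepdims=True)
        centered /= np.linalg.norm(centered, axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        assert abs(abs(tset.templates[0] @ vt[0]) - 1.0) < 1e-9

    def test_rejects_too_few_maps(self):
        with pytest.raises(ValueError):
            aahc_cluster(np.eye(4), 4)

    def test_matches_exhaustive_two_partition_search(self):
        # on <= 30 maps and k=2 the greedy result should agree with the
        # best 2-partition by total explained variance on >= 90% of maps
        rng = np.random.default_rng(5)
        templates = generate_templates(12, 2, 0.0, seed=6)
        idx = rng.integers(0, 2, 16)
        maps = templates[idx] + 0.25 * rng.standard_normal((16, 12))
        maps -= maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)

        def partition_ev(assign):
            ev = 0.0
            for lab in (0, 1):
                sub = maps[assign == lab]
                if len(sub) == 0:
                    return -np.inf
                ev += np.linalg.eigvalsh(sub.T @ sub)[-1]
            return ev

        best_ev, best_assign = -np.inf, None
        for bits in itertools.product([0, 1], repeat=15):
            assign = np.array((0,) + bits)
            ev = partition_ev(assign)
            if ev > best_ev:
                best_ev, best_assign = ev, assign

        tset = aahc_cluster(maps, 2)
        sim = compute_similarity(
            EEGRecording(data=maps.T, sfreq=1.0), tset
        )
        greedy = assign_labels(sim).labels - 1
        agreement = max(
            np.mean(greedy == best_assign), np.mean(greedy == 1 - best_assign)
        )
        assert agreement >= 0.90


class TestAlignment:
    def test_permuted_sign_flipped_subjects_recover_reference(self):
        ref = MicrostateTemplateSet(
            templates=generate_templates(16, 4, 0.0, seed=7),
            labels=list("ABCD"),
        )
        rng = np.random.default_rng(8)
        subjects = []
        for _ in range(5):
            perm = rng.permutation(4)
            signs = rng.choice([-1.0, 1.0], 4)
            subjects.append(
                MicrostateTemplateSet(
                    templates=signs[:, None] * ref.templates[perm], labels=list("ABCD")
                )
            )
        group = align_and_average_templates(subjects, reference=ref)
        np.testing.assert_allclose(group.templates, ref.templates, atol=1e-12)

    def test_group_mean_beats_individual_noise(self):
        ref = MicrostateTemplateSet(
            templates=generate_templates(16, 4, 0.0, seed=9), labels=list("ABCD")
        )
        rng = np.random.default_rng(10)
        subjects = []
        for _ in range(8):
            noisy = ref.templates + 0.2 * rng.standard_normal((4, 16))
            noisy -= noisy.mean(axis=1, keepdims=True)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            subjects.append(
                MicrostateTemplateSet(templates=noisy, labels=list("ABCD"))
            )
        group = align_and_average_templates(subjects, reference=ref)
        group_corr = np.diag(np.abs(group.templates @ ref.templates.T)).min()
        indiv = [
            np.diag(np.abs(s.templates @ ref.templates.T)).min() for s in subjects
        ]
        assert group_corr >= max(indiv)

    def test_single_subject_passthrough(self):
        ref = MicrostateTemplateSet(
            templates=generate_templates(16, 4, 0.0, seed=11), labels=list("ABCD")
        )
        group = align_and_average_templates([ref], reference=ref)
        np.testing.assert_allclose(group.templates, ref.templates, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        a = MicrostateTemplateSet(
            templates=generate_templates(16, 4, 0.0, seed=1), labels=list("ABCD")
        )
        b = MicrostateTemplateSet(
            templates=generate_templates(12, 4, 0.0, seed=1), labels=list("ABCD")
        )
        with pytest.raises(ValueError):
            align_and_average_templates([a, b])


class TestBackfitting:
    def _tset(self, seed=12, p=16):
        return MicrostateTemplateSet(
            templates=generate_templates(p, 4, 0.0, seed=seed), labels=list("ABCD")
        )

    def test_similarity_of_templates_and_their_negations(self):
        tset = self._tset()
        data = np.vstack([tset.templates[1], -tset.templates[1]]).T
        sim = compute_similarity(EEGRecording(data=data, sfreq=1.0), tset)
        np.testing.assert_allclose(sim.values[:, 1], 1.0, atol=1e-9)

    def test_orthogonal_sample_scores_zero(self):
        tset = self._tset()
        # build a zero-mean map orthogonal to all four templates
        rng = np.random.default_rng(13)
        v = rng.standard_normal(16)
        v -= v.mean()
        for t in tset.templates:
            v -= (v @ t) * t
        v -= v.mean()
        sim = compute_similarity(EEGRecording(data=np.vstack([v, v]).T, sfreq=1.0), tset)
        assert np.abs(sim.values).max() < 1e-9

    def test_winner_take_all_and_tie_rule(self):
        f = SimilarityMatrix(
            values=np.array([[0.9, 0.1, 0.2, 0.3], [0.1, 0.5, 0.5, 0.2]]),
            flagged=np.zeros(2, dtype=bool),
        )
        labels = assign_labels(f)
        assert labels.labels.tolist() == [1, 2]  # tie between 2 and 3 -> 2

    def test_flagged_samples_carry_previous_label(self):
        f = SimilarityMatrix(
            values=np.array([[0.0, 0.0], [0.2, 0.9], [0.0, 0.0]]),
            flagged=np.array([True, False, True]),
        )
        assert assign_labels(f).labels.tolist() == [1, 2, 2]

    def test_label_runs_follow_generated_sequence(self):
        truth = make_truth(noise_sd=0.0, duration_s=5.0)
        eeg = generate_eeg(truth)
        tset = MicrostateTemplateSet(templates=truth.templates, labels=list("ABCD"))
        labels = assign_labels(compute_similarity(eeg, tset), sfreq=eeg.sfreq)
        np.testing.assert_array_equal(labels.labels, truth.state_sequence)


class TestExplainedVariance:
    def test_noiseless_correct_labels_give_total_one(self):
        truth = make_truth(noise_sd=0.0, duration_s=5.0)
        eeg = generate_eeg(truth)
        tset = MicrostateTemplateSet(templates=truth.templates, labels=list("ABCD"))
        labels = LabelSequence(labels=truth.state_sequence, sfreq=250.0, k=4)
        gev = explained_variance(eeg, tset, labels)
        assert abs(gev["total"] - 1.0) < 1e-9
        assert abs(sum(gev[n] for n in "ABCD") - gev["total"]) < 1e-12

    def test_random_labels_explain_less(self):
        truth = make_truth(noise_sd=0.0, duration_s=5.0)
        eeg = generate_eeg(truth)
        tset = MicrostateTemplateSet(templates=truth.templates, labels=list("ABCD"))
        rng = np.random.default_rng(14)
        scrambled = LabelSequence(
            labels=rng.integers(1, 5, truth.state_sequence.size), sfreq=250.0, k=4
        )
        correct = LabelSequence(labels=truth.state_sequence, sfreq=250.0, k=4)
        assert (
            explained_variance(eeg, tset, scrambled)["total"]
            < explained_variance(eeg, tset, correct)["total"]
        )

    def test_matches_per_sample_oracle(self, default_eeg, default_truth):
        tset = MicrostateTemplateSet(
            templates=default_truth.templates, labels=list("ABCD")
        )
        labels = assign_labels(compute_similarity(default_eeg, tset), sfreq=250.0)
        gev = explained_variance(default_eeg, tset, labels)
        # brute-force recomputation, sample by sample
        data = default_eeg.data - default_eeg.data.mean(axis=0, keepdims=True)
        gfp2 = data.var(axis=0, ddof=0)
        num = 0.0
        for t in range(data.shape[1]):
            v = data[:, t]
            tem = tset.templates[labels.labels[t] - 1]
            norm = np.linalg.norm(v)
            if norm > 0:
                num += gfp2[t] * (v @ tem / norm) ** 2
        assert abs(gev["total"] - num / gfp2.sum()) < 1e-9


class TestPolarityInvariance:
    def test_negated_recording_equivalent(self, default_eeg, default_truth):
        tset = MicrostateTemplateSet(
            templates=default_truth.templates, labels=list("ABCD")
        )
        neg = EEGRecording(data=-default_eeg.data, sfreq=default_eeg.sfreq)
        np.testing.assert_allclose(
            compute_gfp(neg).values, compute_gfp(default_eeg).values, atol=1e-12
        )
        sim_pos = compute_similarity(default_eeg, tset)
        sim_neg = compute_similarity(neg, tset)
        np.testing.assert_allclose(sim_neg.values, sim_pos.values, atol=1e-12)
        np.testing.assert_array_equal(
            assign_labels(sim_neg).labels, assign_labels(sim_pos).labels
        )

    def test_aahc_templates_unchanged_up_to_sign(self, default_eeg):
        gfp = compute_gfp(default_eeg)
        peaks = sample_peaks(detect_gfp_peaks(gfp), 2000, seed=0)
        pos = aahc_cluster(default_eeg.data[:, peaks].T, 4)
        negdata = -default_eeg.data
        negset = aahc_cluster(negdata[:, peaks].T, 4)
        assert (_matched_abs_corr(negset.templates, pos.templates) > 1 - 1e-9).all()
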