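import numpy as np
import pytest
from scipy import integrate, stats

from metabolink.core_model import Spectrum
from metabolink.iokr import (
    FingerprintVector,
    IOKRModel,
    SpectrumKernelParams,
    aggregate_gcf_mf,
    filter_peaks,
    fingerprint,
    fit_iokr,
    ppk,
    rank_candidates,
    rank_of,
    score_pair,
    structure_key,
    topn_curve,
)
from metabolink.synthetic_data import SpectrumSimParams, simulate_spectra

from conftest import random_spectra


def spec(sid, peaks):
    return Spectrum(id=sid, peaks=tuple(peaks))


class TestFilterPeaks:
    def test_keeps_only_matched_peaks(self):
        s = spec("s", [(100.0, 1.0), (250.0, 0.5)])
        out = filter_peaks(s, [100.0], tol=0.01)
        assert out.mz == (100.0,)

    def test_infinite_tolerance_is_noop(self):
        s = spec("s", [(100.0, 1.0), (250.0, 0.5)])
        assert filter_peaks(s, [100.0], tol=np.inf).peaks == s.peaks

    def test_boundary_tolerance(self):
        s = spec("s", [(100.004, 1.0)])
        assert filter_peaks(s, [100.0], tol=0.005).peaks
        assert not filter_peaks(s, [100.0], tol=0.003).peaks

    def test_empty_reference_drops_everything(self):
        s = spec("s", [(100.0, 1.0)])
        assert not filter_peaks(s, [], tol=0.1).peaks


class TestPPK:
    def test_identical_spectra_normalise_to_one(self):
        s = spec("s", [(150.0, 0.8)])
        assert ppk(s, s) == pytest.approx(1.0)

    def test_distant_peaks_decay_to_zero(self):
        p = SpectrumKernelParams(sigma_mz=0.5)
        a = spec("a", [(100.0, 1.0)])
        b = spec("b", [(500.0, 1.0)])
        assert ppk(a, b, p) == pytest.approx(0.0, abs=1e-12)

    def test_empty_spectrum_scores_zero(self):
        a = spec("a", [(100.0, 1.0)])
        b = spec("b", [])
        assert ppk(a, b) == 0.0

    def test_nonpositive_widths_rejected(self):
        with pytest.raises(ValueError):
            SpectrumKernelParams(sigma_mz=0.0)
        with pytest.raises(ValueError):
            SpectrumKernelParams(sigma_int=-1.0)

    def test_matches_numerical_integration_of_mixture_product(self):
        """Quadrature oracle: integral of the product of two Gaussian mixtures."""
        params = SpectrumKernelParams(
            sigma_mz=2.0, sigma_int=0.3, normalise=False, rescale_intensity=False
        )
        a = spec("a", [(100.0, 0.8), (110.0, 0.4)])
        b = spec("b", [(101.0, 0.7), (108.0, 0.9)])

        def mixture(peaks, x, y, smz, sint):
            return np.mean(
                [
                    stats.norm.pdf(x, mz, smz) * stats.norm.pdf(y, it, sint)
                    for mz, it in peaks
                ],
                axis=0,
            )

        val, _ = integrate.dblquad(
            lambda y, x: mixture(a.peaks, x, y, 2.0, 0.3)
            * mixture(b.peaks, x, y, 2.0, 0.3),
            80.0,
            130.0,
            -3.0,
            4.0,
            epsabs=1e-10,
        )
        assert ppk(a, b, params) == pytest.approx(val, rel=1e-6)

    def test_gram_matrix_is_psd_with_unit_diagonal(self):
        rng = np.random.default_rng(11)
        spectra = random_spectra(30, rng)
        K = np.array([[ppk(a, b) for b in spectra] for a in spectra])
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * eig.max()


class TestFingerprintBackends:
    def test_precomputed_backend_returns_table_row(self, precomputed_backend):
        fp = fingerprint("CCO", precomputed_backend)
        assert fp.bits == (0, 1, 1, 0)

    def test_same_structure_twice_identical(self, precomputed_backend):
        assert fingerprint("CCO", precomputed_backend) == fingerprint(
            "CCO", precomputed_backend
        )

    def test_unknown_structure_named_in_error(self, precomputed_backend):
        with pytest.raises(KeyError, match="c1ccccc1"):
            fingerprint("c1ccccc1", precomputed_backend)

    def test_inchikey_stereoisomers_share_key(self):
        k1 = structure_key("BQJCRHHNABKAKU-KBQPJGBKSA-N")
        k2 = structure_key("BQJCRHHNABKAKU-XYZZYZZYSA-N")
        assert k1 == k2 == "BQJCRHHNABKAKU"

    def test_smiles_key_is_verbatim(self):
        assert structure_key("CCO") == "CCO"

    def test_rdkit_backend_parses_and_rejects(self):
        pytest.importorskip("rdkit")
        from metabolink.iokr import RDKitFingerprinter

        backend = RDKitFingerprinter(n_bits_path=128, n_bits_morgan=128)
        fp = backend("CCO")
        assert sum(fp.bits) > 0
        assert backend("CCO") == fp
        with pytest.raises(ValueError, match="not-a-smiles"):
            backend("not-a-smiles")


class TestFit:
    def test_duplicate_spectra_fit_with_ridge(self):
        s = spec("s", [(100.0, 1.0)])
        pairs = [(s, FingerprintVector(bits=(1, 0))), (s, FingerprintVector(bits=(0, 1)))]
        model = fit_iokr(pairs, lambda_reg=0.1)
        assert model.n_train == 2

    def test_duplicate_spectra_without_ridge_rejected(self):
        s = spec("s", [(100.0, 1.0)])
        pairs = [(s, FingerprintVector(bits=(1, 0))), (s, FingerprintVector(bits=(0, 1)))]
        with pytest.raises(np.linalg.LinAlgError, match="lambda_reg > 0"):
            fit_iokr(pairs, lambda_reg=0.0)

    def test_interpolation_limit_recovers_training_fingerprints(self, toy_training_set):
        model = fit_iokr(toy_training_set, lambda_reg=1e-10)
        for s, fp in toy_training_set:
            pred = model.predict_fingerprint(s)
            assert np.linalg.norm(pred - fp.to_array()) < 1e-4

    def test_constant_target_predicts_it_everywhere(self, toy_training_set):
        fp = FingerprintVector(bits=(1, 0, 1, 0, 0, 1))
        pairs = [(s, fp) for s, _ in toy_training_set]
        model = fit_iokr(pairs, lambda_reg=1e-8)
        for s, _ in toy_training_set:
            np.testing.assert_allclose(
                model.predict_fingerprint(s), fp.to_array(), atol=1e-4
            )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_iokr([(spec("s", [(1.0, 1.0)]), FingerprintVector(bits=(1,)))])

    def test_inconsistent_fingerprint_lengths_rejected(self):
        pairs = [
            (spec("a", [(100.0, 1.0)]), FingerprintVector(bits=(1, 0))),
            (spec("b", [(200.0, 1.0)]), FingerprintVector(bits=(1, 0, 1))),
        ]
        with pytest.raises(ValueError, match="lengths"):
            fit_iokr(pairs)

    def test_permutation_equivariance(self, toy_training_set):
        m1 = fit_iokr(toy_training_set, lambda_reg=1e-4)
        m2 = fit_iokr(toy_training_set[::-1], lambda_reg=1e-4)
        query = spec("q", [(150.0, 0.9), (350.0, 0.4)])
        fp = FingerprintVector(bits=(1, 1, 0, 0, 1, 0))
        assert score_pair(m1, query, fp) == pytest.approx(
            score_pair(m2, query, fp), abs=1e-10
        )

    def test_save_load_roundtrip(self, toy_model, tmp_path):
        path = tmp_path / "model.npz"
        toy_model.save(path)
        loaded = IOKRModel.load(path)
        query = spec("q", [(200.0, 0.5)])
        fp = FingerprintVector(bits=(1, 0, 0, 1, 0, 1))
        assert score_pair(loaded, query, fp) == pytest.approx(
            score_pair(toy_model, query, fp)
        )


class TestScorePair:
    def test_training_spectrum_ranks_own_fingerprint_first(self, toy_training_set):
        model = fit_iokr(toy_training_set, lambda_reg=1e-10)
        cands = [(f"fp_{i}", fp) for i, (_, fp) in enumerate(toy_training_set)]
        for i, (s, _) in enumerate(toy_training_set):
            ranked = rank_candidates(model, s, cands)
            assert ranked[0].key == f"fp_{i}"

    def test_zero_fingerprint_scores_zero(self, toy_model):
        q = spec("q", [(150.0, 0.9)])
        assert score_pair(toy_model, q, FingerprintVector(bits=(0,) * 6)) == 0.0

    def test_linearity_in_candidate_fingerprint(self, toy_model):
        q = spec("q", [(150.0, 0.9), (300.0, 0.2)])
        a = FingerprintVector(bits=(1, 0, 0, 1, 0, 0))
        b = FingerprintVector(bits=(0, 1, 0, 0, 1, 0))
        ab = FingerprintVector(bits=(1, 1, 0, 1, 1, 0))
        assert score_pair(toy_model, q, ab) == pytest.approx(
            score_pair(toy_model, q, a) + score_pair(toy_model, q, b)
        )

    def test_unmatched_spectrum_scores_zero_with_warning(self, toy_training_set):
        model = fit_iokr(toy_training_set)  # default finite peak-match tolerance
        q = spec("q", [(9999.0, 1.0)])
        fp = FingerprintVector(bits=(1,) * 6)
        with pytest.warns(UserWarning, match="no peaks"):
            assert score_pair(model, q, fp) == 0.0

    def test_length_mismatch_rejected(self, toy_model):
        with pytest.raises(ValueError, match="length"):
            score_pair(toy_model, spec("q", [(150.0, 1.0)]), FingerprintVector(bits=(1,)))


class TestRankCandidates:
    def test_single_candidate_gets_rank_one(self, toy_model):
        ranked = rank_candidates(
            toy_model,
            spec("q", [(150.0, 0.9)]),
            [("only", FingerprintVector(bits=(1, 0, 1, 0, 0, 1)))],
        )
        assert ranked[0].rank == 1

    def test_duplicated_candidate_tie_broken_by_key(self, toy_model):
        fp = FingerprintVector(bits=(1, 0, 1, 0, 0, 1))
        ranked = rank_candidates(
            toy_model, spec("q", [(150.0, 0.9)]), [("b", fp), ("a", fp)]
        )
        assert [r.key for r in ranked] == ["a", "b"]
        assert ranked[0].score == ranked[1].score

    def test_empty_candidate_set_rejected(self, toy_model):
        with pytest.raises(ValueError, match="empty"):
            rank_candidates(toy_model, spec("q", [(150.0, 0.9)]), [])

    def test_recovery_beats_shuffled_baseline(self):
        params = SpectrumSimParams(
            n_train=60, n_test=20, n_candidates=25, seed=5
        )
        train, test, cands = simulate_spectra(params)
        model = fit_iokr(train)
        ranks = np.array(
            [rank_of(rank_candidates(model, s, cands), [k]) for s, k in test]
        )
        rng = np.random.default_rng(0)
        keys = [k for _, k in test]
        shuffled = [keys[i] for i in rng.permutation(len(keys))]
        shuffled_ranks = np.array(
            [
                rank_of(rank_candidates(model, s, cands), [k])
                for (s, _), k in zip(test, shuffled)
            ]
        )
        res = stats.mannwhitneyu(ranks, shuffled_ranks, alternative="less")
        assert res.pvalue < 0.01


class TestAggregate:
    def _fps(self):
        return {
            "bgc1": [("k1", FingerprintVector(bits=(1, 0, 1, 0, 0, 1)))],
            "bgc2": [
                ("k2", FingerprintVector(bits=(0, 1, 1, 0, 0, 1))),
                ("k3", FingerprintVector(bits=(1, 1, 0, 0, 1, 0))),
            ],
        }

    def test_single_pair_equals_score_pair(self, toy_model):
        q = spec("q", [(150.0, 0.9)])
        fp = FingerprintVector(bits=(1, 0, 1, 0, 0, 1))
        link = aggregate_gcf_mf(toy_model, {"bgc1": [("k1", fp)]}, [q])
        assert link.value == pytest.approx(score_pair(toy_model, q, fp))
        assert link.argmax_pair == ("q", "bgc1")

    def test_adding_pairs_never_lowers_aggregate(self, toy_model):
        q1 = spec("q1", [(150.0, 0.9)])
        q2 = spec("q2", [(350.0, 0.5)])
        small = aggregate_gcf_mf(toy_model, self._fps(), [q1])
        big = aggregate_gcf_mf(toy_model, self._fps(), [q1, q2])
        assert big.value >= small.value

    def test_2x2_grid_equals_brute_force_maximum(self, toy_model):
        specs = [spec("q1", [(150.0, 0.9)]), spec("q2", [(350.0, 0.5)])]
        fps = self._fps()
        link = aggregate_gcf_mf(toy_model, fps, specs)
        brute = max(
            score_pair(toy_model, s, fp)
            for s in specs
            for pairs in fps.values()
            for _, fp in pairs
        )
        assert link.value == pytest.approx(brute)

    def test_unscorable_gcf_is_undefined_not_zero(self, toy_model):
        assert aggregate_gcf_mf(toy_model, {}, [spec("q", [(150.0, 1.0)])]) is None
        assert aggregate_gcf_mf(toy_model, {"b": []}, [spec("q", [(150.0, 1.0)])]) is None


class TestTopNCurve:
    def test_perfect_model_saturates(self, toy_training_set):
        model = fit_iokr(toy_training_set, lambda_reg=1e-10)
        cands = [(f"fp_{i}", fp) for i, (_, fp) in enumerate(toy_training_set)]
        test_pairs = [(s, [f"fp_{i}"]) for i, (s, _) in enumerate(toy_training_set)]
        curve, auc = topn_curve(model, test_pairs, cands)
        assert curve[0] == 1.0
        assert curve[-1] == 1.0
        assert auc == 1.0

    def test_curve_is_nondecreasing_and_ends_at_one(self, toy_model, toy_training_set):
        cands = [(f"fp_{i}", fp) for i, (_, fp) in enumerate(toy_training_set)]
        test_pairs = [(s, [f"fp_{(i + 1) % 5}"]) for i, (s, _) in enumerate(toy_training_set)]
        curve, auc = topn_curve(toy_model, test_pairs, cands)
        assert (np.diff(curve) >= 0).all()
        assert curve[-1] == 1.0
        assert 0.0 <= auc <= 1.0
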