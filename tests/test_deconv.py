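"""Mass channels, non-negative LASSO, AICc selection, shadow rescoring.

The LASSO solver is checked against an independent projected-gradient oracle
and the model selection against exhaustive subset least squares; exact
mixtures have closed-form coefficients that must be recovered to numerical
precision.
"""

import numpy as np
import pytest

from specdecon.deconv import (
    ChannelMatrix,
    aicc_value,
    build_channel_matrix,
    deconvolve_and_rescore,
    fit_nn_lasso,
    lasso_objective,
    select_model_aicc,
    shadow_spectrum,
)
from specdecon.proteome import Peptide
from specdecon.search import CandidateMatch, match_peaks, score_psm


def projected_gradient_nn_lasso(X, y, lam, n_iter=60_000):
    """Independent oracle: projected gradient on RSS + lam*sum(beta), beta>=0."""
    XXt = X @ X.T
    L = np.linalg.eigvalsh(2.0 * XXt).max() if X.shape[0] else 1.0
    step = 1.0 / max(L, 1e-12)
    beta = np.zeros(X.shape[0])
    Xy = X @ y
    for _ in range(n_iter):
        grad = 2.0 * (XXt @ beta - Xy) + lam
        new = np.maximum(0.0, beta - step * grad)
        if np.max(np.abs(new - beta)) < 1e-13:
            beta = new
            break
        beta = new
    return beta


def random_instance(rng, P=None, M=None):
    P = P or int(rng.integers(1, 9))
    M = M or int(rng.integers(max(P + 3, 5), 41))
    X = rng.uniform(0, 1, size=(P, M))
    X /= X.sum(axis=1, keepdims=True)  # rows normalized like predictions
    true_beta = rng.uniform(0, 100, size=P) * (rng.uniform(size=P) < 0.7)
    y = X.T @ true_beta + rng.normal(0, 0.5, size=M)
    y = np.maximum(y, 0.0)
    return X, y


class TestFitNnLasso:
    def test_single_candidate_recovers_matched_intensity_sum(self):
        X = np.array([[1 / 6, 2 / 6, 3 / 6]])
        y = 60.0 * X[0]
        beta = fit_nn_lasso(design=X, exp_intensity=y, lam=0.0)
        assert beta[0] == pytest.approx(60.0, rel=1e-9)

    def test_disjoint_candidates_exact(self):
        X = np.array([[1 / 3, 2 / 3, 0, 0], [0, 0, 1 / 2, 1 / 2]])
        y = np.array([10.0, 20.0, 5.0, 5.0])
        np.testing.assert_allclose(
            fit_nn_lasso(design=X, exp_intensity=y, lam=0.0), [30.0, 10.0], rtol=1e-9
        )

    def test_shared_channel_splits_intensity(self):
        X = np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]])
        y = np.array([12.0, 6.0, 6.0])
        np.testing.assert_allclose(
            fit_nn_lasso(design=X, exp_intensity=y, lam=0.0), [12.0, 12.0], rtol=1e-6
        )

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_nn_lasso(design=np.array([[np.nan]]), exp_intensity=np.array([1.0]),
                         lam=0.0)

    def test_matches_projected_gradient_oracle(self):
        """Objective within 1e-6 relative of the oracle on 200 random instances."""
        rng = np.random.default_rng(1234)
        lam_grid = [0.0, 0.1, 1.0, 10.0, 100.0]
        for i in range(200):
            X, y = random_instance(rng)
            lam = lam_grid[i % len(lam_grid)]
            ours = fit_nn_lasso(design=X, exp_intensity=y, lam=lam)
            oracle = projected_gradient_nn_lasso(X, y, lam)
            f_ours = lasso_objective(X, y, ours, lam)
            f_oracle = lasso_objective(X, y, oracle, lam)
            assert f_ours <= f_oracle * (1 + 1e-6) + 1e-9

    def test_noiseless_conservation(self):
        """For exact mixtures at lambda=0, sum(beta) equals total intensity."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            P = int(rng.integers(1, 6))
            M = int(rng.integers(P + 3, 30))
            X = rng.uniform(0, 1, size=(P, M))
            X /= X.sum(axis=1, keepdims=True)
            true_beta = rng.uniform(1, 100, size=P)
            y = X.T @ true_beta
            beta = fit_nn_lasso(design=X, exp_intensity=y, lam=0.0)
            assert beta.sum() == pytest.approx(y.sum(), rel=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(55)
        X, y = random_instance(rng, P=4, M=25)
        m = ChannelMatrix(np.arange(25.0), y, X, [None] * 4, [])
        res1 = select_model_aicc(m)
        s = 37.5
        m2 = ChannelMatrix(np.arange(25.0), s * y, X, [None] * 4, [])
        res2 = select_model_aicc(m2)
        np.testing.assert_allclose(res2.coefficients, s * res1.coefficients,
                                   rtol=1e-5, atol=1e-8)


class TestPathAndAicc:
    def test_l1_norm_non_increasing_along_path(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            X, y = random_instance(rng)
            m = ChannelMatrix(np.arange(X.shape[1], dtype=float), y, X,
                              [None] * X.shape[0], [])
            res = select_model_aicc(m)
            lams = [l for l, _, _ in res.path]
            norms = []
            beta = np.zeros(X.shape[0])
            for lam in lams:
                beta = fit_nn_lasso(design=X, exp_intensity=y, lam=lam, beta0=beta)
                norms.append(np.abs(beta).sum())
            # path is evaluated at descending lambda: L1 norm non-decreasing
            for a, b in zip(norms, norms[1:]):
                assert b >= a - 1e-6 * max(1.0, a)

    def test_noise_candidate_zeroed(self):
        """AICc sets the pure-noise candidate to zero in >= 95% of instances.

        The noise candidate is built the way a false peptide appears in a
        channel matrix: most of its normalized intensity sits on its own
        zero-intensity (unmatched) channels, with a handful of chance matches
        on the signal channels.  Oracle cross-check: exhaustive subset least
        squares + AICc must make the same include/exclude call per instance.
        """
        from scipy.optimize import nnls

        rng = np.random.default_rng(2024)
        zeroed = oracle_zeroed = agree = 0
        n = 100
        for _ in range(n):
            Ms, Mn = 30, 20
            M = Ms + Mn
            signal = np.zeros(M)
            signal[:Ms] = rng.uniform(0, 1, Ms) ** 2
            signal /= signal.sum()
            noise_cand = np.zeros(M)
            noise_cand[Ms:] = rng.uniform(0, 1, Mn) ** 2
            k = rng.integers(3, 6)
            noise_cand[rng.choice(Ms, k, replace=False)] = rng.uniform(0, 1, k) ** 2
            noise_cand /= noise_cand.sum()
            y = np.zeros(M)
            y[:Ms] = np.maximum(200.0 * signal[:Ms] + rng.normal(0, 2.0, Ms), 0)
            X = np.vstack([signal, noise_cand])
            m = ChannelMatrix(np.arange(M, dtype=float), y, X, [None, None], [])
            ours_zero = select_model_aicc(m).coefficients[1] == 0.0
            best = (np.inf, None)
            for support in ([], [0], [1], [0, 1]):
                if support:
                    b, _ = nnls(X[support].T, y)
                    resid = y - X[support].T @ b
                    kk = int(np.sum(b > 0))
                else:
                    resid, kk = y, 0
                a = aicc_value(M, float(resid @ resid), kk)
                if a < best[0]:
                    best = (a, support)
            orc_zero = 1 not in (best[1] or [])
            zeroed += ours_zero
            oracle_zeroed += orc_zero
            agree += ours_zero == orc_zero
        assert oracle_zeroed >= 0.95 * n  # the oracle's own expectation
        assert zeroed >= 0.95 * n
        assert agree >= 0.98 * n  # per-instance agreement with the oracle

    def test_perfect_single_candidate_selects_perfect_fit(self):
        # RSS -> 0 dominates AICc: the exact model wins; its coefficients are
        # the unshrunk refit, identical to the lambda = 0 solution
        X = np.array([[0.2, 0.3, 0.5, 0.0, 0.0, 0.0, 0.0]])
        y = 100.0 * X[0]
        m = ChannelMatrix(np.arange(7.0), y, X, [None], [])
        res = select_model_aicc(m)
        assert res.rss == pytest.approx(0.0, abs=1e-12)
        assert res.coefficients[0] == pytest.approx(100.0, rel=1e-6)
        lam0 = fit_nn_lasso(design=X, exp_intensity=y, lam=0.0)
        np.testing.assert_allclose(res.coefficients, lam0, rtol=1e-6)

    def test_aicc_tie_prefers_larger_lambda(self):
        # all-zero response: every model on the path has beta = 0 and equal
        # AICc; the largest lambda must win
        X = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]])
        y = np.zeros(4)
        m = ChannelMatrix(np.arange(4.0), y, X, [None, None], [])
        res = select_model_aicc(m)
        assert np.all(res.coefficients == 0.0)

    def test_small_m_disqualification(self):
        assert aicc_value(2, 1.0, 1) == np.inf  # M - k - 1 = -1
        assert np.isfinite(aicc_value(10, 1.0, 1))

    def test_chosen_lambda_belongs_to_path(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, P=3, M=20)
        m = ChannelMatrix(np.arange(20.0), y, X, [None] * 3, [])
        res = select_model_aicc(m)
        assert any(res.lam == l for l, _, _ in res.path)


class TestChannelMatrix:
    def _candidates(self, predictor, sequences, spectrum, charge=2):
        out = []
        for s in sequences:
            pred = predictor.predict_fragments(s, charge)
            idx = match_peaks(pred, spectrum, 20.0)
            sv = score_psm(idx, pred, spectrum)
            out.append(CandidateMatch(0, Peptide(sequence=s), charge, pred, idx, sv))
        return out

    def test_shared_experimental_peak_shares_channel(self, predictor, make_spectrum):
        # two peptides with the same C-terminal residue share the y1 ion
        a = predictor.predict_fragments("AAADEFGK", 2)
        b = predictor.predict_fragments("WWYHNEK", 2)
        y1_a = a.mz[(np.array(a.ion_type) == "y") & (a.ion_index == 1)][0]
        y1_b = b.mz[(np.array(b.ion_type) == "y") & (b.ion_index == 1)][0]
        assert y1_a == pytest.approx(y1_b, abs=1e-9)
        mz = np.unique(np.concatenate([a.mz, b.mz]).round(6))
        spec = make_spectrum(mz, np.ones(len(mz)))
        cands = self._candidates(predictor, ["AAADEFGK", "WWYHNEK"], spec)
        m = build_channel_matrix(cands, spec)
        shared = np.sum((m.design[0] > 0) & (m.design[1] > 0))
        assert shared >= 1  # y1 channel is shared
        np.testing.assert_allclose(m.design.sum(axis=1), 1.0, atol=1e-9)

    def test_unmatched_fragment_gets_zero_channel(self, predictor, make_spectrum):
        pred = predictor.predict_fragments("PEPTIDEK", 2)
        keep = np.ones(len(pred.mz), dtype=bool)
        keep[3] = False  # remove one peak from the experimental spectrum
        spec = make_spectrum(pred.mz[keep], pred.intensity[keep] * 100)
        cands = self._candidates(predictor, ["PEPTIDEK"], spec)
        m = build_channel_matrix(cands, spec)
        assert (m.exp_intensity == 0).sum() >= 1
        np.testing.assert_allclose(m.design.sum(axis=1), 1.0, atol=1e-9)

    def test_channel_count_matched_plus_unmatched(self, predictor, make_spectrum):
        from specdecon.predictor import PredictedSpectrum
        from specdecon.search import CandidateMatch, ScoreVector

        # one candidate: 5 matched + 2 unmatched (far apart) fragments -> M = 7
        mz = np.array([100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0])
        inten = np.full(7, 1 / 7)
        pred = PredictedSpectrum("XX", (), 2, 450.0, mz, inten,
                                 tuple("b" * 7), np.arange(7),
                                 np.ones(7, dtype=int), tuple([""] * 7))
        spec = make_spectrum(mz[:5], np.ones(5))
        idx = match_peaks(pred, spec, 20.0)
        cand = CandidateMatch(0, Peptide(sequence="AAK"), 2, pred, idx, ScoreVector())
        m = build_channel_matrix([cand], spec)
        assert m.M == 7
        assert (m.exp_intensity == 0).sum() == 2

    def test_empty_candidates_give_sentinel(self, make_spectrum):
        m = build_channel_matrix([], make_spectrum([100.0], [1.0]))
        assert m.P == 0 and m.M == 0


class TestShadow:
    def test_single_candidate_shadow_is_experimental(self):
        X = np.array([[0.3, 0.7]])
        y = np.array([30.0, 70.0])
        m = ChannelMatrix(np.arange(2.0), y, X, [None], [])
        np.testing.assert_allclose(shadow_spectrum(m, np.array([100.0]), 0), y)

    def test_exact_two_candidate_mixture(self):
        X = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]])
        beta = np.array([40.0, 20.0])
        y = X.T @ beta
        m = ChannelMatrix(np.arange(3.0), y, X, [None, None], [])
        np.testing.assert_allclose(shadow_spectrum(m, beta, 0), beta[0] * X[0],
                                   atol=1e-9)

    def test_over_explained_channel_clamped_at_zero(self):
        X = np.array([[1.0, 0.0], [0.5, 0.5]])
        y = np.array([10.0, 5.0])
        m = ChannelMatrix(np.arange(2.0), y, X, [None, None], [])
        shadow = shadow_spectrum(m, np.array([5.0, 40.0]), 0)
        assert shadow[0] == 0.0  # 10 - 0.5*40 < 0 -> clamped

    def test_shadow_consistency_before_clamp(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng, P=4, M=20)
        beta = fit_nn_lasso(design=X, exp_intensity=y, lam=1.0)
        fitted = X.T @ beta
        resid = y - fitted
        np.testing.assert_allclose(fitted + resid, y, atol=1e-9)


class TestDeconvolveAndRescore:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_exact_mixture_recovery(self, k, predictor, make_spectrum):
        """Noiseless k-peptide chimeras: every generator recovered with beta
        within 0.1% of its generating scalar."""
        sequences = ["MKTAYIAK", "QISFVDSH", "PEGTIDEK", "AAACDDEEK",
                     "GGWWYYHK", "TTSSNNQQK"][:k]
        scalars = np.array([100.0, 70.0, 40.0, 25.0, 55.0, 140.0][:k])
        from specdecon.simulate import _merge_peaks

        preds = [predictor.predict_fragments(s, 2) for s in sequences]
        mz = np.concatenate([p.mz for p in preds])
        inten = np.concatenate([p.intensity * c for p, c in zip(preds, scalars)])
        mz, inten = _merge_peaks(mz, inten, tol_ppm=5.0)  # centroided instrument
        spec = make_spectrum(mz, inten)
        cands = []
        for s, p in zip(sequences, preds):
            idx = match_peaks(p, spec, 20.0)
            sv = score_psm(idx, p, spec)
            cands.append(CandidateMatch(0, Peptide(sequence=s), 2, p, idx, sv))
        psms, res = deconvolve_and_rescore(spec, cands)
        assert len(psms) == k
        got = {p.candidate.peptide.sequence: p.coefficient for p in psms}
        for s, c in zip(sequences, scalars):
            assert got[s] == pytest.approx(c, rel=1e-3)
        assert sum(got.values()) == pytest.approx(scalars.sum(), rel=1e-3)

    def test_zero_coefficient_candidate_absent(self, predictor, make_spectrum):
        pred_a = predictor.predict_fragments("MKTAYIAK", 2)
        spec = make_spectrum(pred_a.mz.copy(), pred_a.intensity * 100,
                             center=pred_a.mono_mz)
        cands = []
        for s in ("MKTAYIAK", "QISFVDSH"):
            p = predictor.predict_fragments(s, 2)
            idx = match_peaks(p, spec, 20.0)
            cands.append(CandidateMatch(0, Peptide(sequence=s), 2, p, idx,
                                        score_psm(idx, p, spec)))
        psms, _ = deconvolve_and_rescore(spec, cands)
        assert [p.candidate.peptide.sequence for p in psms] == ["MKTAYIAK"]

    def test_shadow_prefilter_reapplied(self, predictor, make_spectrum):
        # candidate B matches only 3 shared peaks of A; once A's contribution
        # is removed, the shadow leaves B without matched intensity
        pred_a = predictor.predict_fragments("MKTAYIAK", 2)
        spec = make_spectrum(pred_a.mz.copy(), pred_a.intensity * 100,
                             center=pred_a.mono_mz)
        idx_a = match_peaks(pred_a, spec, 20.0)
        cand_a = CandidateMatch(0, Peptide(sequence="MKTAYIAK"), 2, pred_a, idx_a,
                                score_psm(idx_a, pred_a, spec))
        psms, _ = deconvolve_and_rescore(spec, [cand_a])
        assert len(psms) == 1
        assert psms[0].score.spectral_angle == pytest.approx(1.0, abs=1e-6)
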