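"""Fragment index, isotope envelopes, candidate retrieval, matching, scoring."""

import numpy as np
import pytest
from scipy import stats

from specdecon.predictor import ToyPredictor
from specdecon.proteome import Peptide
from specdecon.search import (
    CandidateMatch,
    FragmentIndex,
    PrecursorSpace,
    ScoreVector,
    candidates_for_spectrum,
    isotope_envelope,
    match_peaks,
    prefilter_psm,
    score_psm,
    select_isobaric_representative,
    spectral_angle,
)


class TestIsotopeEnvelope:
    def test_abundances_sum_to_one(self):
        env = isotope_envelope(1500.0, 2)
        assert env.abundances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_plus_one_fraction_monotone_in_mass(self):
        # Poisson property: P(1)/P(0) = lambda grows linearly with mass, so
        # below lambda = 1 (~1683 Da) the +1 fraction rises monotonically
        fracs = [isotope_envelope(m, 2).abundances[1] for m in (600, 900, 1200, 1500)]
        assert all(a < b for a, b in zip(fracs, fracs[1:]))
        # and the +1/mono ratio is monotone at any mass
        ratios = [
            isotope_envelope(m, 2).abundances[1] / isotope_envelope(m, 2).abundances[0]
            for m in (800, 1600, 2400, 3200)
        ]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_mass_1683_gives_lambda_one(self):
        # oracle: direct truncated-Poisson evaluation at lambda = 0.000594 * 1683
        lam = 0.000594 * 1683.0
        pmf = stats.poisson.pmf(np.arange(5), lam)
        expected = pmf / pmf.sum()
        env = isotope_envelope(1683.0, 2)
        assert lam == pytest.approx(1.0, abs=0.001)
        np.testing.assert_allclose(env.abundances, expected, rtol=1e-9)
        assert env.abundances[1] == pytest.approx(env.abundances[0], rel=0.002)

    def test_isotope_spacing(self):
        env = isotope_envelope(1000.0, 2)
        np.testing.assert_allclose(np.diff(env.mzs), 1.0033548 / 2, atol=1e-6)


class TestFragmentIndex:
    def _single_index(self):
        return FragmentIndex(np.array([500.000]), np.array([0]), 1)

    def test_hit_within_ppm(self):
        assert list(self._single_index().query(500.005, 20.0)) == [0]

    def test_miss_outside_ppm(self):
        assert list(self._single_index().query(500.02, 20.0)) == []

    def test_matches_brute_force_on_random_queries(self):
        rng = np.random.default_rng(17)
        frag_mz = np.sort(rng.uniform(100, 1500, size=5000))
        owner = rng.integers(0, 200, size=5000)
        index = FragmentIndex(frag_mz.copy(), owner.copy(), 200)
        for mz in rng.uniform(100, 1500, size=1000):
            tol = mz * 20e-6
            brute = np.unique(owner[np.abs(frag_mz - mz) <= tol])
            np.testing.assert_array_equal(index.query(mz, 20.0), brute)


@pytest.fixture(scope="module")
def small_space():
    predictor = ToyPredictor(seed=7)
    peptides = [Peptide(sequence=s) for s in
                ("MKTAYIAK", "QISFVKSHFSR", "PEPTIDEK", "AAACDDEEK", "GGWWYYK")]
    space = PrecursorSpace.build(peptides, (2, 3), predictor)
    index = FragmentIndex.build(space)
    return predictor, space, index


class TestCandidates:
    def test_full_envelope_overlap_kept(self, small_space, make_spectrum):
        predictor, space, index = small_space
        cid = 0
        mono = space.mono_mz[cid]
        pred = predictor.predict_fragments(space.peptides[cid], int(space.charges[cid]))
        spec = make_spectrum(pred.mz.copy(), pred.intensity * 100,
                             center=mono + 0.2, lower=0.7, upper=0.7)
        ids = candidates_for_spectrum(spec, space, index)
        assert cid in ids

    def test_partial_envelope_overlap_kept(self, small_space, make_spectrum):
        # monoisotopic peak below the window; only +1/+2 isotopes inside
        predictor, space, index = small_space
        cid = 0
        mono = space.mono_mz[cid]
        z = int(space.charges[cid])
        pred = predictor.predict_fragments(space.peptides[cid], z)
        spec = make_spectrum(pred.mz.copy(), pred.intensity * 100,
                             center=mono + 0.4 + 1.0033548 / z,
                             lower=0.4, upper=0.4)
        assert space.envelope_mz[cid, 0] < spec.window[0]  # mono outside
        ids = candidates_for_spectrum(spec, space, index)
        assert cid in ids

    def test_no_envelope_overlap_excluded(self, small_space, make_spectrum):
        predictor, space, index = small_space
        cid = 0
        pred = predictor.predict_fragments(space.peptides[cid], int(space.charges[cid]))
        spec = make_spectrum(pred.mz.copy(), pred.intensity * 100,
                             center=space.mono_mz[cid] + 50.0, lower=0.7, upper=0.7)
        assert cid not in candidates_for_spectrum(spec, space, index)

    def test_rt_filter_only_removes(self, small_space, make_spectrum):
        """Every pass-2 candidate set is a subset of the pass-1 set."""
        from specdecon.predictor import RtModel

        predictor, space, index = small_space
        rng = np.random.default_rng(3)
        rt_model = RtModel(slope=30.0, intercept=0.0, rt_window_halfwidth=1.0)
        for _ in range(20):
            center = rng.uniform(420, 700)
            mz = np.sort(rng.uniform(100, 1200, 60))
            spec = make_spectrum(mz, np.ones(60), center=center, lower=5.0, upper=5.0,
                                 rt=rng.uniform(0, 30))
            pass1 = set(candidates_for_spectrum(spec, space, index, rt_model=None,
                                                min_hits=1))
            pass2 = set(candidates_for_spectrum(spec, space, index, rt_model=rt_model,
                                                min_hits=1))
            assert pass2 <= pass1

    def test_candidate_outside_rt_window_excluded_in_pass2(self, small_space, make_spectrum):
        from specdecon.predictor import RtModel

        predictor, space, index = small_space
        cid = 0
        pred = predictor.predict_fragments(space.peptides[cid], int(space.charges[cid]))
        rt_model = RtModel(slope=30.0, intercept=0.0, rt_window_halfwidth=1.0)
        rt_pred = rt_model.predict_minutes(space.rt_frac[cid])
        spec = make_spectrum(pred.mz.copy(), pred.intensity * 100,
                             center=space.mono_mz[cid], rt=rt_pred + 3.0)
        assert cid not in candidates_for_spectrum(spec, space, index, rt_model=rt_model)
        assert cid in candidates_for_spectrum(spec, space, index, rt_model=None)


class TestMatchPeaks:
    def _pred(self, mzs):
        from specdecon.predictor import PredictedSpectrum

        n = len(mzs)
        return PredictedSpectrum(
            peptide="XX", modifications=(), charge=2, mono_mz=500.0,
            mz=np.asarray(mzs, dtype=float), intensity=np.full(n, 1.0 / n),
            ion_type=tuple("b" * n), ion_index=np.arange(n),
            frag_charge=np.ones(n, dtype=int), neutral_loss=tuple([""] * n),
        )

    def test_nearest_peak_wins(self, make_spectrum):
        spec = make_spectrum([399.999, 400.02], [1.0, 1.0])
        out = match_peaks(self._pred([400.000]), spec, 20.0)
        assert out[0] == 0

    def test_no_peak_within_tolerance(self, make_spectrum):
        spec = make_spectrum([401.0], [1.0])
        assert match_peaks(self._pred([400.0]), spec, 20.0)[0] == -1

    def test_equidistant_tie_breaks_to_lower_mz(self, make_spectrum):
        spec = make_spectrum([399.998, 400.002], [1.0, 1.0])
        assert match_peaks(self._pred([400.000]), spec, 20.0)[0] == 0

    def test_shared_peak_serves_multiple_fragments(self, make_spectrum):
        spec = make_spectrum([400.0], [1.0])
        out = match_peaks(self._pred([399.9999, 400.0001]), spec, 20.0)
        assert list(out) == [0, 0]


class TestSpectralAngle:
    def test_proportional_vectors_give_one(self):
        assert spectral_angle(np.array([1, 2, 3.0]), np.array([10, 20, 30.0])) == \
            pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert spectral_angle(np.array([1, 0.0]), np.array([0, 1.0])) == pytest.approx(0.0)

    def test_cosine_096_case(self):
        # 1 - 2*arccos(0.96)/pi evaluated directly
        expected = 1.0 - 2.0 * np.arccos(0.96) / np.pi
        assert spectral_angle(np.array([3, 4.0]), np.array([4, 3.0])) == \
            pytest.approx(expected)
        assert expected == pytest.approx(0.8193, abs=5e-5)

    def test_all_zero_vector_scores_zero(self):
        assert spectral_angle(np.array([1, 2.0]), np.zeros(2)) == 0.0


class TestPrefilter:
    def _score(self, n_matched, base, top3):
        return ScoreVector(n_matched=n_matched, base_peak_matched=base,
                           top3_matched_count=top3)

    @pytest.mark.parametrize(
        "n_matched,base,top3,keep",
        [
            (2, True, 3, False),   # fewer than three matched fragments
            (5, False, 2, False),  # base peak unmatched
            (3, True, 2, True),    # base peak + one more of the top 3
            (3, True, 1, False),   # only the base peak among the top 3
            (10, True, 3, True),
        ],
    )
    def test_rules(self, n_matched, base, top3, keep):
        assert prefilter_psm(self._score(n_matched, base, top3)) is keep

    def test_true_peptide_passes_in_perfect_regime(self, spectrum_for):
        pred, spec = spectrum_for("MKTAYIAKQR", 2)
        sv = score_psm(match_peaks(pred, spec, 20.0), pred, spec)
        assert prefilter_psm(sv)
        assert sv.spectral_angle == pytest.approx(1.0, abs=1e-6)


class TestIsobaricRepresentative:
    def _match(self, predictor, seq, spec, score=None):
        pred = predictor.predict_fragments(seq, 2)
        idx = match_peaks(pred, spec, 20.0)
        sv = score_psm(idx, pred, spec)
        if score is not None:
            sv.spectral_angle = score
        return CandidateMatch(0, Peptide(sequence=seq), 2, pred, idx, sv)

    def test_identical_predictions_keep_one(self, predictor, spectrum_for):
        pred, spec = spectrum_for("PEPTIDEK", 2)
        a = self._match(predictor, "PEPTIDEK", spec)
        b = CandidateMatch(1, Peptide(sequence="PEPTIDEK"), 2, a.predicted,
                           a.match_idx.copy(), a.score)
        kept = select_isobaric_representative([a, b])
        assert len(kept) == 1

    def test_same_mass_disjoint_fragments_both_kept(self, predictor, make_spectrum):
        # positional variants with (near-)identical precursor mass but mostly
        # different fragment series; matched peak sets overlap far below 90%
        a_pred = predictor.predict_fragments("ADEFGHIKK", 2)
        b_pred = predictor.predict_fragments("KADEFGHIK", 2)
        mz = np.sort(np.concatenate([a_pred.mz, b_pred.mz]))
        spec = make_spectrum(mz, np.ones(len(mz)), center=a_pred.mono_mz)
        a = CandidateMatch(0, Peptide(sequence="ADEFGHIKK"), 2, a_pred,
                           match_peaks(a_pred, spec, 20.0),
                           score_psm(match_peaks(a_pred, spec, 20.0), a_pred, spec))
        b = CandidateMatch(1, Peptide(sequence="KADEFGHIK"), 2, b_pred,
                           match_peaks(b_pred, spec, 20.0),
                           score_psm(match_peaks(b_pred, spec, 20.0), b_pred, spec))
        assert len(select_isobaric_representative([a, b])) == 2

    def test_score_tie_breaks_lexicographically(self, predictor, spectrum_for):
        pred, spec = spectrum_for("PEPTIDEK", 2)
        a = self._match(predictor, "PEPTIDEK", spec, score=0.9)
        b = CandidateMatch(1, Peptide(sequence="PEPTIDEA"), 2, a.predicted,
                           a.match_idx.copy(),
                           ScoreVector(spectral_angle=0.9))
        kept = select_isobaric_representative([a, b])
        assert len(kept) == 1
        assert kept[0].peptide.sequence == "PEPTIDEA"
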