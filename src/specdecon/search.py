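"""Candidate retrieval, peak matching, scoring and pre-deconvolution filters.

Candidate peptides for a spectrum must (i) have at least one precursor
isotope inside the isolation window (plus a ppm tolerance) — partial envelope
overlap is enough — and, in the main pass, (ii) a calibrated retention time
within the data-dependent RT window.  Candidates are ranked by the number of
fragment hits returned by a sorted-array fragment ion index and the top
``n_rank`` survive to matching and scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .predictor import PROTON, WATER, AA_MASS, PredictedSpectrum
from .proteome import Peptide
from .spectra import ExperimentalSpectrum

NEUTRON_SPACING = 1.0033548  # Th at charge 1
ISOTOPE_LAMBDA_PER_DA = 0.000594
MAX_ISOTOPES = 5


@dataclass
class IsotopeEnvelope:
    mzs: np.ndarray
    abundances: np.ndarray
    n_isotopes: int


def isotope_envelope(peptide_mass: float, charge: int) -> IsotopeEnvelope:
    """Poisson approximation of the precursor isotope envelope.

    The mean number of heavy isotopes grows linearly with mass
    (lambda = 0.000594 per Da); the envelope is truncated at 5 isotopes and
    renormalized to sum 1.
    """
    if peptide_mass <= 0:
        raise ValueError("peptide mass must be positive")
    lam = ISOTOPE_LAMBDA_PER_DA * peptide_mass
    k = np.arange(MAX_ISOTOPES)
    log_pmf = -lam + k * np.log(lam) - np.cumsum(np.concatenate([[0.0], np.log(k[1:])]))
    ab = np.exp(log_pmf)
    ab /= ab.sum()
    mono_mz = (peptide_mass + charge * PROTON) / charge
    mzs = mono_mz + k * NEUTRON_SPACING / charge
    return IsotopeEnvelope(mzs=mzs, abundances=ab, n_isotopes=MAX_ISOTOPES)


# ---------------------------------------------------------------------------
# precursor space + fragment index
# ---------------------------------------------------------------------------


@dataclass
class PrecursorSpace:
    """All candidate precursors (peptide x charge) with vectorized metadata."""

    peptides: list[Peptide]
    charges: np.ndarray  # (N,)
    neutral_mass: np.ndarray  # (N,)
    mono_mz: np.ndarray  # (N,)
    envelope_mz: np.ndarray  # (N, MAX_ISOTOPES)
    rt_frac: np.ndarray  # (N,)
    labels: np.ndarray  # (N,) 0 target, 1 decoy, 2 entrapment

    def __len__(self) -> int:
        return len(self.peptides)

    @classmethod
    def build(
        cls,
        peptides: list[Peptide],
        charges: tuple[int, ...],
        predictor,
    ) -> "PrecursorSpace":
        fixed = getattr(predictor, "fixed_mods", {})
        peps: list[Peptide] = []
        zs, masses, rts, labels = [], [], [], []
        for pep in peptides:
            if pep.unshufflable:
                continue
            m = sum(AA_MASS[c] + fixed.get(c, 0.0) for c in pep.sequence) + WATER
            m += sum(delta for _, delta, *_ in pep.modifications)
            rt = predictor.predict_rt(pep)
            # decoy status takes precedence: decoys of entrapment peptides
            # compete as decoys, not as entrapment targets
            lab = 1 if pep.is_decoy else (2 if pep.is_entrapment else 0)
            for z in charges:
                peps.append(pep)
                zs.append(z)
                masses.append(m)
                rts.append(rt)
                labels.append(lab)
        zs = np.asarray(zs, dtype=np.int64)
        masses = np.asarray(masses)
        mono = (masses + zs * PROTON) / zs
        k = np.arange(MAX_ISOTOPES)
        env = mono[:, None] + k[None, :] * NEUTRON_SPACING / zs[:, None]
        return cls(
            peptides=peps,
            charges=zs,
            neutral_mass=masses,
            mono_mz=mono,
            envelope_mz=env,
            rt_frac=np.asarray(rts),
            labels=np.asarray(labels, dtype=np.int64),
        )


def _fragment_mzs(pep: Peptide, charge: int, fixed_mods: dict[str, float]) -> np.ndarray:
    """b/y fragment m/z values (no intensities) for index construction."""
    seq = pep.sequence
    res = np.array([AA_MASS[c] + fixed_mods.get(c, 0.0) for c in seq])
    for pos, delta, *_ in pep.modifications:
        if isinstance(pos, int):
            res[pos - 1] += delta
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    neutral = prefix[-1] + WATER
    b = prefix[1:-1]
    y = neutral - prefix[1:-1]
    frag_charges = [1] if charge < 3 else [1, 2]
    out = []
    for fz in frag_charges:
        out.append((b + fz * PROTON) / fz)
        out.append((y + fz * PROTON) / fz)
    return np.concatenate(out) if out else np.empty(0)


class FragmentIndex:
    """Sorted-array fragment ion index: m/z -> owning precursor candidates.

    Queries run in O(log F + hits) by binary search over one flat sorted
    array of all candidate fragment m/z values.
    """

    def __init__(self, frag_mz: np.ndarray, owner: np.ndarray, n_candidates: int):
        order = np.argsort(frag_mz, kind="stable")
        self.frag_mz = frag_mz[order]
        self.owner = owner[order]
        self.n_candidates = n_candidates

    @classmethod
    def build(cls, space: PrecursorSpace, fixed_mods: dict[str, float] | None = None) -> "FragmentIndex":
        fixed = fixed_mods or {"C": 57.021464}
        mz_parts, owner_parts = [], []
        for i, (pep, z) in enumerate(zip(space.peptides, space.charges)):
            mzs = _fragment_mzs(pep, int(z), fixed)
            mz_parts.append(mzs)
            owner_parts.append(np.full(len(mzs), i, dtype=np.int64))
        frag_mz = np.concatenate(mz_parts) if mz_parts else np.empty(0)
        owner = np.concatenate(owner_parts) if owner_parts else np.empty(0, dtype=np.int64)
        return cls(frag_mz, owner, len(space))

    def query(self, mz: float, tol_ppm: float) -> np.ndarray:
        """Candidate ids owning a fragment within +-tol_ppm of ``mz``."""
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.frag_mz, mz - tol, side="left")
        hi = np.searchsorted(self.frag_mz, mz + tol, side="right")
        return np.unique(self.owner[lo:hi])

    def count_hits(
        self, peaks_mz: np.ndarray, tol_ppm: float, ppm_shift: float = 0.0
    ) -> np.ndarray:
        """Number of fragment hits per candidate over all experimental peaks."""
        if len(peaks_mz) == 0:
            return np.zeros(self.n_candidates, dtype=np.int64)
        mz = peaks_mz * (1.0 - ppm_shift * 1e-6)
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.frag_mz, mz - tol, side="left")
        hi = np.searchsorted(self.frag_mz, mz + tol, side="right")
        total = int((hi - lo).sum())
        if total == 0:
            return np.zeros(self.n_candidates, dtype=np.int64)
        owners = np.concatenate([self.owner[a:b] for a, b in zip(lo, hi) if b > a])
        return np.bincount(owners, minlength=self.n_candidates)


def candidates_for_spectrum(
    spectrum: ExperimentalSpectrum,
    space: PrecursorSpace,
    index: FragmentIndex,
    rt_model=None,
    fragment_tol_ppm: float = 20.0,
    precursor_tol_ppm: float = 10.0,
    n_rank: int = 200,
    ppm_shift: float = 0.0,
    min_hits: int = 3,
) -> np.ndarray:
    """Ranked candidate ids for one spectrum (see module docstring)."""
    lo, hi = spectrum.window
    lo *= 1.0 - precursor_tol_ppm * 1e-6
    hi *= 1.0 + precursor_tol_ppm * 1e-6
    mask = np.any((space.envelope_mz >= lo) & (space.envelope_mz <= hi), axis=1)
    if rt_model is not None:
        rt_pred = rt_model.predict_minutes(space.rt_frac)
        mask &= np.abs(rt_pred - spectrum.retention_time) <= rt_model.rt_window_halfwidth
    if not mask.any():
        return np.empty(0, dtype=np.int64)
    hits = index.count_hits(spectrum.mz, fragment_tol_ppm, ppm_shift)
    hits = np.where(mask, hits, 0)
    ids = np.nonzero(hits >= max(1, min_hits))[0]
    if len(ids) == 0:
        return ids
    order = np.argsort(hits[ids], kind="stable")[::-1]
    return ids[order][:n_rank]


# ---------------------------------------------------------------------------
# matching + scoring
# ---------------------------------------------------------------------------


def match_peaks(
    predicted: PredictedSpectrum,
    spectrum: ExperimentalSpectrum,
    tol_ppm: float = 20.0,
    ppm_shift: float = 0.0,
) -> np.ndarray:
    """Match each predicted fragment to its nearest experimental peak.

    Returns an array of experimental peak indices (-1 = unmatched).  Several
    fragments may match the same peak; equidistant peaks break toward lower
    m/z.  ``ppm_shift`` is subtracted from the experimental m/z axis
    (pass-1 mass recalibration).
    """
    exp_mz = spectrum.mz * (1.0 - ppm_shift * 1e-6)
    n = len(exp_mz)
    out = np.full(len(predicted.mz), -1, dtype=np.int64)
    if n == 0:
        return out
    pos = np.searchsorted(exp_mz, predicted.mz)
    left = np.clip(pos - 1, 0, n - 1)
    right = np.clip(pos, 0, n - 1)
    d_left = np.abs(predicted.mz - exp_mz[left])
    d_right = np.abs(exp_mz[right] - predicted.mz)
    pick = np.where(d_left <= d_right, left, right)  # tie -> lower m/z
    dist = np.minimum(d_left, d_right)
    tol = predicted.mz * tol_ppm * 1e-6
    out[dist <= tol] = pick[dist <= tol]
    return out


@dataclass
class ScoreVector:
    n_matched: int = 0
    matched_intensity_fraction: float = 0.0
    spectral_angle: float = 0.0
    explained_tic_fraction: float = 0.0
    rt_delta_rel: float = 0.0
    precursor_ppm_error: float = 0.0
    peptide_length: int = 0
    charge: int = 0
    missed_cleavages: int = 0
    base_peak_matched: bool = False
    top3_matched_count: int = 0

    FEATURES = (
        "n_matched",
        "matched_intensity_fraction",
        "spectral_angle",
        "explained_tic_fraction",
        "rt_delta_rel",
        "precursor_ppm_error",
        "peptide_length",
        "charge",
        "missed_cleavages",
        "base_peak_matched",
        "top3_matched_count",
    )

    def as_array(self) -> np.ndarray:
        return np.array([float(getattr(self, f)) for f in self.FEATURES])


def spectral_angle(pred: np.ndarray, exp: np.ndarray) -> float:
    """Normalized spectral contrast angle: 1 - 2*arccos(cosine)/pi in [0, 1]."""
    np_norm = np.linalg.norm
    a, b = np_norm(pred), np_norm(exp)
    if a == 0 or b == 0:
        return 0.0
    cos = float(np.clip(np.dot(pred, exp) / (a * b), 0.0, 1.0))
    return 1.0 - 2.0 * np.arccos(cos) / np.pi


def score_psm(
    match_idx: np.ndarray,
    predicted: PredictedSpectrum,
    spectrum: ExperimentalSpectrum,
    rt_model=None,
    rt_frac: float | None = None,
    gradient_length: float | None = None,
    peptide: Peptide | None = None,
    exp_intensity: np.ndarray | None = None,
) -> ScoreVector:
    """Full score vector for one candidate-spectrum pairing.

    ``exp_intensity`` overrides the experimental intensity per matched
    fragment (used for shadow-spectrum rescoring); by default the matched
    peak intensities of ``spectrum`` are used.  Unmatched fragments
    contribute experimental 0 in the spectral-angle vectors.
    """
    matched = match_idx >= 0
    if exp_intensity is None:
        exp_vec = np.zeros(len(predicted.mz))
        exp_vec[matched] = spectrum.intensity[match_idx[matched]]
    else:
        exp_vec = np.asarray(exp_intensity, dtype=float)
        matched = matched & (exp_vec > 0)

    n_matched = int(matched.sum())
    sa = spectral_angle(predicted.intensity, np.where(matched, exp_vec, 0.0))
    tic = spectrum.tic
    if tic > 0:
        unique_peaks = np.unique(match_idx[matched])
        explained = float(spectrum.intensity[unique_peaks].sum()) if len(unique_peaks) else 0.0
        explained_frac = min(1.0, explained / tic)
    else:
        explained_frac = 0.0

    rt_delta_rel = 0.0
    if rt_model is not None and rt_frac is not None and gradient_length:
        rt_pred = float(rt_model.predict_minutes(rt_frac))
        rt_delta_rel = abs(rt_pred - spectrum.retention_time) / gradient_length

    width = spectrum.isolation_lower_offset + spectrum.isolation_upper_offset
    ppm_err = 0.0
    if width <= 3.0:  # narrow-window schemes: center tracks the precursor
        center = spectrum.isolation_center
        k = np.arange(MAX_ISOTOPES)
        env = predicted.mono_mz + k * NEUTRON_SPACING / predicted.charge
        ppm_err = float(np.min(np.abs(env - center)) / center * 1e6)

    base_idx = predicted.base_peak
    top3 = predicted.top3
    return ScoreVector(
        n_matched=n_matched,
        matched_intensity_fraction=float(predicted.intensity[matched].sum()),
        spectral_angle=sa,
        explained_tic_fraction=explained_frac,
        rt_delta_rel=rt_delta_rel,
        precursor_ppm_error=min(ppm_err, 1000.0),
        peptide_length=len(predicted.peptide),
        charge=predicted.charge,
        missed_cleavages=peptide.missed_cleavages if peptide is not None else 0,
        base_peak_matched=bool(matched[base_idx]),
        top3_matched_count=int(matched[top3].sum()),
    )


def prefilter_psm(score: ScoreVector) -> bool:
    """Spurious-PSM filter: >= 3 matched fragments, the predicted base peak
    matched, and at least one more of the top-3 predicted peaks matched."""
    return (
        score.n_matched >= 3
        and score.base_peak_matched
        and score.top3_matched_count >= 2
    )


@dataclass
class CandidateMatch:
    """One scored candidate for one spectrum, pre-deconvolution."""

    candidate_id: int
    peptide: Peptide
    charge: int
    predicted: PredictedSpectrum
    match_idx: np.ndarray
    score: ScoreVector
    rt_frac: float = 0.0
    label: int = 0  # 0 target, 1 decoy, 2 entrapment


def select_isobaric_representative(
    psms: list[CandidateMatch],
    precursor_tol_ppm: float = 10.0,
    channel_overlap: float = 0.9,
) -> list[CandidateMatch]:
    """Within groups of isobaric candidates (precursor m/z within tolerance and
    >= ``channel_overlap`` shared matched-peak positions) keep only the best
    spectral angle; ties break toward the lexicographically smaller sequence."""
    if len(psms) <= 1:
        return list(psms)
    order = sorted(range(len(psms)), key=lambda i: psms[i].predicted.mono_mz)
    peak_sets = [frozenset(int(j) for j in p.match_idx if j >= 0) for p in psms]
    parent = list(range(len(psms)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_pos in range(len(order)):
        i = order[a_pos]
        for b_pos in range(a_pos + 1, len(order)):
            j = order[b_pos]
            mz_i, mz_j = psms[i].predicted.mono_mz, psms[j].predicted.mono_mz
            if (mz_j - mz_i) / mz_i * 1e6 > precursor_tol_ppm:
                break
            si, sj = peak_sets[i], peak_sets[j]
            denom = max(len(si), len(sj))
            overlap = (len(si & sj) / denom) if denom else 1.0
            if overlap >= channel_overlap:
                parent[find(i)] = find(j)

    best: dict[int, CandidateMatch] = {}
    for i, psm in enumerate(psms):
        root = find(i)
        cur = best.get(root)
        if (
            cur is None
            or psm.score.spectral_angle > cur.score.spectral_angle
            or (
                psm.score.spectral_angle == cur.score.spectral_angle
                and psm.peptide.sequence < cur.peptide.sequence
            )
        ):
            best[root] = psm
    kept = set(id(p) for p in best.values())
    return [p for p in psms if id(p) in kept]
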