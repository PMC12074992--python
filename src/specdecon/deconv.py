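"""Spectrum deconvolution: mass channels, non-negative LASSO, AICc, shadows.

A chimeric MS2 spectrum is modeled as a non-negative linear combination of
sum-normalized predicted spectra.  The design is expressed over *mass
channels*: one channel per experimental peak matched by at least one
predicted fragment (two fragments hitting the same peak share a channel —
this is how shared fragment ions are handled) plus one zero-intensity channel
per cluster of unmatched predicted fragments.  The coefficients beta_p >= 0
minimize

    sum_m (I_m_exp - I_m^T beta)^2 + lambda * ||beta||_1

by cyclic coordinate descent; lambda is chosen by evaluating a geometric path
and picking the model with the lowest corrected Akaike information criterion
(ties resolved toward stronger regularization).  Because every design row
sums to 1, a coefficient is directly interpretable as the interference-
corrected total ion current of its precursor in that scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .search import CandidateMatch, ScoreVector, prefilter_psm, score_psm
from .spectra import ExperimentalSpectrum

log = logging.getLogger("specdecon")


@dataclass
class ChannelMatrix:
    """P x M design of predicted intensities over mass channels."""

    channel_mz: np.ndarray  # (M,) anchor m/z per channel
    exp_intensity: np.ndarray  # (M,) experimental channel intensities
    design: np.ndarray  # (P, M), rows sum to 1
    candidates: list[CandidateMatch]
    frag_channel: list[np.ndarray]  # per candidate: channel id per fragment

    @property
    def M(self) -> int:
        return len(self.channel_mz)

    @property
    def P(self) -> int:
        return len(self.candidates)


EMPTY_MATRIX = ChannelMatrix(
    channel_mz=np.empty(0),
    exp_intensity=np.empty(0),
    design=np.empty((0, 0)),
    candidates=[],
    frag_channel=[],
)


def build_channel_matrix(
    candidates: list[CandidateMatch],
    spectrum: ExperimentalSpectrum,
    tol_ppm: float = 20.0,
) -> ChannelMatrix:
    """Construct the mass-channel design for one spectrum.

    Fragments matched to the same experimental peak share one channel.
    Unmatched predicted fragments are clustered at the match tolerance and
    each cluster becomes a channel with experimental intensity 0, so every
    predicted fragment is assigned and each design row sums to 1.
    """
    if not candidates:
        return EMPTY_MATRIX

    matched_peaks = sorted(
        {int(j) for c in candidates for j in c.match_idx if j >= 0}
    )
    peak_to_channel = {pk: i for i, pk in enumerate(matched_peaks)}
    channel_mz = [float(spectrum.mz[pk]) for pk in matched_peaks]
    exp_int = [float(spectrum.intensity[pk]) for pk in matched_peaks]

    # cluster unmatched fragment m/z across all candidates at the tolerance
    unmatched: list[tuple[float, int, int]] = []  # (mz, cand idx, frag idx)
    for ci, c in enumerate(candidates):
        for fi in np.nonzero(c.match_idx < 0)[0]:
            unmatched.append((float(c.predicted.mz[fi]), ci, int(fi)))
    unmatched.sort()
    cluster_of: dict[tuple[int, int], int] = {}
    next_channel = len(channel_mz)
    cluster_start = None
    for mz, ci, fi in unmatched:
        if cluster_start is None or (mz - cluster_start) / cluster_start * 1e6 > tol_ppm:
            cluster_start = mz
            channel_mz.append(mz)
            exp_int.append(0.0)
            next_channel = len(channel_mz) - 1
        cluster_of[(ci, fi)] = next_channel

    M = len(channel_mz)
    P = len(candidates)
    design = np.zeros((P, M))
    frag_channel = []
    for ci, c in enumerate(candidates):
        chans = np.empty(len(c.predicted.mz), dtype=np.int64)
        for fi in range(len(c.predicted.mz)):
            pk = int(c.match_idx[fi])
            chans[fi] = peak_to_channel[pk] if pk >= 0 else cluster_of[(ci, fi)]
        np.add.at(design[ci], chans, c.predicted.intensity)
        frag_channel.append(chans)

    return ChannelMatrix(
        channel_mz=np.asarray(channel_mz),
        exp_intensity=np.asarray(exp_int),
        design=design,
        candidates=list(candidates),
        frag_channel=frag_channel,
    )


# ---------------------------------------------------------------------------
# non-negative LASSO
# ---------------------------------------------------------------------------


def fit_nn_lasso(
    matrix: ChannelMatrix | None = None,
    lam: float = 0.0,
    design: np.ndarray | None = None,
    exp_intensity: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    max_sweeps: int = 1000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Minimize RSS + lambda*||beta||_1 subject to beta >= 0.

    Cyclic coordinate descent with the non-negative soft-threshold update
    ``beta_p <- max(0, c_p - lambda/2) / ||col_p||^2`` where
    ``c_p = col_p . (residual + col_p * beta_p)``.  Converged when
    ``max |dbeta| <= tol * max(1, max beta)`` or after ``max_sweeps`` sweeps.
    """
    if design is None:
        design = matrix.design
        exp_intensity = matrix.exp_intensity
    X = np.asarray(design, dtype=np.float64)
    y = np.asarray(exp_intensity, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.isfinite(lam)):
        raise ValueError("non-finite inputs to fit_nn_lasso")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    P = X.shape[0]
    if P == 0:
        return np.empty(0)
    col_sq = np.einsum("pm,pm->p", X, X)
    beta = np.zeros(P) if beta0 is None else np.array(beta0, dtype=np.float64)
    resid = y - X.T @ beta
    half_lam = lam / 2.0
    for _ in range(max_sweeps):
        max_delta = 0.0
        for p in range(P):
            if col_sq[p] <= 0:
                continue
            c_p = X[p] @ resid + col_sq[p] * beta[p]
            new = max(0.0, c_p - half_lam) / col_sq[p]
            delta = new - beta[p]
            if delta != 0.0:
                resid -= X[p] * delta
                beta[p] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta <= tol * max(1.0, beta.max(initial=0.0)):
            break
    return beta


def lasso_objective(design: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    resid = y - design.T @ beta
    return float(resid @ resid + lam * np.abs(beta).sum())


@dataclass
class DeconvolutionResult:
    coefficients: np.ndarray  # beta_p >= 0, interference-corrected TIC
    lam: float
    aicc: float
    rss: float
    path: list[tuple[float, int, float]] = field(default_factory=list)  # (lam, nnz, aicc)


def aicc_value(M: int, rss: float, n_nonzero: int) -> float:
    """Corrected AIC with k = (#nonzero coefficients) + 1 (noise variance).

    Returns +inf (disqualified) when M - k - 1 <= 0.
    """
    k = n_nonzero + 1
    if M - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return M * np.log(rss / M) + 2 * k + 2 * k * (k + 1) / (M - k - 1)


def select_model_aicc(
    matrix: ChannelMatrix,
    n_lambda: int = 30,
    lambda_floor_ratio: float = 1e-3,
    aicc_tie_window: float = 0.0,
    max_sweeps: int = 1000,
    cd_tol: float = 1e-8,
) -> DeconvolutionResult:
    """Evaluate a geometric lambda path and pick the minimum-AICc model.

    The path runs from ``lambda_max = max_p 2 * col_p . y`` (the smallest
    lambda with an all-zero solution) down to ``lambda_max * floor``, plus
    lambda = 0, with warm starts.  Each lambda proposes a *support* (the
    nonzero set of the LASSO solution); the model actually scored by AICc is
    the non-negative least-squares refit on that support, which removes the
    soft-threshold shrinkage bias so that AICc compares models rather than
    shrinkage levels and the winning coefficients remain interpretable as
    interference-corrected total ion current.  Exact ties (or ties within
    ``aicc_tie_window``) resolve toward the larger lambda — the most
    regularized of the equally good models.  If every model is disqualified
    by the small-sample rule the all-zero lambda_max model is returned with
    a warning.
    """
    if matrix.P == 0 or matrix.M == 0:
        return DeconvolutionResult(np.zeros(matrix.P), 0.0, np.inf, 0.0, [])
    X, y = matrix.design, matrix.exp_intensity
    lam_max = float(np.max(2.0 * (X @ y)))
    if lam_max <= 0:
        return DeconvolutionResult(
            np.zeros(matrix.P), 0.0, aicc_value(matrix.M, float(y @ y), 0), float(y @ y), []
        )
    lams = np.geomspace(lam_max, lam_max * lambda_floor_ratio, n_lambda)
    lams = np.concatenate([lams, [0.0]])  # descending order
    path: list[tuple[float, int, float]] = []
    betas = []
    beta = np.zeros(matrix.P)
    refit_cache: dict[tuple, tuple[np.ndarray, float]] = {}
    for lam in lams:
        beta = fit_nn_lasso(
            design=X, exp_intensity=y, lam=float(lam), beta0=beta,
            max_sweeps=max_sweeps, tol=cd_tol,
        )
        support = tuple(np.nonzero(beta > 0)[0])
        if support not in refit_cache:
            refit = np.zeros(matrix.P)
            if support:
                from scipy.optimize import nnls

                b, _ = nnls(X[list(support)].T, y)
                refit[list(support)] = b
            resid = y - X.T @ refit
            refit_cache[support] = (refit, float(resid @ resid))
        refit, rss = refit_cache[support]
        nnz = int(np.sum(refit > 0))
        path.append((float(lam), nnz, aicc_value(matrix.M, rss, nnz)))
        betas.append((refit, rss))

    aiccs = np.array([a for _, _, a in path])
    if not np.any(np.isfinite(aiccs)):
        log.warning("all lambda models disqualified by AICc; falling back to lambda_max")
        return DeconvolutionResult(np.zeros(matrix.P), lam_max, np.inf, float(y @ y), path)
    best_aicc = np.min(aiccs)
    # ties toward larger lambda: lams are descending, take the first qualifying
    idx = int(np.nonzero(aiccs <= best_aicc + aicc_tie_window)[0][0])
    beta, rss = betas[idx]
    return DeconvolutionResult(
        coefficients=beta.copy(), lam=float(lams[idx]), aicc=float(aiccs[idx]),
        rss=rss, path=path,
    )


def shadow_spectrum(matrix: ChannelMatrix, beta: np.ndarray, p: int) -> np.ndarray:
    """Experimental channel intensities minus all *other* fitted contributions.

    ``shadow_m = max(0, I_m_exp - sum_{q != p} beta_q I_{q,m})`` over all
    channels; candidate p's own channels are the nonzero entries of its
    design row.
    """
    others = matrix.design.T @ beta - matrix.design[p] * beta[p]
    return np.maximum(0.0, matrix.exp_intensity - others)


@dataclass
class DeconvolvedPSM:
    candidate: CandidateMatch
    coefficient: float
    score: ScoreVector  # shadow-spectrum based
    raw_score: ScoreVector  # pre-deconvolution


def deconvolve_and_rescore(
    spectrum: ExperimentalSpectrum,
    candidates: list[CandidateMatch],
    tol_ppm: float = 20.0,
    n_lambda: int = 30,
    lambda_floor_ratio: float = 1e-3,
    aicc_tie_window: float = 0.0,
    rt_model=None,
    gradient_length: float | None = None,
) -> tuple[list[DeconvolvedPSM], DeconvolutionResult]:
    """Full per-spectrum deconvolution: channel matrix, AICc-selected LASSO,
    shadow-spectrum rescoring and re-application of the pre-filter.

    Only candidates with a positive coefficient that still pass the
    pre-filter against their shadow spectrum are emitted; several PSMs per
    spectrum are first-class output.
    """
    matrix = build_channel_matrix(candidates, spectrum, tol_ppm)
    result = select_model_aicc(
        matrix, n_lambda=n_lambda, lambda_floor_ratio=lambda_floor_ratio,
        aicc_tie_window=aicc_tie_window,
    )
    out: list[DeconvolvedPSM] = []
    beta = result.coefficients
    # floor at the coordinate-descent precision: coefficients this far below
    # the spectrum's dominant signal are numerical residue, not evidence
    beta_floor = 1e-8 * beta.max(initial=0.0)
    for p in np.nonzero(beta > beta_floor)[0]:
        cand = matrix.candidates[p]
        shadow = shadow_spectrum(matrix, beta, int(p))
        frag_exp = shadow[matrix.frag_channel[p]]
        frag_exp = np.where(cand.match_idx >= 0, frag_exp, 0.0)
        sv = score_psm(
            cand.match_idx, cand.predicted, spectrum,
            rt_model=rt_model, rt_frac=cand.rt_frac,
            gradient_length=gradient_length, peptide=cand.peptide,
            exp_intensity=frag_exp,
        )
        if prefilter_psm(sv):
            out.append(
                DeconvolvedPSM(
                    candidate=cand, coefficient=float(beta[p]),
                    score=sv, raw_score=cand.score,
                )
            )
    return out, result
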