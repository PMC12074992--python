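"""End-to-end two-pass search workflow.

Pass 1 scores candidates without a retention-time filter and rescoring with
a linear discriminant yields a confident PSM set, which drives three
calibrations: a least-squares retention-time model with a data-dependent
window, fragment m/z recalibration with a shrunk match tolerance, and
pruning of peptide classes without confident identifications.  Pass 2
repeats candidate retrieval under the RT filter, deconvolves every spectrum
(channel matrix, AICc-selected non-negative LASSO, shadow rescoring) and
hands the multi-PSM-per-spectrum table to semi-supervised rescoring and
target-decoy FDR at all contexts/levels, followed by coefficient-based
quantification for DIA/PRM/DI runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config
from .deconv import deconvolve_and_rescore
from .fdr import (
    LABEL_DECOY,
    annotate_qvalues,
    semi_supervised_rescore,
    tdc_qvalues,
)
from .predictor import LibraryPredictor, RtModel, ToyPredictor, calibrate_rt, prune_peptide_classes
from .proteome import Peptide, generate_decoys, select_il_representatives
from .search import (
    CandidateMatch,
    FragmentIndex,
    PrecursorSpace,
    candidates_for_spectrum,
    match_peaks,
    prefilter_psm,
    score_psm,
    select_isobaric_representative,
)
from .spectra import ExperimentalSpectrum, RunMetadata

log = logging.getLogger("specdecon")

FEATURE_COLUMNS = [
    "n_matched",
    "matched_intensity_fraction",
    "spectral_angle",
    "explained_tic_fraction",
    "rt_delta_rel",
    "precursor_ppm_error",
    "peptide_length",
    "charge_f",
    "missed_cleavages",
    "top3_matched_count",
    "log_coefficient",
    "raw_spectral_angle",
]


@dataclass
class SearchResult:
    psm_table: pd.DataFrame
    precursor_table: pd.DataFrame
    peptide_group_table: pd.DataFrame
    rt_models: dict[str, RtModel] = field(default_factory=dict)
    ppm_shift: float = 0.0
    fragment_tol_ppm: float = 20.0
    diagnostics: dict = field(default_factory=dict)


def _make_predictor(config: Config):
    p = config.predictor
    if p.mode == "library":
        return LibraryPredictor(p.library_path)
    return ToyPredictor(
        seed=p.seed,
        fixed_mods=config.digest.fixed_mods,
        neutral_losses=p.neutral_losses,
        prediction_noise_sigma=p.prediction_noise_sigma,
    )


def _score_candidates(
    spectrum: ExperimentalSpectrum,
    cand_ids: np.ndarray,
    space: PrecursorSpace,
    predictor,
    tol_ppm: float,
    ppm_shift: float,
    rt_model,
    gradient_length,
) -> list[CandidateMatch]:
    out = []
    for cid in cand_ids:
        pep = space.peptides[cid]
        z = int(space.charges[cid])
        pred = predictor.predict_fragments(pep, z)
        match_idx = match_peaks(pred, spectrum, tol_ppm, ppm_shift)
        if np.count_nonzero(match_idx >= 0) < 3:
            continue
        sv = score_psm(
            match_idx, pred, spectrum, rt_model=rt_model,
            rt_frac=float(space.rt_frac[cid]), gradient_length=gradient_length,
            peptide=pep,
        )
        if not prefilter_psm(sv):
            continue
        out.append(
            CandidateMatch(
                candidate_id=int(cid), peptide=pep, charge=z, predicted=pred,
                match_idx=match_idx, score=sv, rt_frac=float(space.rt_frac[cid]),
                label=int(space.labels[cid]),
            )
        )
    return out


def _pass1(runs, space, index, predictor, config: Config):
    """Coarse search: best prefilter-passing PSM per spectrum, no RT filter."""
    sc = config.search
    rows = []
    for spectra, meta in runs:
        for spectrum in spectra:
            cand_ids = candidates_for_spectrum(
                spectrum, space, index, rt_model=None,
                fragment_tol_ppm=sc.fragment_tol_ppm,
                precursor_tol_ppm=sc.precursor_tol_ppm,
                n_rank=min(50, sc.n_rank),
            )
            if len(cand_ids) == 0:
                continue
            matches = _score_candidates(
                spectrum, cand_ids, space, predictor, sc.fragment_tol_ppm,
                0.0, None, meta.gradient_length,
            )
            if not matches:
                continue
            best = max(matches, key=lambda m: m.score.spectral_angle)
            rows.append(
                {
                    "run_id": spectrum.run_id,
                    "scan_id": spectrum.scan_id,
                    "label": best.label,
                    "is_decoy": best.label == LABEL_DECOY,
                    "sequence": best.peptide.sequence,
                    "peptide": best.peptide,
                    "rt_frac": best.rt_frac,
                    "rt_obs": spectrum.retention_time,
                    "spectral_angle": best.score.spectral_angle,
                    "match": best,
                }
            )
    return pd.DataFrame(rows)


def _ppm_errors(match: CandidateMatch, spectrum: ExperimentalSpectrum) -> np.ndarray:
    m = match.match_idx >= 0
    pred_mz = match.predicted.mz[m]
    exp_mz = spectrum.mz[match.match_idx[m]]
    return (exp_mz - pred_mz) / pred_mz * 1e6


def run_search(
    config: Config,
    runs: list[tuple[list[ExperimentalSpectrum], RunMetadata]],
    target_peptides: list[Peptide],
    entrapment_peptides: list[Peptide] | None = None,
) -> SearchResult:
    """Execute the full two-pass workflow on in-memory runs and peptides."""
    sc, dc = config.search, config.deconv
    predictor = _make_predictor(config)

    # --- search space: targets (+ entrapment) + matched shuffled decoys
    peptides = list(target_peptides)
    if entrapment_peptides:
        target_keys = {p.il_group_key for p in target_peptides}
        peptides += [
            p for p in entrapment_peptides if p.il_group_key not in target_keys
        ]
    decoys = generate_decoys(peptides, seed=config.module_seed("decoys"))
    groups = select_il_representatives(peptides + decoys)
    reps = [rep for rep, _ in groups.values()]
    expansion = {
        (rep.sequence, rep.mod_key, rep.is_decoy): members
        for rep, members in groups.values()
    }
    log.info(
        "search space: %d peptides -> %d I/L representatives (%d decoys)",
        len(peptides) + len(decoys), len(reps), sum(r.is_decoy for r in reps),
    )

    space = PrecursorSpace.build(reps, config.digest.charges, predictor)
    index = FragmentIndex.build(space, config.digest.fixed_mods)
    spectra_by_scan = {
        (s.run_id, s.scan_id): s for spectra, _ in runs for s in spectra
    }

    # --- pass 1: coarse search + LDA-confident set ------------------------
    is_di = all(meta.acquisition_scheme == "DI" for _, meta in runs)
    p1 = _pass1(runs, space, index, predictor, config)
    log.info("pass 1: %d spectra with a prefilter-passing PSM", len(p1))
    rt_models: dict[str, RtModel] = {}
    ppm_shift = 0.0
    frag_tol = sc.fragment_tol_ppm
    confident_peptides: list[Peptide] = []
    if len(p1):
        q1 = tdc_qvalues(p1["spectral_angle"].to_numpy(), p1["is_decoy"].to_numpy())
        conf = p1[(q1 <= 0.01) & ~p1["is_decoy"]]
        log.info("pass 1: %d confident PSMs at 1%% FDR", len(conf))
        confident_peptides = list(conf["peptide"])
        # RT calibration per run
        for _, meta in runs:
            sub = conf[conf["run_id"] == meta.run_id]
            rt_models[meta.run_id] = calibrate_rt(
                list(zip(sub["rt_frac"], sub["rt_obs"])),
                meta.gradient_length,
                security_factor=sc.rt_security_factor,
                floor_minutes=sc.rt_window_floor_min,
            )
        # fragment m/z recalibration
        if sc.recalibrate and len(conf):
            errs = np.concatenate(
                [
                    _ppm_errors(m, spectra_by_scan[(r, s)])
                    for m, r, s in zip(conf["match"], conf["run_id"], conf["scan_id"])
                ]
            )
            if len(errs):
                ppm_shift = float(np.median(errs))
                resid = np.abs(errs - ppm_shift)
                frag_tol = max(
                    sc.recal_tol_floor_ppm, 1.5 * float(np.quantile(resid, 0.95))
                )
                log.info(
                    "recalibration: shift %.2f ppm, tolerance %.2f ppm",
                    ppm_shift, frag_tol,
                )
    if not rt_models:
        for _, meta in runs:
            rt_models[meta.run_id] = calibrate_rt([], meta.gradient_length)

    # class pruning before pass 2; skipped when pass 1 yielded too few
    # confident identifications to define a meaningful class census
    if len(confident_peptides) >= sc.min_confident_for_pruning:
        reps2 = prune_peptide_classes(confident_peptides, reps, sc.min_ids_per_class)
    else:
        reps2 = reps
    if len(reps2) < len(reps):
        log.info("class pruning: %d -> %d representatives", len(reps), len(reps2))
        space = PrecursorSpace.build(reps2, config.digest.charges, predictor)
        index = FragmentIndex.build(space, config.digest.fixed_mods)

    # --- pass 2: RT-filtered search + deconvolution -----------------------
    rows = []
    for spectra, meta in runs:
        rt_model = None if is_di else rt_models[meta.run_id]
        for spectrum in spectra:
            cand_ids = candidates_for_spectrum(
                spectrum, space, index, rt_model=rt_model,
                fragment_tol_ppm=frag_tol, precursor_tol_ppm=sc.precursor_tol_ppm,
                n_rank=sc.n_rank, ppm_shift=ppm_shift,
            )
            if len(cand_ids) == 0:
                continue
            matches = _score_candidates(
                spectrum, cand_ids, space, predictor, frag_tol, ppm_shift,
                rt_model, meta.gradient_length,
            )
            if not matches:
                continue
            matches = select_isobaric_representative(
                matches, sc.precursor_tol_ppm, sc.isobaric_channel_overlap
            )
            psms, _ = deconvolve_and_rescore(
                spectrum, matches, tol_ppm=frag_tol, n_lambda=dc.n_lambda,
                lambda_floor_ratio=dc.lambda_floor_ratio,
                aicc_tie_window=dc.aicc_tie_window, rt_model=rt_model,
                gradient_length=meta.gradient_length,
            )
            for p in psms:
                sv = p.score
                rows.append(
                    {
                        "run_id": spectrum.run_id,
                        "scan_id": spectrum.scan_id,
                        "sequence": p.candidate.peptide.sequence,
                        "il_group_key": p.candidate.peptide.il_group_key,
                        "mod_key": str(p.candidate.peptide.mod_key),
                        "charge": p.candidate.charge,
                        "label": p.candidate.label,
                        "coefficient": p.coefficient,
                        "retention_time": spectrum.retention_time,
                        "rel_rt": spectrum.retention_time / meta.gradient_length,
                        "cycle_index": spectrum.cycle_index,
                        "window_lo": spectrum.window[0],
                        "window_hi": spectrum.window[1],
                        "ambiguous": False,
                        # features
                        "n_matched": sv.n_matched,
                        "matched_intensity_fraction": sv.matched_intensity_fraction,
                        "spectral_angle": sv.spectral_angle,
                        "explained_tic_fraction": sv.explained_tic_fraction,
                        "rt_delta_rel": sv.rt_delta_rel,
                        "precursor_ppm_error": sv.precursor_ppm_error,
                        "peptide_length": sv.peptide_length,
                        "charge_f": float(p.candidate.charge),
                        "missed_cleavages": sv.missed_cleavages,
                        "top3_matched_count": sv.top3_matched_count,
                        "log_coefficient": float(np.log1p(p.coefficient)),
                        "raw_spectral_angle": p.raw_score.spectral_angle,
                    }
                )

    psm_table = pd.DataFrame(rows)
    if len(psm_table) == 0:
        empty = _empty_psm_table()
        return SearchResult(empty, empty.iloc[:0], empty.iloc[:0], rt_models,
                            ppm_shift, frag_tol)
    log.info("pass 2: %d PSMs from %d spectra", len(psm_table),
             psm_table.groupby(["run_id", "scan_id"]).ngroups)

    # --- rescoring + FDR ---------------------------------------------------
    n_dec = int((psm_table["label"] == LABEL_DECOY).sum())
    if n_dec > 0 and n_dec < len(psm_table):
        psm_table["combined_score"] = semi_supervised_rescore(
            psm_table, FEATURE_COLUMNS, folds=config.fdr.folds,
            iterations=config.fdr.iterations, train_fdr=config.fdr.train_fdr,
            subset_cap=config.fdr.subset_cap, seed=config.module_seed("fdr"),
        )
    else:
        psm_table["combined_score"] = psm_table["spectral_angle"]
    psm_table = annotate_qvalues(psm_table)

    # --- I/L expansion: duplicate rows for group members, identical scores
    multi = {
        (rep.sequence, str(rep.mod_key), rep.is_decoy): members
        for rep, members in groups.values()
        if len(members) > 1
    }
    if multi:
        key_series = list(
            zip(
                psm_table["sequence"],
                psm_table["mod_key"],
                psm_table["label"] == LABEL_DECOY,
            )
        )
        hit_rows = [i for i, k in enumerate(key_series) if k in multi]
        extra_rows = []
        for i in hit_rows:
            row = psm_table.iloc[i]
            psm_table.iat[i, psm_table.columns.get_loc("ambiguous")] = True
            for m in multi[key_series[i]]:
                if m.sequence != row["sequence"]:
                    r = row.copy()
                    r["sequence"] = m.sequence
                    r["ambiguous"] = True
                    extra_rows.append(r)
        if extra_rows:
            psm_table = pd.concat(
                [psm_table, pd.DataFrame(extra_rows)], ignore_index=True
            )

    # --- quantification ----------------------------------------------------
    from .quant import assemble_quant_table

    run_meta = {meta.run_id: meta for _, meta in runs}
    precursor_table, pg_table = assemble_quant_table(
        psm_table, run_meta, mode=config.quant.mode,
        q_threshold=config.quant.q_threshold, gap_scans=config.quant.gap_scans,
        border_fallback_min=config.quant.border_fallback_min,
        min_precursors_for_borders=config.quant.min_precursors_for_borders,
    )

    psm_table = psm_table.sort_values(
        ["run_id", "scan_id", "combined_score"],
        ascending=[True, True, False], kind="stable",
    ).reset_index(drop=True)
    return SearchResult(
        psm_table=psm_table, precursor_table=precursor_table,
        peptide_group_table=pg_table, rt_models=rt_models,
        ppm_shift=ppm_shift, fragment_tol_ppm=frag_tol,
    )


def _empty_psm_table() -> pd.DataFrame:
    cols = [
        "run_id", "scan_id", "sequence", "il_group_key", "mod_key", "charge",
        "label", "coefficient", "retention_time", "rel_rt", "cycle_index",
        "window_lo", "window_hi", "ambiguous", "combined_score",
        "q_run_psm", "q_run_precursor", "q_global_precursor",
        "q_global_peptide_group",
    ] + FEATURE_COLUMNS
    return pd.DataFrame(columns=pd.Index(dict.fromkeys(cols)))


PSM_REQUIRED = ["run_id", "scan_id", "sequence", "charge", "label", "coefficient",
                "combined_score", "q_run_psm", "ambiguous"]


def write_results(
    psm_table: pd.DataFrame,
    precursor_table: pd.DataFrame,
    peptide_group_table: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write psms.tsv / precursors.tsv / peptide_groups.tsv.

    Rows are ordered deterministically (run_id, scan_id, score descending);
    multiple PSMs per spectrum are preserved and I/L-ambiguous rows keep
    their 'ambiguous' flag.  Empty tables yield header-only files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {out_dir}: {exc}") from exc

    missing = [c for c in PSM_REQUIRED if c not in psm_table.columns]
    if missing:
        raise ValueError(f"psm table missing required columns: {missing}")
    psm = psm_table.sort_values(
        ["run_id", "scan_id", "combined_score"],
        ascending=[True, True, False], kind="stable",
    )
    paths = {}
    for name, df in (
        ("psms", psm),
        ("precursors", precursor_table),
        ("peptide_groups", peptide_group_table),
    ):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
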