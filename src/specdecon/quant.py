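"""Coefficient-based quantification for DIA/PRM.

A precursor's fitted coefficients across consecutive MS2 scans of one
isolation window form a pseudo-XIC.  The elution apex is the coefficient-
weighted mean of relative retention times over PSMs passing run-specific
PSM-level FDR (transferred from other runs when the run itself has none).
Integration borders per run are capped at the 99% quantile of peak widths at
base from well-covered precursors.  Walking outward from the apex, a single
missing scan is bridged (gap scan); a second consecutive missing scan
inserts a zero and closes the border.  Quantities are either the maximum
coefficient inside the borders (apex mode) or the trapezoidal integral of
the coefficient trace (area mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("specdecon")


@dataclass
class PseudoXIC:
    precursor_key: tuple
    run_id: str
    window: tuple[float, float]
    retention_times: np.ndarray  # minutes, ordered
    coefficients: np.ndarray  # >= 0, zeros may be inserted boundaries
    apex_rt: float
    border_left: float
    border_right: float

    @property
    def apex_intensity(self) -> float:
        return float(self.coefficients.max()) if len(self.coefficients) else 0.0

    @property
    def area(self) -> float:
        if len(self.retention_times) < 2:
            return 0.0
        return float(np.trapezoid(self.coefficients, self.retention_times))


def determine_apex(
    run_psms: pd.DataFrame,
    gradient_length: float,
    cross_run_psms: pd.DataFrame | None = None,
    q_threshold: float = 0.01,
) -> float | None:
    """Apex relative RT for one precursor in one run.

    Coefficient-weighted mean of relative retention times over PSMs meeting
    the run-specific PSM-level q threshold; when none qualify in this run
    the apex is transferred from qualifying PSMs of other runs.  Returns the
    relative position in [0, 1] or None when nothing qualifies anywhere.
    """
    for source in (run_psms, cross_run_psms):
        if source is None or len(source) == 0:
            continue
        qual = source[source["q_run_psm"] <= q_threshold]
        if len(qual) == 0:
            continue
        w = qual["coefficient"].to_numpy(dtype=float)
        rel = qual["rel_rt"].to_numpy(dtype=float)
        if w.sum() <= 0:
            continue
        return float(np.average(rel, weights=w))
    return None


def _peak_width_at_base(
    trace: pd.DataFrame, apex_rel: float, gradient_length: float, gap_scans: int = 1
) -> float:
    """RT span (minutes) of the contiguous coefficient run around the apex
    under the gap rule; ``trace`` has columns cycle_index, rel_rt, coefficient."""
    trace = trace.sort_values("cycle_index")
    cycles = trace["cycle_index"].to_numpy()
    rts = trace["rel_rt"].to_numpy() * gradient_length
    apex_min = apex_rel * gradient_length
    i_apex = int(np.argmin(np.abs(rts - apex_min)))
    lo = i_apex
    while lo > 0 and cycles[lo] - cycles[lo - 1] <= gap_scans + 1:
        lo -= 1
    hi = i_apex
    while hi < len(cycles) - 1 and cycles[hi + 1] - cycles[hi] <= gap_scans + 1:
        hi += 1
    return float(rts[hi] - rts[lo])


def integration_borders(
    run_psm_table: pd.DataFrame,
    gradient_length: float,
    q_threshold: float = 0.01,
    min_psms_per_precursor: int = 3,
    min_precursors: int = 20,
    fallback_minutes: float = 1.0,
    gap_scans: int = 1,
) -> float:
    """Per-run maximum integration border width (minutes).

    The 99% quantile (linear-interpolation definition) of peak widths at base
    from precursors with at least ``min_psms_per_precursor`` PSMs passing the
    run-specific PSM q threshold; falls back to ``fallback_minutes`` when
    fewer than ``min_precursors`` precursors qualify.
    """
    qual = run_psm_table[run_psm_table["q_run_psm"] <= q_threshold]
    widths = []
    for key, sub in qual.groupby(["il_group_key", "mod_key", "charge"], sort=True):
        if len(sub) < min_psms_per_precursor:
            continue
        w = sub["coefficient"].to_numpy(dtype=float)
        apex_rel = float(np.average(sub["rel_rt"], weights=w)) if w.sum() > 0 else None
        if apex_rel is None:
            continue
        widths.append(_peak_width_at_base(sub, apex_rel, gradient_length, gap_scans))
    if len(widths) < min_precursors:
        return fallback_minutes
    return float(np.quantile(widths, 0.99))  # type-7 linear interpolation


def build_pseudo_xic(
    trace: pd.DataFrame,
    apex_rt: float,
    max_border_width: float,
    precursor_key: tuple = (),
    run_id: str = "",
    window: tuple[float, float] = (0.0, 0.0),
    gap_scans: int = 1,
) -> PseudoXIC:
    """Assemble one pseudo-XIC from a coefficient series.

    ``trace`` has columns cycle_index, retention_time (minutes), coefficient;
    one row per scan of the isolation window where the precursor received a
    coefficient.  Walking outward from the scan nearest the apex, up to
    ``gap_scans`` consecutive missing cycles are bridged; the next missing
    cycle inserts a coefficient of 0 at its retention time and terminates the
    border on that side.  Borders are finally clipped symmetrically to
    apex +- max_border_width/2.
    """
    trace = trace.sort_values("cycle_index")
    cycles = trace["cycle_index"].to_numpy()
    rts = trace["retention_time"].to_numpy(dtype=float)
    coefs = trace["coefficient"].to_numpy(dtype=float)
    if len(cycles) == 0:
        return PseudoXIC(precursor_key, run_id, window, np.empty(0), np.empty(0),
                         apex_rt, apex_rt, apex_rt)
    # median cycle spacing in RT, for placing inserted zeros
    if len(rts) > 1:
        dt = np.median(np.diff(rts) / np.maximum(1, np.diff(cycles)))
    else:
        dt = 0.0
    i_apex = int(np.argmin(np.abs(rts - apex_rt)))

    take = [i_apex]
    left_zero = right_zero = None
    i = i_apex
    while i > 0:
        if cycles[i] - cycles[i - 1] <= gap_scans + 1:
            i -= 1
            take.insert(0, i)
        else:
            left_zero = rts[i] - dt
            break
    else:
        pass
    i = i_apex
    while i < len(cycles) - 1:
        if cycles[i + 1] - cycles[i] <= gap_scans + 1:
            i += 1
            take.append(i)
        else:
            right_zero = rts[i] + dt
            break

    xs = list(rts[take])
    ys = list(coefs[take])
    if left_zero is not None:
        xs.insert(0, left_zero)
        ys.insert(0, 0.0)
    if right_zero is not None:
        xs.append(right_zero)
        ys.append(0.0)
    xs = np.asarray(xs)
    ys = np.asarray(ys)

    left = max(xs[0], apex_rt - max_border_width / 2.0)
    right = min(xs[-1], apex_rt + max_border_width / 2.0)
    keep = (xs >= left) & (xs <= right)
    return PseudoXIC(
        precursor_key=precursor_key, run_id=run_id, window=window,
        retention_times=xs[keep], coefficients=ys[keep],
        apex_rt=apex_rt, border_left=left, border_right=right,
    )


def quantify_xic(xic: PseudoXIC, mode: str = "apex") -> float:
    """Quantity of one pseudo-XIC: max coefficient (apex) or trapezoid (area)."""
    if len(xic.coefficients) == 0:
        raise ValueError("cannot quantify an empty pseudo-XIC")
    if mode == "apex":
        return xic.apex_intensity
    if mode == "area":
        return xic.area
    raise ValueError(f"unknown quantification mode {mode!r}")


def assemble_quant_table(
    psm_table: pd.DataFrame,
    run_meta: dict[str, "RunMetadata"],
    mode: str = "apex",
    q_threshold: float = 0.01,
    gap_scans: int = 1,
    border_fallback_min: float = 1.0,
    min_precursors_for_borders: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Precursor- and peptide-group-level quantification tables.

    Every precursor confidently identified in at least one run (global
    precursor q <= threshold) is quantified in all runs where a pseudo-XIC
    can be assembled, irrespective of its run-specific q — both q values are
    reported so users can filter either way.  DDA runs carry identification
    only (empty quantity).  The DI scheme has no RT axis: the quantity is the
    per-scan coefficient summed over scans sharing the isolation window.
    Peptide-group quantity is the sum over member precursors per run.
    """
    df = psm_table[psm_table["label"] != 1].copy()  # targets + entrapment
    prec_keys = ["il_group_key", "mod_key", "charge"]
    confident = df[df["q_global_precursor"] <= q_threshold]
    confident_keys = set(map(tuple, confident[prec_keys].itertuples(index=False)))

    border_by_run = {}
    for run_id, meta in run_meta.items():
        sub = df[df["run_id"] == run_id]
        if meta.acquisition_scheme in ("DIA", "PRM") and len(sub):
            border_by_run[run_id] = integration_borders(
                sub, meta.gradient_length, q_threshold,
                min_precursors=min_precursors_for_borders,
                fallback_minutes=border_fallback_min, gap_scans=gap_scans,
            )

    rows = []
    for key, prec_df in df.groupby(prec_keys, sort=True):
        if tuple(key) not in confident_keys:
            continue
        for run_id, run_df in prec_df.groupby("run_id", sort=True):
            meta = run_meta[run_id]
            rec = {
                "il_group_key": key[0], "mod_key": key[1], "charge": key[2],
                "run_id": run_id,
                "sequence": run_df["sequence"].iloc[0],
                "q_run_precursor": float(run_df["q_run_precursor"].min()),
                "q_global_precursor": float(run_df["q_global_precursor"].min()),
                "ambiguous": bool(run_df["ambiguous"].any()),
                "quantity": np.nan,
                "apex_rel_rt": np.nan,
            }
            if meta.acquisition_scheme == "DDA":
                rows.append(rec)  # identification only in DDA
                continue
            if meta.acquisition_scheme == "DI":
                rec["quantity"] = float(run_df["coefficient"].sum())
                rows.append(rec)
                continue
            cross = prec_df[prec_df["run_id"] != run_id]
            apex_rel = determine_apex(run_df, meta.gradient_length, cross, q_threshold)
            if apex_rel is None:
                rows.append(rec)
                continue
            # one XIC per isolation window; pick the one nearest the precursor
            best_xic = None
            for win, win_df in run_df.groupby(["window_lo", "window_hi"], sort=True):
                trace = win_df[["cycle_index", "retention_time", "coefficient"]]
                trace = trace.groupby("cycle_index", as_index=False).agg(
                    retention_time=("retention_time", "first"),
                    coefficient=("coefficient", "sum"),
                )
                xic = build_pseudo_xic(
                    trace, apex_rel * meta.gradient_length,
                    border_by_run.get(run_id, border_fallback_min),
                    precursor_key=tuple(key), run_id=run_id, window=win,
                    gap_scans=gap_scans,
                )
                if len(xic.coefficients) and (
                    best_xic is None or xic.apex_intensity > best_xic.apex_intensity
                ):
                    best_xic = xic
            if best_xic is not None:
                rec["quantity"] = quantify_xic(best_xic, mode)
                rec["apex_rel_rt"] = apex_rel
            rows.append(rec)

    prec_cols = ["il_group_key", "mod_key", "charge", "run_id", "sequence",
                 "q_run_precursor", "q_global_precursor", "ambiguous",
                 "quantity", "apex_rel_rt"]
    precursor_table = pd.DataFrame(rows, columns=prec_cols if not rows else None)
    if len(precursor_table) == 0:
        pg_cols = ["il_group_key", "mod_key", "run_id", "quantity", "q_global",
                   "q_run", "ambiguous"]
        return precursor_table, pd.DataFrame(columns=pg_cols)

    pg = (
        precursor_table.groupby(["il_group_key", "mod_key", "run_id"], sort=True)
        .agg(
            quantity=("quantity", lambda s: s.sum(min_count=1)),
            q_global=("q_global_precursor", "min"),
            q_run=("q_run_precursor", "min"),
            ambiguous=("ambiguous", "any"),
        )
        .reset_index()
    )
    return precursor_table, pg
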