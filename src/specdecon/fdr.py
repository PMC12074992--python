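"""Target-decoy FDR control with multiple PSMs per spectrum.

q-values come from classic target-decoy competition,
``FDR(t) = (#decoys >= t + 1) / max(1, #targets >= t)`` with the running
minimum taken over looser thresholds.  Entrapment identifications compete as
targets (they have their own shuffled decoys), which is what makes the
empirical entrapment FDR estimates meaningful.

Rescoring is semi-supervised, as is standard in the field: cross-validation
folds split by spectrum, iterative refinement of a linear discriminant
trained on confident targets versus all decoys, and per-fold scores made
comparable by rank-normalization against the fold's decoy distribution.  All
PSMs of a spectrum are retained throughout — the engine's output is
explicitly multi-PSM-per-spectrum.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

log = logging.getLogger("specdecon")

LABEL_TARGET, LABEL_DECOY, LABEL_ENTRAPMENT = 0, 1, 2


@dataclass
class PSMRecord:
    """One candidate-spectrum match after deconvolution."""

    run_id: str
    scan_id: str
    sequence: str
    il_group_key: str
    mod_key: tuple
    charge: int
    label: int  # LABEL_TARGET | LABEL_DECOY | LABEL_ENTRAPMENT
    coefficient: float
    features: dict
    combined_score: float = 0.0
    q_run_psm: float = 1.0
    q_run_precursor: float = 1.0
    q_global_precursor: float = 1.0
    q_global_peptide_group: float = 1.0
    ambiguous: bool = False


def tdc_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-value per record under target-decoy competition.

    Decoys receive the q of their score position; tied scores share one q.
    With zero targets every q is 1.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n = len(scores)
    if n == 0:
        return np.empty(0)
    if (~is_decoy).sum() == 0:
        return np.ones(n)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = is_decoy[order]
    decoys_ge = np.cumsum(d_sorted)
    targets_ge = np.cumsum(~d_sorted)
    fdr = (decoys_ge + 1) / np.maximum(1, targets_ge)
    # tied scores share the counts at the end of the tie block
    last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    block_fdr = fdr.copy()
    idx_last = np.nonzero(last_of_tie)[0]
    start = 0
    for end in idx_last:
        block_fdr[start : end + 1] = fdr[end]
        start = end + 1
    q_sorted = np.minimum.accumulate(block_fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _spectrum_fold(run_id: str, scan_id: str, folds: int, seed: int) -> int:
    h = hashlib.blake2b(f"{seed}|{run_id}|{scan_id}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "little") % folds


def _best_single_feature(
    X: np.ndarray, is_decoy: np.ndarray, train_fdr: float
) -> tuple[int, float]:
    """(feature index, sign) maximizing targets accepted at train_fdr."""
    best = (0, 1.0)
    best_n = -1
    for j in range(X.shape[1]):
        for sign in (1.0, -1.0):
            q = tdc_qvalues(sign * X[:, j], is_decoy)
            n_acc = int(np.sum((q <= train_fdr) & ~is_decoy))
            if n_acc > best_n:
                best_n = n_acc
                best = (j, sign)
    return best


def semi_supervised_rescore(
    psm_table: pd.DataFrame,
    feature_columns: list[str],
    folds: int = 3,
    iterations: int = 10,
    train_fdr: float = 0.01,
    subset_cap: int = 400_000,
    seed: int = 0,
) -> np.ndarray:
    """Combined score per PSM from iterative LDA rescoring (see module doc).

    ``psm_table`` needs columns ``run_id``, ``scan_id``, ``label`` plus the
    feature columns.  Deterministic under ``seed``.  ``iterations=0`` returns
    the best single-feature score.
    """
    df = psm_table
    if len(df) == 0:
        return np.empty(0)
    is_decoy = (df["label"].to_numpy() == LABEL_DECOY)
    if is_decoy.all() or (~is_decoy).sum() == 0 or (is_decoy.sum() == 0):
        raise ValueError("rescoring needs at least one target and one decoy")

    X = df[feature_columns].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(feature_columns, keep) if not k]
        log.warning("dropping zero-variance features: %s", dropped)
        X = X[:, keep]
    mu, sigma = X.mean(axis=0), X.std(axis=0)
    X = (X - mu) / sigma

    fold_of = np.array(
        [
            _spectrum_fold(r, s, folds, seed)
            for r, s in zip(df["run_id"].astype(str), df["scan_id"].astype(str))
        ]
    )
    rng = np.random.default_rng(seed)
    raw = np.zeros(len(df))
    combined = np.zeros(len(df))
    for f in range(folds):
        test = fold_of == f
        train = ~test if folds > 1 else test
        tr_idx = np.nonzero(train)[0]
        if len(tr_idx) > subset_cap:
            tr_idx = rng.choice(tr_idx, size=subset_cap, replace=False)
            tr_idx.sort()
        Xtr, dtr = X[tr_idx], is_decoy[tr_idx]
        if dtr.all() or not dtr.any():
            raw[test] = X[test, 0]
            continue
        j, sign = _best_single_feature(Xtr, dtr, train_fdr)
        score_tr = sign * Xtr[:, j]
        model = None
        for _ in range(iterations):
            q = tdc_qvalues(score_tr, dtr)
            pos = (~dtr) & (q <= train_fdr)
            if pos.sum() < 5:
                break
            sel = pos | dtr
            m = LinearDiscriminantAnalysis()
            m.fit(Xtr[sel], pos[sel].astype(int))
            new = m.decision_function(Xtr)
            # guard against degenerate iterations that lose the positive set
            if np.sum((tdc_qvalues(new, dtr) <= train_fdr) & ~dtr) >= pos.sum() * 0.5:
                score_tr = new
                model = m
        if model is not None:
            raw[test] = model.decision_function(X[test])
        else:
            raw[test] = sign * X[test, j]

        # rank-normalize against the held-out fold's decoy distribution
        dec_scores = np.sort(raw[test & is_decoy])
        if len(dec_scores) == 0:
            dec_scores = np.sort(raw[is_decoy]) if is_decoy.any() else np.array([0.0])
        pos_rank = np.searchsorted(dec_scores, raw[test], side="left")
        combined[test] = pos_rank / max(1, len(dec_scores)) + raw[test] * 1e-9

    return combined


# ---------------------------------------------------------------------------
# rollups
# ---------------------------------------------------------------------------

_LEVEL_KEYS = {
    "psm": ["run_id", "scan_id", "il_group_key", "mod_key", "charge"],
    "precursor": ["il_group_key", "mod_key", "charge"],
    "peptide_group": ["il_group_key", "mod_key"],
}


def rollup(
    records: pd.DataFrame, level: str = "precursor", context: str = "global"
) -> pd.DataFrame:
    """Entity-level q-values: best member score per entity, re-competed.

    ``level`` is one of psm / precursor / peptide_group; ``context`` is run
    (competition within each run) or global (across runs).  Entities whose
    members are all decoys are decoy entities; they are never reported as
    identifications, only used for competition.
    """
    if level not in _LEVEL_KEYS:
        raise ValueError(f"unknown level {level!r}")
    keys = list(_LEVEL_KEYS[level])
    if context == "run" and "run_id" not in keys:
        keys = ["run_id"] + keys
    elif context not in ("run", "global"):
        raise ValueError(f"unknown context {context!r}")
    df = records.copy()
    df["_decoy"] = df["label"] == LABEL_DECOY
    grouped = (
        df.groupby(keys, sort=True)
        .agg(score=("combined_score", "max"), is_decoy=("_decoy", "all"))
        .reset_index()
    )
    if context == "run":
        parts = []
        for _, sub in grouped.groupby("run_id", sort=True):
            sub = sub.copy()
            sub["q"] = tdc_qvalues(sub["score"].to_numpy(), sub["is_decoy"].to_numpy())
            parts.append(sub)
        out = pd.concat(parts, ignore_index=True)
    else:
        grouped["q"] = tdc_qvalues(
            grouped["score"].to_numpy(), grouped["is_decoy"].to_numpy()
        )
        out = grouped
    return out


def annotate_qvalues(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the standard q-value columns to a PSM table.

    Adds ``q_run_psm``, ``q_run_precursor``, ``q_global_precursor`` and
    ``q_global_peptide_group`` by merging the respective rollups.
    """
    df = records.copy()
    for col, (level, context) in {
        "q_run_psm": ("psm", "run"),
        "q_run_precursor": ("precursor", "run"),
        "q_global_precursor": ("precursor", "global"),
        "q_global_peptide_group": ("peptide_group", "global"),
    }.items():
        ent = rollup(df, level=level, context=context)
        keys = [k for k in ent.columns if k not in ("score", "is_decoy", "q")]
        df = df.merge(ent[keys + ["q"]].rename(columns={"q": col}), on=keys, how="left")
    return df


# ---------------------------------------------------------------------------
# entrapment FDR
# ---------------------------------------------------------------------------


@dataclass
class EntrapmentResult:
    thresholds: list[float]
    efdr_lower: list[float]
    efdr_combined: list[float]
    r: float
    n_accepted: list[int] = field(default_factory=list)
    n_entrapment: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "efdr_lower": self.efdr_lower,
                "efdr_combined": self.efdr_combined,
                "n_accepted": self.n_accepted,
                "n_entrapment": self.n_entrapment,
            }
        )


def entrapment_efdr(
    records: pd.DataFrame,
    r: float,
    thresholds: list[float] = (0.01, 0.05),
    q_column: str = "q_run_psm",
) -> EntrapmentResult:
    """Empirical FDR from entrapment identifications.

    At each self-reported q cutoff with N accepted (original + entrapment)
    targets of which E are entrapment: ``efdr_lower = E/N`` and
    ``efdr_combined = E*(1 + 1/r)/N`` where r is the entrapment-to-target
    database size ratio.
    """
    if r <= 0:
        raise ValueError("entrapment ratio r must be > 0")
    df = records[records["label"] != LABEL_DECOY]
    lower, combined, ns, es = [], [], [], []
    for t in thresholds:
        acc = df[df[q_column] <= t]
        n = len(acc)
        e = int((acc["label"] == LABEL_ENTRAPMENT).sum())
        lower.append(e / n if n else 0.0)
        combined.append(min(1.0, e * (1 + 1 / r) / n) if n else 0.0)
        ns.append(n)
        es.append(e)
    return EntrapmentResult(
        thresholds=list(thresholds), efdr_lower=lower, efdr_combined=combined,
        r=r, n_accepted=ns, n_entrapment=es,
    )
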