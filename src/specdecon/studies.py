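"""Reproducible simulation studies built on the synthetic-data generator.

Each study wires the simulator, the two-pass search and the FDR/quant layers
into one seeded, self-contained experiment and reports the summary numbers a
reviewer would ask for: empirical FDP against ground truth, entrapment-based
eFDR, ratio recovery and correlation with true abundances.  The studies are
what the acceptance checks and the test suite run; their defaults are the
study conditions themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config
from .fdr import LABEL_DECOY, LABEL_ENTRAPMENT, entrapment_efdr
from .pipeline import SearchResult, run_search
from .proteome import Peptide, digest_protein, il_key
from .simulate import (
    GroundTruth,
    NoiseConfig,
    generate_proteome,
    simulate_acquisition,
    two_condition_design,
)


def _stable_hash(s: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.blake2b(s.encode(), digest_size=4).digest(), "little")


def _digest_proteome(proteins, max_missed=0, length_range=(7, 30)):
    peptides, seen = [], set()
    for pid, seq in proteins:
        for pep in digest_protein(
            seq, max_missed=max_missed, length_range=length_range,
            protein_id=pid.split()[0],
        ):
            if pep.il_group_key not in seen:
                seen.add(pep.il_group_key)
                peptides.append(pep)
    return peptides


def _entrapment_peptides(proteins, seed, target_keys, length_range=(7, 30)):
    """Digest-level entrapment set: per-peptide shuffles of the target digest."""
    from .proteome import generate_decoys

    targets = _digest_proteome(proteins, length_range=length_range)
    shuffled = generate_decoys(targets, seed=seed)
    out = []
    for p in shuffled:
        if p.unshufflable or p.il_group_key in target_keys:
            continue
        out.append(
            Peptide(
                sequence=p.sequence, is_entrapment=True,
                protein_ids=frozenset("ENTRAP_" + x for x in p.protein_ids),
                missed_cleavages=p.missed_cleavages,
            )
        )
    return out


@dataclass
class CalibrationOutcome:
    fdp_at_q01: float
    efdr_lower_at_q01: float
    efdr_combined_at_q01: float
    n_accepted: int
    n_true_accepted: int
    recovery: float  # fraction of sampled generating peptides recovered


def _true_scan_keys(truth: GroundTruth) -> dict[str, set[str]]:
    return {
        sid: {truth.peptides[i].il_group_key for i, _ in pairs}
        for sid, pairs in truth.contributions.items()
    }


def fdr_calibration_study(
    seed: int,
    window_width: float = 1.4,
    n_proteins: int = 110,
    n_true_peptides: int = 2000,
    gradient_min: float = 30.0,
    cycle_time_s: float = 3.0,
    entrapment_ratio: int = 1,
    noise: NoiseConfig | None = None,
    config: Config | None = None,
) -> CalibrationOutcome:
    """Simulated DDA run with noise spectra and an entrapment database.

    True peptides are drawn from the target digest; the search competes
    targets, an equally sized entrapment set and shuffled decoys.  Reported:
    the ground-truth false discovery proportion among target PSMs accepted at
    run-specific PSM q <= 0.01 (entrapment hits count as false), the
    entrapment eFDR estimates at the same cutoff, and recovery of the
    generating peptides.
    """
    noise = noise or NoiseConfig(
        peak_sigma=0.35,
        noise_peaks_per_spectrum=20,
        noise_peak_intensity=800.0,
        dropout_floor=20.0,
        noise_spectra_per_cycle=2,
    )
    rng = np.random.default_rng(seed)
    proteins = generate_proteome(n_proteins, seed=seed)
    targets = _digest_proteome(proteins)
    target_keys = {p.il_group_key for p in targets}
    entrap = []
    for k in range(entrapment_ratio):
        entrap += _entrapment_peptides(proteins, seed=seed * 1000 + 17 + k, target_keys=target_keys)

    n_true = min(n_true_peptides, len(targets))
    idx = rng.choice(len(targets), size=n_true, replace=False)
    sim_peps = [targets[i] for i in sorted(idx)]
    abund = np.exp(rng.normal(np.log(1e5), 1.0, size=n_true))
    spectra, meta, truth = simulate_acquisition(
        sim_peps, abund, scheme="DDA", window_width=window_width,
        cycle_time_s=cycle_time_s, gradient_min=gradient_min, noise=noise,
        seed=seed, run_id=f"dda_w{window_width}_s{seed}",
    )

    cfg = config or _default_study_config(seed)
    result = run_search(cfg, [(spectra, meta)], targets, entrap)
    return _calibration_outcome(result, truth, entrapment_ratio)


def _default_study_config(seed: int) -> Config:
    cfg = Config(seed=seed)
    cfg.digest.charges = (2, 3)
    return cfg


def _calibration_outcome(
    result: SearchResult, truth: GroundTruth, entrapment_ratio: float
) -> CalibrationOutcome:
    df = result.psm_table
    df = df[~df["ambiguous"] | ~df.duplicated(["run_id", "scan_id", "il_group_key", "charge"])]
    scan_truth = _true_scan_keys(truth)
    acc = df[(df["label"] != LABEL_DECOY) & (df["q_run_psm"] <= 0.01)]
    n_acc = len(acc)
    is_true = [
        lab != LABEL_ENTRAPMENT and k in scan_truth.get(sid, set())
        for lab, k, sid in zip(acc["label"], acc["il_group_key"], acc["scan_id"])
    ]
    n_true_acc = int(np.sum(is_true))
    fdp = (n_acc - n_true_acc) / n_acc if n_acc else 0.0
    eres = entrapment_efdr(df, r=entrapment_ratio, thresholds=[0.01], q_column="q_run_psm")
    sampled_keys = set().union(*scan_truth.values()) if scan_truth else set()
    rec_keys = set(acc[acc["label"] == 0]["il_group_key"]) & sampled_keys
    return CalibrationOutcome(
        fdp_at_q01=fdp,
        efdr_lower_at_q01=eres.efdr_lower[0],
        efdr_combined_at_q01=eres.efdr_combined[0],
        n_accepted=n_acc,
        n_true_accepted=n_true_acc,
        recovery=len(rec_keys) / len(sampled_keys) if sampled_keys else 0.0,
    )


@dataclass
class QuantOutcome:
    ratio_error: dict[str, float]  # species -> |recovered - true| of mean log2 ratio
    recovered_ratio: dict[str, float]
    pearson_r_log: float  # apex quantity vs true abundance, log10 scale
    n_quantified: int


def dia_two_condition_study(
    seed: int,
    n_proteins: int = 24,
    n_peptides: int = 260,
    log2_ratios: dict[str, float] | None = None,
    replicates: int = 1,
    window_width: float = 20.0,
    gradient_min: float = 8.0,
    cycle_time_s: float = 2.0,
    sigma_scale: float = 0.12,
    jitter_cv: float = 0.0,
    mode: str = "apex",
    config: Config | None = None,
) -> QuantOutcome:
    """Two-condition synthetic DIA with three species at known log2 ratios.

    Peptides are partitioned into species tags carrying true log2 fold
    changes; both conditions are simulated, searched and quantified, and the
    per-species mean recovered log2 ratio is compared to truth.  Also reports
    the Pearson correlation between apex quantity and true abundance on the
    log scale within the reference condition.
    """
    log2_ratios = log2_ratios or {"ECOLI": -2.0, "HUMAN": 0.0, "YEAST": 1.0}
    rng = np.random.default_rng(seed)
    proteins = generate_proteome(n_proteins, seed=seed + 7)
    targets = _digest_proteome(proteins)
    # keep precursors inside the simulated window range
    from .predictor import PROTON, peptide_neutral_mass
    from .simulate import assign_charge

    mz_lo, mz_hi = 420.0, 820.0
    in_range = [
        p for p in targets
        if mz_lo
        <= (peptide_neutral_mass(p.sequence, fixed_mods={"C": 57.021464})
            + assign_charge(p) * PROTON) / assign_charge(p)
        <= mz_hi
    ]
    n_pep = min(n_peptides, len(in_range))
    idx = rng.choice(len(in_range), size=n_pep, replace=False)
    sim_peps = [in_range[i] for i in sorted(idx)]
    tags = list(log2_ratios)
    species = [tags[i % len(tags)] for i in range(n_pep)]
    base = np.exp(rng.normal(np.log(1e5), 0.8, size=n_pep))
    design, runs_abund = two_condition_design(
        species, log2_ratios, base, replicates=replicates,
        jitter_cv=jitter_cv, seed=seed,
    )

    cfg = config or _default_study_config(seed)
    cfg.scheme = "DIA"
    cfg.quant.mode = mode
    runs = []
    truths = {}
    for _, drow in design.iterrows():
        rid = drow["run_id"]
        spectra, meta, truth = simulate_acquisition(
            sim_peps, runs_abund[rid], scheme="DIA", window_width=window_width,
            cycle_time_s=cycle_time_s, gradient_min=gradient_min,
            seed=seed + _stable_hash(rid) % 1000, run_id=rid,
            mz_range=(mz_lo, mz_hi), sigma_scale=sigma_scale, species=species,
        )
        runs.append((spectra, meta))
        truths[rid] = truth

    result = run_search(cfg, runs, targets)
    prec = result.precursor_table
    prec = prec[prec["quantity"].notna() & ~prec["ambiguous"]]

    key_of = {il_key(p.sequence): i for i, p in enumerate(sim_peps)}
    prec = prec[prec["il_group_key"].isin(key_of)]
    a_runs = design[design["condition"] == "A"]["run_id"].tolist()
    b_runs = design[design["condition"] == "B"]["run_id"].tolist()
    wide = prec.pivot_table(
        index="il_group_key", columns="run_id", values="quantity", aggfunc="sum"
    )
    rec_ratio: dict[str, list[float]] = {t: [] for t in tags}
    for k, row in wide.iterrows():
        a = np.nanmean([row.get(r, np.nan) for r in a_runs])
        b = np.nanmean([row.get(r, np.nan) for r in b_runs])
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
            rec_ratio[species[key_of[k]]].append(np.log2(b / a))
    recovered = {t: float(np.mean(v)) if v else np.nan for t, v in rec_ratio.items()}
    errors = {t: abs(recovered[t] - log2_ratios[t]) for t in tags}

    # apex quantity vs true abundance, log scale, reference condition run A1
    ref = a_runs[0]
    sub = prec[prec["run_id"] == ref]
    x, y = [], []
    t_ref = truths[ref]
    ab_of = {il_key(p.sequence): t_ref.abundance[i] for i, p in enumerate(sim_peps)}
    for _, row in sub.iterrows():
        ab = ab_of.get(row["il_group_key"])
        if ab and row["quantity"] > 0:
            x.append(np.log10(ab))
            y.append(np.log10(row["quantity"]))
    r = float(np.corrcoef(x, y)[0, 1]) if len(x) > 2 else np.nan
    return QuantOutcome(
        ratio_error=errors, recovered_ratio=recovered,
        pearson_r_log=r, n_quantified=len(prec),
    )
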