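"""Ground-truthed synthetic acquisitions (DDA / DIA / PRM / DI).

The simulator implements the same forward model the engine inverts: every
MS2 spectrum is a linear combination of sum-normalized predicted spectra,
with the contribution of peptide p at retention time t equal to
``abundance_p * exp(-(t - apex_p)^2 / (2 sigma_p^2))``.  The predictor is
shared with the searcher, so a noiseless simulation is a perfect-prediction
regime with exact ground truth.  Configurable noise — per-peak log-normal
jitter, uniform-m/z noise peaks, pure-noise spectra and an intensity-floor
dropout — provides the minimal stress set for the pre-filters, the AICc
model selection and FDR calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta

from .predictor import PROTON, ToyPredictor, peptide_neutral_mass
from .proteome import Peptide
from .spectra import ExperimentalSpectrum, RunMetadata, write_mgf

# canonical vertebrate-like amino-acid frequencies; K+R ~ 11% tunes tryptic
# peptides into the searched 7-30 length range
AA_FREQS = {
    "A": 0.079, "R": 0.055, "N": 0.043, "D": 0.054, "C": 0.019, "Q": 0.039,
    "E": 0.067, "G": 0.066, "H": 0.023, "I": 0.059, "L": 0.097, "K": 0.058,
    "M": 0.024, "F": 0.041, "P": 0.047, "S": 0.066, "T": 0.054, "W": 0.011,
    "Y": 0.029, "V": 0.069,
}


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
    out_fasta: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Random protein sequences with realistic composition; deterministic."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_FREQS))
    probs = np.array(list(AA_FREQS.values()))
    probs = probs / probs.sum()
    entries = []
    for i in range(n_proteins):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=n, p=probs))
        entries.append((f"SYN_{i:05d} synthetic protein {i}", seq))
    if out_fasta is not None:
        _fasta.write(entries, str(out_fasta), file_mode="w")
    return entries


@dataclass
class NoiseConfig:
    peak_sigma: float = 0.0  # log-normal sigma per peak
    noise_peaks_per_spectrum: int = 0
    noise_peak_intensity: float = 0.0  # mean of exponential noise intensity
    dropout_floor: float = 0.0  # absolute intensity floor
    noise_spectra_per_cycle: int = 0  # pure-noise MS2 scans added per cycle (DDA)


@dataclass
class GroundTruth:
    """True abundances, elution parameters and per-scan contributions."""

    peptides: list[Peptide]
    abundance: np.ndarray
    apex_rel: np.ndarray  # fraction of gradient
    sigma_min: np.ndarray  # elution sigma in minutes
    charge: np.ndarray
    mono_mz: np.ndarray
    species: list[str]
    contributions: dict[str, list[tuple[int, float]]] = field(default_factory=dict)

    def peptides_in_scan(self, scan_id: str) -> list[int]:
        return [i for i, _ in self.contributions.get(scan_id, [])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [p.sequence for p in self.peptides],
                "species": self.species,
                "abundance": self.abundance,
                "apex_rel_rt": self.apex_rel,
                "sigma_min": self.sigma_min,
                "charge": self.charge,
                "mono_mz": self.mono_mz,
            }
        )


def assign_charge(pep: Peptide) -> int:
    """2+ for plain tryptic peptides, 3+ with an internal basic residue."""
    internal = pep.sequence[:-1]
    basics = sum(internal.count(c) for c in "RKH")
    return 2 if basics == 0 else 3


def _merge_peaks(
    mz: np.ndarray, intensity: np.ndarray, tol_ppm: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid-merge peaks closer than tol_ppm (intensity-weighted m/z)."""
    if len(mz) == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [], []
    cur_mz, cur_int = mz[0], intensity[0]
    for m, i in zip(mz[1:], intensity[1:]):
        if (m - cur_mz) / cur_mz * 1e6 <= tol_ppm:
            tot = cur_int + i
            cur_mz = (cur_mz * cur_int + m * i) / tot if tot > 0 else cur_mz
            cur_int = tot
        else:
            out_mz.append(cur_mz)
            out_int.append(cur_int)
            cur_mz, cur_int = m, i
    out_mz.append(cur_mz)
    out_int.append(cur_int)
    return np.asarray(out_mz), np.asarray(out_int)


def simulate_acquisition(
    peptides: list[Peptide],
    abundances: np.ndarray,
    scheme: str = "DDA",
    window_width: float = 1.4,
    cycle_time_s: float = 3.0,
    gradient_min: float = 30.0,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    predictor: ToyPredictor | None = None,
    run_id: str = "sim_run",
    mz_range: tuple[float, float] = (400.0, 1000.0),
    sigma_scale: float | None = None,
    species: list[str] | None = None,
    top_n: int = 10,
    dynamic_exclusion_s: float = 20.0,
    n_cycles_di: int = 50,
    merge_tol_ppm: float = 5.0,
) -> tuple[list[ExperimentalSpectrum], RunMetadata, GroundTruth]:
    """Simulate one run of the chosen acquisition scheme (see module doc).

    DIA covers ``mz_range`` with contiguous windows of ``window_width``; DDA
    picks the ``top_n`` most intense precursors per cycle (simulated MS1)
    with dynamic exclusion; PRM cycles over the inclusion windows of all
    peptides; DI has no retention-time axis and acquires ``n_cycles_di``
    cycles at constant composition.  Deterministic under ``seed``.
    """
    noise = noise or NoiseConfig()
    predictor = predictor or ToyPredictor(seed=0)
    rng = np.random.default_rng(seed)
    n = len(peptides)
    abundances = np.asarray(abundances, dtype=float)
    species = list(species) if species is not None else ["default"] * n

    charge = np.array([assign_charge(p) for p in peptides])
    mass = np.array(
        [peptide_neutral_mass(p.sequence, p.modifications, predictor.fixed_mods)
         for p in peptides]
    )
    mono_mz = (mass + charge * PROTON) / charge
    apex_rel = np.array([predictor.predict_rt(p) for p in peptides])
    sigma_center = sigma_scale if sigma_scale is not None else 0.05 * gradient_min / 60.0
    sigma = np.exp(rng.normal(np.log(sigma_center), 0.3, size=n))

    orphans = (mono_mz < mz_range[0]) | (mono_mz > mz_range[1])
    if scheme in ("DIA", "DI") and orphans.any():
        import logging

        logging.getLogger("specdecon").warning(
            "%d peptides outside the simulated window range", int(orphans.sum())
        )

    truth = GroundTruth(
        peptides=list(peptides), abundance=abundances, apex_rel=apex_rel,
        sigma_min=sigma, charge=charge, mono_mz=mono_mz, species=species,
    )
    apex_min = apex_rel * gradient_min
    cycle_min = cycle_time_s / 60.0
    spectra: list[ExperimentalSpectrum] = []

    def make_spectrum(scan_id, rt, center, lo, hi, contrib_ids, contrib_scalars, cyc):
        mz_parts, int_parts = [], []
        for pid, s in zip(contrib_ids, contrib_scalars):
            ps = predictor.predict_fragments(peptides[pid], int(charge[pid]))
            mz_parts.append(ps.mz)
            int_parts.append(ps.intensity * s)
        if mz_parts:
            mz = np.concatenate(mz_parts)
            inten = np.concatenate(int_parts)
            mz, inten = _merge_peaks(mz, inten, merge_tol_ppm)
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        if noise.peak_sigma > 0 and len(inten):
            inten = inten * np.exp(rng.normal(0.0, noise.peak_sigma, size=len(inten)))
        if noise.noise_peaks_per_spectrum > 0:
            k = rng.poisson(noise.noise_peaks_per_spectrum)
            if k > 0:
                nmz = rng.uniform(100.0, 1500.0, size=k)
                nint = rng.exponential(noise.noise_peak_intensity or 1.0, size=k)
                mz, inten = _merge_peaks(
                    np.concatenate([mz, nmz]), np.concatenate([inten, nint]),
                    merge_tol_ppm,
                )
        if noise.dropout_floor > 0 and len(inten):
            keep = inten >= noise.dropout_floor
            mz, inten = mz[keep], inten[keep]
        if len(mz) == 0:
            return None
        spec = ExperimentalSpectrum(
            run_id=run_id, scan_id=scan_id, ms_level=2, retention_time=rt,
            isolation_center=center, isolation_lower_offset=center - lo,
            isolation_upper_offset=hi - center, mz=mz, intensity=inten,
            cycle_index=cyc,
        )
        truth.contributions[scan_id] = list(zip(contrib_ids, contrib_scalars))
        return spec

    def active_at(rt):
        z = (rt - apex_min) / sigma
        mask = np.abs(z) <= 4.0
        ids = np.nonzero(mask)[0]
        return ids, abundances[ids] * np.exp(-0.5 * z[ids] ** 2)

    if scheme in ("DIA", "PRM"):
        if scheme == "DIA":
            edges = np.arange(mz_range[0], mz_range[1] + window_width, window_width)
            windows = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        else:  # PRM: inclusion windows on each in-range peptide
            windows = sorted(
                {
                    (round(m - window_width / 2, 4), round(m + window_width / 2, 4))
                    for m, o in zip(mono_mz, orphans)
                    if not o
                }
            )
        n_cycles = int(gradient_min / cycle_min)
        scan_dt = cycle_min / max(1, len(windows))
        for cyc in range(n_cycles):
            rt0 = cyc * cycle_min
            for wi, (lo, hi) in enumerate(windows):
                rt = rt0 + wi * scan_dt
                ids, scal = active_at(rt)
                in_win = [
                    (i, s)
                    for i, s in zip(ids, scal)
                    if lo <= mono_mz[i] <= hi and s > 0
                ]
                spec = make_spectrum(
                    f"c{cyc}w{wi}", rt, (lo + hi) / 2, lo, hi,
                    [i for i, _ in in_win], [s for _, s in in_win], cyc,
                )
                if spec is not None:
                    spectra.append(spec)
        scheme_name = scheme

    elif scheme == "DDA":
        n_cycles = int(gradient_min / cycle_min)
        last_selected = np.full(n, -np.inf)
        excl_min = dynamic_exclusion_s / 60.0
        scan_counter = 0
        for cyc in range(n_cycles):
            rt0 = cyc * cycle_min
            ids, scal = active_at(rt0)
            if len(ids):
                eligible = rt0 - last_selected[ids] > excl_min
                cand = ids[eligible]
                cscal = scal[eligible]
                order = np.argsort(cscal, kind="stable")[::-1][:top_n]
                selected = cand[order]
            else:
                selected = np.empty(0, dtype=int)
            n_sel = len(selected)
            extra = noise.noise_spectra_per_cycle
            scan_dt = cycle_min / max(1, n_sel + extra)
            slot = 0
            for pid in selected:
                last_selected[pid] = rt0
                center = mono_mz[pid]
                lo, hi = center - window_width / 2, center + window_width / 2
                rt = rt0 + slot * scan_dt
                ids2, scal2 = active_at(rt)
                in_win = [
                    (i, s)
                    for i, s in zip(ids2, scal2)
                    if lo <= mono_mz[i] <= hi and s > 0
                ]
                spec = make_spectrum(
                    f"s{scan_counter}", rt, center, lo, hi,
                    [i for i, _ in in_win], [s for _, s in in_win], cyc,
                )
                scan_counter += 1
                slot += 1
                if spec is not None:
                    spectra.append(spec)
            for _ in range(extra):  # pure-noise MS2 scans
                center = rng.uniform(*mz_range)
                lo, hi = center - window_width / 2, center + window_width / 2
                rt = rt0 + slot * scan_dt
                spec = make_spectrum(f"s{scan_counter}", rt, center, lo, hi, [], [], cyc)
                scan_counter += 1
                slot += 1
                if spec is not None:
                    spectra.append(spec)
        scheme_name = "DDA"

    elif scheme == "DI":
        edges = np.arange(mz_range[0], mz_range[1] + window_width, window_width)
        windows = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        for cyc in range(n_cycles_di):
            for wi, (lo, hi) in enumerate(windows):
                in_win = [
                    (i, float(abundances[i]))
                    for i in range(n)
                    if lo <= mono_mz[i] <= hi
                ]
                spec = make_spectrum(
                    f"c{cyc}w{wi}", 0.0, (lo + hi) / 2, lo, hi,
                    [i for i, _ in in_win], [s for _, s in in_win], cyc,
                )
                if spec is not None:
                    spectra.append(spec)
        scheme_name = "DI"
    else:
        raise ValueError(f"unknown acquisition scheme {scheme!r}")

    meta = RunMetadata(
        run_id=run_id,
        gradient_length=gradient_min if scheme != "DI" else 1.0,
        acquisition_scheme=scheme_name,
        window_scheme=sorted({(round(s.window[0], 4), round(s.window[1], 4)) for s in spectra}),
    )
    return spectra, meta, truth


def two_condition_design(
    species: list[str],
    log2_ratios: dict[str, float],
    base_abundance: np.ndarray,
    replicates: int = 1,
    jitter_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Two-condition abundance design: B = A * 2**ratio(species) per peptide,
    with optional multiplicative replicate jitter of the given CV."""
    for s, r in log2_ratios.items():
        if not np.isfinite(r):
            raise ValueError(f"non-finite ratio for species {s!r}")
    rng = np.random.default_rng(seed)
    base = np.asarray(base_abundance, dtype=float)
    ratio = np.array([log2_ratios.get(s, 0.0) for s in species])
    sigma = np.sqrt(np.log1p(jitter_cv**2)) if jitter_cv > 0 else 0.0
    runs: dict[str, np.ndarray] = {}
    rows = []
    for cond, scale in (("A", np.ones_like(base)), ("B", 2.0**ratio)):
        for rep in range(1, replicates + 1):
            run_id = f"{cond}{rep}"
            ab = base * scale
            if sigma > 0:
                ab = ab * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(ab)))
            runs[run_id] = ab
            rows.append({"run_id": run_id, "condition": cond, "replicate": rep})
    return pd.DataFrame(rows), runs


def write_simulation(
    spectra: list[ExperimentalSpectrum],
    truth: GroundTruth,
    out_dir: str | Path,
    run_id: str = "sim_run",
) -> dict[str, Path]:
    """Write the MGF plus ground_truth.tsv for one simulated run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mgf = write_mgf(spectra, out_dir / f"{run_id}.mgf")
    gt_path = out_dir / f"{run_id}.ground_truth.tsv"
    truth.to_frame().to_csv(gt_path, sep="\t", index=False)
    contrib = pd.DataFrame(
        [
            {"scan_id": sid, "peptide_index": i, "contribution": c}
            for sid, pairs in truth.contributions.items()
            for i, c in pairs
        ]
    )
    contrib_path = out_dir / f"{run_id}.contributions.tsv"
    contrib.to_csv(contrib_path, sep="\t", index=False)
    return {"mgf": mgf, "ground_truth": gt_path, "contributions": contrib_path}
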