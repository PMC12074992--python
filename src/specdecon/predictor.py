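"""Fragment-intensity and retention-time prediction.

The engine only requires that *some* predictor supplies, for every candidate
precursor, a sum-normalized fragment spectrum and a relative retention time.
Two predictors are provided:

* :class:`ToyPredictor` — a deterministic hash-based predictor.  Fragment
  intensities are uniform variates derived from a 64-bit hash of the ion
  descriptor, squared to create dynamic range, then normalized to sum 1.
  The same predictor drives the simulator and the searcher, which yields a
  perfect-prediction regime with exact ground truth; a multiplicative
  log-normal ``prediction_noise_sigma`` degrades the match for robustness
  studies.
* :class:`LibraryPredictor` — intensities and iRT values read from a spectral
  library TSV (columns: peptide, charge, ion_type, index, frag_charge,
  neutral_loss, relative_intensity, irt).

Retention-time calibration maps predicted relative RT (fraction of gradient)
to observed minutes by least squares and derives the pass-2 RT window as the
maximum absolute residual times a security factor of 2.5.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _mass
from scipy import stats

from .proteome import Peptide

PROTON = 1.00727646688
WATER = _mass.calculate_mass(formula="H2O")
NH3 = _mass.calculate_mass(formula="NH3")
AA_MASS = dict(_mass.std_aa_mass)

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

H2O_LOSS_RESIDUES = set("STED")
NH3_LOSS_RESIDUES = set("RKNQ")


@dataclass(frozen=True)
class PredictedSpectrum:
    """Annotated predicted fragment spectrum, intensities normalized to sum 1."""

    peptide: str
    modifications: tuple
    charge: int
    mono_mz: float
    mz: np.ndarray  # sorted ascending
    intensity: np.ndarray
    ion_type: tuple[str, ...]  # "b" | "y"
    ion_index: np.ndarray
    frag_charge: np.ndarray
    neutral_loss: tuple[str, ...]  # "" | "H2O" | "NH3"

    @property
    def base_peak(self) -> int:
        """Index of the most intense predicted fragment."""
        return int(np.argmax(self.intensity))

    @property
    def top3(self) -> np.ndarray:
        """Indices of the (up to) three most intense predicted fragments."""
        k = min(3, len(self.intensity))
        return np.argsort(self.intensity)[::-1][:k]


def normalize(intensity: np.ndarray) -> np.ndarray:
    """Scale intensities to total sum 1 (identity on normalized input)."""
    total = intensity.sum()
    if total <= 0:
        raise ValueError("cannot normalize all-zero intensities")
    return intensity / total


def peptide_neutral_mass(
    sequence: str,
    modifications: tuple = (),
    fixed_mods: dict[str, float] | None = None,
) -> float:
    m = sum(AA_MASS[c] for c in sequence) + WATER
    if fixed_mods:
        m += sum(fixed_mods.get(c, 0.0) for c in sequence)
    m += sum(delta for _, delta, *_ in modifications)
    return m


def _hash_unit(key: str) -> float:
    h = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(h, "little") / 2.0**64


class ToyPredictor:
    """Deterministic stand-in fragment/RT predictor (see module docstring)."""

    def __init__(
        self,
        seed: int = 0,
        fixed_mods: dict[str, float] | None = None,
        neutral_losses: bool = False,
        prediction_noise_sigma: float = 0.0,
        cache_size: int = 300_000,
    ) -> None:
        self.seed = seed
        self.fixed_mods = dict(fixed_mods or {"C": 57.021464})
        self.neutral_losses = neutral_losses
        self.noise_sigma = prediction_noise_sigma
        self._cache: dict[tuple, PredictedSpectrum] = {}
        self._cache_size = cache_size

    # -- fragments ---------------------------------------------------------
    def predict_fragments(
        self, peptide: Peptide | str, charge: int
    ) -> PredictedSpectrum:
        if isinstance(peptide, str):
            peptide = Peptide(sequence=peptide)
        if len(peptide.sequence) < 2:
            raise ValueError("peptide must have length >= 2")
        if charge < 1:
            raise ValueError("charge must be >= 1")
        key = (peptide.sequence, peptide.modifications, charge)
        hit = self._cache.get(key)
        if hit is not None:
            return hit

        seq = peptide.sequence
        n = len(seq)
        res = np.array([AA_MASS[c] + self.fixed_mods.get(c, 0.0) for c in seq])
        for pos, delta, *_ in peptide.modifications:
            if isinstance(pos, int):
                res[pos - 1] += delta
        prefix = np.concatenate([[0.0], np.cumsum(res)])
        neutral = prefix[-1] + WATER
        mono_mz = (neutral + charge * PROTON) / charge

        frag_charges = [1] if charge < 3 else [1, 2]
        mk = peptide.mod_key
        mzs, intens, itypes, idxs, fzs, losses = [], [], [], [], [], []
        for i in range(1, n):
            b_neutral = prefix[i]
            y_neutral = neutral - prefix[i]
            y_index = n - i
            for ion, frag_neutral, idx, span in (
                ("b", b_neutral, i, seq[:i]),
                ("y", y_neutral, y_index, seq[i:]),
            ):
                loss_opts = [("", 0.0)]
                if self.neutral_losses:
                    if set(span) & H2O_LOSS_RESIDUES:
                        loss_opts.append(("H2O", WATER))
                    if set(span) & NH3_LOSS_RESIDUES:
                        loss_opts.append(("NH3", NH3))
                for loss_name, loss_mass in loss_opts:
                    for fz in frag_charges:
                        u = _hash_unit(
                            f"{self.seed}|{seq}|{mk}|{ion}|{idx}|{fz}|{loss_name}"
                        )
                        raw = u * u  # exponent tilt for dynamic range
                        if loss_name:
                            raw *= 0.25  # losses are minor species
                        if self.noise_sigma > 0:
                            g = _hash_unit(
                                f"noise|{self.seed}|{seq}|{mk}|{ion}|{idx}|{fz}|{loss_name}"
                            )
                            z = stats.norm.ppf(min(max(g, 1e-12), 1 - 1e-12))
                            raw *= float(np.exp(self.noise_sigma * z))
                        mzs.append((frag_neutral - loss_mass + fz * PROTON) / fz)
                        intens.append(raw)
                        itypes.append(ion)
                        idxs.append(idx)
                        fzs.append(fz)
                        losses.append(loss_name)

        order = np.argsort(mzs, kind="stable")
        spec = PredictedSpectrum(
            peptide=seq,
            modifications=peptide.modifications,
            charge=charge,
            mono_mz=mono_mz,
            mz=np.asarray(mzs)[order],
            intensity=normalize(np.asarray(intens)[order]),
            ion_type=tuple(np.asarray(itypes)[order]),
            ion_index=np.asarray(idxs)[order],
            frag_charge=np.asarray(fzs)[order],
            neutral_loss=tuple(np.asarray(losses)[order]),
        )
        if len(self._cache) < self._cache_size:
            self._cache[key] = spec
        return spec

    # -- retention time ----------------------------------------------------
    def predict_rt(self, peptide: Peptide | str) -> float:
        """Relative RT in [0, 1]: affine in mean Kyte-Doolittle hydropathy."""
        seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
        mean_kd = sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)
        return float(np.clip(0.5 + mean_kd / 9.0, 0.02, 0.98))


class LibraryPredictor:
    """Spectral-library predictor reading the TSV dialect described above."""

    def __init__(self, library_path: str) -> None:
        df = pd.read_csv(library_path, sep="\t")
        required = {
            "peptide", "charge", "ion_type", "index", "frag_charge",
            "neutral_loss", "relative_intensity", "irt",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"library missing columns: {sorted(missing)}")
        self._groups = {k: g for k, g in df.groupby(["peptide", "charge"])}
        irts = df.groupby("peptide")["irt"].first()
        lo, hi = float(irts.min()), float(irts.max())
        span = hi - lo if hi > lo else 1.0
        self._rt = {p: (v - lo) / span for p, v in irts.items()}
        self.fixed_mods = {"C": 57.021464}

    def predict_fragments(self, peptide: Peptide | str, charge: int) -> PredictedSpectrum:
        seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
        mods = peptide.modifications if isinstance(peptide, Peptide) else ()
        key = (seq, charge)
        if key not in self._groups:
            raise KeyError(f"library has no entry for {seq}/{charge}+")
        g = self._groups[key].copy()
        neutral = peptide_neutral_mass(seq, mods, self.fixed_mods)
        mono_mz = (neutral + charge * PROTON) / charge
        n = len(seq)
        res = np.array([AA_MASS[c] + self.fixed_mods.get(c, 0.0) for c in seq])
        prefix = np.concatenate([[0.0], np.cumsum(res)])
        mzs = []
        for _, row in g.iterrows():
            idx, fz = int(row["index"]), int(row["frag_charge"])
            if row["ion_type"] == "b":
                frag_neutral = prefix[idx]
            else:
                frag_neutral = (prefix[-1] + WATER) - prefix[n - idx]
            loss = str(row["neutral_loss"]) if str(row["neutral_loss"]) not in ("nan", "none") else ""
            frag_neutral -= {"": 0.0, "H2O": WATER, "NH3": NH3}[loss]
            mzs.append((frag_neutral + fz * PROTON) / fz)
        g["mz"] = mzs
        g = g.sort_values("mz", kind="stable")
        return PredictedSpectrum(
            peptide=seq,
            modifications=mods,
            charge=charge,
            mono_mz=mono_mz,
            mz=g["mz"].to_numpy(),
            intensity=normalize(g["relative_intensity"].to_numpy(dtype=float)),
            ion_type=tuple(g["ion_type"]),
            ion_index=g["index"].to_numpy(dtype=int),
            frag_charge=g["frag_charge"].to_numpy(dtype=int),
            neutral_loss=tuple(
                "" if str(x) in ("nan", "none") else str(x) for x in g["neutral_loss"]
            ),
        )

    def predict_rt(self, peptide: Peptide | str) -> float:
        seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
        if seq not in self._rt:
            raise KeyError(f"library has no iRT for {seq}")
        return float(self._rt[seq])


@dataclass
class RtModel:
    """Calibration of predicted relative RT to observed minutes."""

    slope: float
    intercept: float
    rt_window_halfwidth: float  # minutes
    mode: str = "toy"
    calibrated: bool = True

    def predict_minutes(self, rt_fraction: float | np.ndarray) -> float | np.ndarray:
        return self.slope * rt_fraction + self.intercept


def calibrate_rt(
    confident_psms: list[tuple[float, float]],
    gradient_length: float,
    security_factor: float = 2.5,
    floor_minutes: float = 0.5,
    min_psms: int = 10,
) -> RtModel:
    """Fit predicted-fraction -> observed-minutes by least squares.

    The pass-2 RT window halfwidth is the 100% quantile (maximum) of the
    absolute residuals times the security factor, floored at
    ``floor_minutes``.  With fewer than ``min_psms`` pairs or a degenerate
    predictor the model falls back to a full-gradient window.
    """
    fallback = RtModel(
        slope=gradient_length,
        intercept=0.0,
        rt_window_halfwidth=gradient_length,
        calibrated=False,
    )
    if len(confident_psms) < min_psms:
        return fallback
    pred = np.array([p for p, _ in confident_psms], dtype=float)
    obs = np.array([o for _, o in confident_psms], dtype=float)
    if np.ptp(pred) <= 0:
        import logging

        logging.getLogger("specdecon").warning(
            "degenerate RT predictor (zero variance); full-gradient window"
        )
        return fallback
    fit = stats.linregress(pred, obs)
    if fit.slope <= 0:
        return fallback
    resid = obs - (fit.slope * pred + fit.intercept)
    halfwidth = max(floor_minutes, float(np.max(np.abs(resid))) * security_factor)
    return RtModel(
        slope=float(fit.slope), intercept=float(fit.intercept),
        rt_window_halfwidth=halfwidth,
    )


def peptide_class(peptide: Peptide) -> tuple:
    """Search-space class key: (length, missed cleavages, modification multiset)."""
    return (len(peptide.sequence), peptide.missed_cleavages, peptide.mod_key)


def prune_peptide_classes(
    confident_peptides: list[Peptide],
    search_space: list[Peptide],
    min_ids_per_class: int = 1,
) -> list[Peptide]:
    """Drop search-space classes with too few confident pass-1 identifications.

    A threshold of 0 disables pruning.  Decoys follow the class census of the
    targets so that target and decoy spaces stay matched.
    """
    if min_ids_per_class <= 0:
        return list(search_space)
    from collections import Counter

    census = Counter(peptide_class(p) for p in confident_peptides)
    return [p for p in search_space if census[peptide_class(p)] >= min_ids_per_class]
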