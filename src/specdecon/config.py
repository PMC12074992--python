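"""Run-level configuration.

A single :class:`Config` object carries every tunable of the engine.  It can
be built programmatically (all fields have defaults) or loaded from a TOML or
YAML file whose top-level tables mirror the dataclass sections below.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("specdecon")


@dataclass
class DigestConfig:
    enzyme: str = "trypsin"  # after K/R, not before P
    max_missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 30
    charges: tuple[int, ...] = (2, 3, 4)
    fixed_mods: dict[str, float] = field(
        default_factory=lambda: {"C": 57.021464}
    )  # carbamidomethyl-C
    variable_mods: dict[str, float] = field(default_factory=dict)  # e.g. {"M": 15.994915}
    max_variable_mods: int = 2


@dataclass
class PredictorConfig:
    mode: str = "toy"  # "toy" | "library"
    seed: int = 0
    prediction_noise_sigma: float = 0.0  # multiplicative log-normal sigma
    neutral_losses: bool = False
    library_path: str | None = None
    collision_energy: float = 28.0  # provenance tag only


@dataclass
class SearchConfig:
    fragment_tol_ppm: float = 20.0
    precursor_tol_ppm: float = 10.0
    n_rank: int = 200  # candidates retained per spectrum pre-deconvolution
    recalibrate: bool = True
    recal_tol_floor_ppm: float = 5.0
    rt_window_floor_min: float = 0.5
    rt_security_factor: float = 2.5
    min_ids_per_class: int = 1
    min_confident_for_pruning: int = 50
    isobaric_channel_overlap: float = 0.9


@dataclass
class DeconvConfig:
    n_lambda: int = 30
    lambda_floor_ratio: float = 1e-3
    aicc_tie_window: float = 0.0
    max_sweeps: int = 1000
    cd_tol: float = 1e-8


@dataclass
class FdrConfig:
    folds: int = 3
    iterations: int = 10
    train_fdr: float = 0.01
    subset_cap: int = 400_000
    seed: int = 0


@dataclass
class QuantConfig:
    mode: str = "apex"  # "apex" | "area"
    gap_scans: int = 1
    border_fallback_min: float = 1.0
    min_precursors_for_borders: int = 20
    q_threshold: float = 0.01


@dataclass
class Config:
    """Top-level engine configuration; sections are plain dataclasses."""

    digest: DigestConfig = field(default_factory=DigestConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    fdr: FdrConfig = field(default_factory=FdrConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    # run-level
    seed: int = 0
    scheme: str = "DDA"  # DDA | DIA | PRM | DI
    default_isolation_width: float = 1.4  # Th, fallback when files lack window info
    gradient_length: float | None = None  # minutes; inferred from data when None
    threads: int = 1

    def module_seed(self, name: str) -> int:
        """Derive a stable per-module seed (< 2**31) from the global seed."""
        import hashlib

        h = hashlib.blake2b(f"{self.seed}:{name}".encode(), digest_size=4).digest()
        return int.from_bytes(h, "little") % (2**31)


_SECTIONS = {
    "digest": DigestConfig,
    "predictor": PredictorConfig,
    "search": SearchConfig,
    "deconv": DeconvConfig,
    "fdr": FdrConfig,
    "quant": QuantConfig,
}


def load_config(path: str | Path) -> Config:
    """Load a :class:`Config` from a ``.toml`` or ``.yaml``/``.yml`` file."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")

    kwargs: dict = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            sec_fields = {f.name for f in dataclasses.fields(_SECTIONS[key])}
            unknown = set(val) - sec_fields
            if unknown:
                raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
            if "charges" in val:
                val["charges"] = tuple(val["charges"])
            kwargs[key] = _SECTIONS[key](**val)
        else:
            kwargs[key] = val
    return Config(**kwargs)


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
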