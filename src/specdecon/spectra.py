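"""Experimental spectra and their file formats (MGF, mzML).

Retention times are stored in **minutes** throughout the package; MGF
``RTINSECONDS`` values are divided by 60 on input.  Isolation windows are
stored as a center m/z plus asymmetric positive offsets.  MGF has no standard
field for the isolation window, so the internal MGF dialect carries it in the
user tags ``ISOLATION_CENTER``, ``ISOLATION_LOWER`` and ``ISOLATION_UPPER``;
files lacking them fall back to a configured default width centered on
``PEPMASS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed or lacks required metadata."""


@dataclass
class ExperimentalSpectrum:
    """One centroided MS2 scan."""

    run_id: str
    scan_id: str
    ms_level: int
    retention_time: float  # minutes
    isolation_center: float  # Th
    isolation_lower_offset: float  # Th, > 0
    isolation_upper_offset: float  # Th, > 0
    mz: np.ndarray  # sorted ascending
    intensity: np.ndarray  # >= 0
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in scan {self.scan_id}")
        if self.isolation_lower_offset <= 0 or self.isolation_upper_offset <= 0:
            raise ValueError(f"non-positive isolation offsets in scan {self.scan_id}")

    @property
    def window(self) -> tuple[float, float]:
        return (
            self.isolation_center - self.isolation_lower_offset,
            self.isolation_center + self.isolation_upper_offset,
        )

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class RunMetadata:
    run_id: str
    gradient_length: float  # minutes
    acquisition_scheme: str = "DDA"  # DDA | DIA | PRM | DI
    window_scheme: list[tuple[float, float]] = field(default_factory=list)


def _window_from_params(
    params: dict, scan_id: str, default_width: float | None
) -> tuple[float, float, float]:
    if "isolation_center" in params:
        center = float(params["isolation_center"])
        lower = float(params.get("isolation_lower", 0.0))
        upper = float(params.get("isolation_upper", 0.0))
        if lower > 0 and upper > 0:
            return center, lower, upper
    pepmass = params.get("pepmass")
    if pepmass is not None and default_width is not None:
        center = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
        return center, default_width / 2.0, default_width / 2.0
    raise SpectrumFormatError(
        f"scan {scan_id}: no isolation window metadata and no default width configured"
    )


def _read_mgf(path: Path, run_id: str, default_width: float | None):
    spectra = []
    try:
        reader = _mgf.MGF(str(path))
    except Exception as exc:  # pragma: no cover - pyteomics raises various types
        raise SpectrumFormatError(f"cannot parse MGF {path}: {exc}") from exc
    with reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            scan_id = str(params.get("scans", params.get("title", f"index={i}")))
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else 0.0
            center, lo, up = _window_from_params(params, scan_id, default_width)
            spectra.append(
                ExperimentalSpectrum(
                    run_id=run_id,
                    scan_id=scan_id,
                    ms_level=2,
                    retention_time=rt_min,
                    isolation_center=center,
                    isolation_lower_offset=lo,
                    isolation_upper_offset=up,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    cycle_index=int(params.get("cycle_index", 0)),
                )
            )
    return spectra


# mzML cv accessions used by the reader
_CV = {
    "ms_level": "MS:1000511",
    "scan_start": "MS:1000016",
    "iso_target": "MS:1000827",
    "iso_lower": "MS:1000828",
    "iso_upper": "MS:1000829",
    "selected_mz": "MS:1000744",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
}


def _cv_params(elem) -> dict[str, str]:
    return {
        c.get("accession"): c.get("value", "")
        for c in elem.iter("{*}cvParam")
    }


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    node = bda.find("{*}binary")
    raw = base64.b64decode(node.text or "")
    if _CV["zlib"] in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV["f32"] in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _read_mzml(path: Path, run_id: str, default_width: float | None):
    """Minimal mzML reader (lxml): centroided MS2 scans with isolation info.

    Supports 32/64-bit float arrays, optional zlib compression and scan start
    times in minutes or seconds.
    """
    spectra = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SpectrumFormatError(f"cannot parse mzML {path}: {exc}") from exc
    for i, spec in enumerate(tree.iter("{*}spectrum")):
        top = {
            c.get("accession"): c.get("value", "")
            for c in spec.findall("{*}cvParam")
        }
        if int(top.get(_CV["ms_level"], 0) or 0) != 2:
            continue
        scan_id = spec.get("id", f"index={i}")
        rt_min = 0.0
        scan = spec.find(".//{*}scanList/{*}scan")
        if scan is not None:
            for c in scan.findall("{*}cvParam"):
                if c.get("accession") == _CV["scan_start"]:
                    rt_min = float(c.get("value"))
                    if c.get("unitName", "minute").startswith("second"):
                        rt_min /= 60.0
        params: dict = {}
        iso = spec.find(".//{*}precursor/{*}isolationWindow")
        if iso is not None:
            p = _cv_params(iso)
            if _CV["iso_target"] in p:
                params["isolation_center"] = float(p[_CV["iso_target"]])
                lo = float(p.get(_CV["iso_lower"], 0) or 0)
                up = float(p.get(_CV["iso_upper"], 0) or 0)
                if lo > 0 and up > 0:
                    params["isolation_lower"] = lo
                    params["isolation_upper"] = up
                elif default_width is not None:
                    params["isolation_lower"] = default_width / 2.0
                    params["isolation_upper"] = default_width / 2.0
        sel = spec.find(".//{*}precursor//{*}selectedIon")
        if sel is not None and "isolation_center" not in params:
            p = _cv_params(sel)
            if _CV["selected_mz"] in p:
                params["pepmass"] = float(p[_CV["selected_mz"]])
        mz = inten = None
        for bda in spec.findall(".//{*}binaryDataArray"):
            p = _cv_params(bda)
            if _CV["mz_array"] in p:
                mz = _decode_binary_array(bda)
            elif _CV["intensity_array"] in p:
                inten = _decode_binary_array(bda)
        if mz is None or inten is None:
            raise SpectrumFormatError(f"scan {scan_id}: missing peak arrays")
        center, lo, up = _window_from_params(params, str(scan_id), default_width)
        spectra.append(
            ExperimentalSpectrum(
                run_id=run_id,
                scan_id=str(scan_id),
                ms_level=2,
                retention_time=rt_min,
                isolation_center=center,
                isolation_lower_offset=lo,
                isolation_upper_offset=up,
                mz=mz,
                intensity=inten,
            )
        )
    return spectra


def read_spectra(
    path: str | Path,
    format: str | None = None,
    default_isolation_width: float | None = 1.4,
    scheme: str = "DDA",
    gradient_length: float | None = None,
) -> tuple[list[ExperimentalSpectrum], RunMetadata]:
    """Read all MS2 scans of a run from an MGF or mzML file.

    Returns the spectra (peaks sorted, RT in minutes) and run-level metadata.
    MS1 scans are skipped.  ``format`` is inferred from the suffix when None.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    run_id = path.stem
    if fmt == "mgf":
        spectra = _read_mgf(path, run_id, default_isolation_width)
    elif fmt == "mzml":
        spectra = _read_mzml(path, run_id, default_isolation_width)
    else:
        raise SpectrumFormatError(f"unsupported spectrum format: {fmt}")

    if gradient_length is None:
        rt_max = max((s.retention_time for s in spectra), default=0.0)
        gradient_length = max(rt_max, 1e-3)
    windows = sorted({(round(s.window[0], 4), round(s.window[1], 4)) for s in spectra})
    meta = RunMetadata(
        run_id=run_id,
        gradient_length=gradient_length,
        acquisition_scheme=scheme,
        window_scheme=[tuple(w) for w in windows],
    )
    return spectra, meta


def write_mgf(spectra: list[ExperimentalSpectrum], path: str | Path) -> Path:
    """Write spectra in the internal MGF dialect (round-trips the isolation window)."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.run_id}.{s.scan_id}\n")
            fh.write(f"SCANS={s.scan_id}\n")
            fh.write(f"RTINSECONDS={s.retention_time * 60.0:.6f}\n")
            fh.write(f"PEPMASS={s.isolation_center:.5f}\n")
            fh.write(f"ISOLATION_CENTER={s.isolation_center:.5f}\n")
            fh.write(f"ISOLATION_LOWER={s.isolation_lower_offset:.5f}\n")
            fh.write(f"ISOLATION_UPPER={s.isolation_upper_offset:.5f}\n")
            fh.write(f"CYCLE_INDEX={s.cycle_index}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {inten:.6g}\n")
            fh.write("END IONS\n\n")
    return path
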