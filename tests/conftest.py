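"""Shared fixtures: predictors, tiny peptide sets and spectrum builders."""

from __future__ import annotations

import base64

import numpy as np
import pytest

from specdecon.predictor import ToyPredictor
from specdecon.proteome import Peptide
from specdecon.spectra import ExperimentalSpectrum


@pytest.fixture(scope="session")
def predictor() -> ToyPredictor:
    return ToyPredictor(seed=42)


@pytest.fixture
def make_spectrum():
    """Factory for an ExperimentalSpectrum with sensible defaults."""

    def _make(mz, intensity, center=500.0, lower=0.7, upper=0.7, rt=10.0,
              run_id="run", scan_id="scan1", cycle_index=0):
        return ExperimentalSpectrum(
            run_id=run_id, scan_id=scan_id, ms_level=2, retention_time=rt,
            isolation_center=center, isolation_lower_offset=lower,
            isolation_upper_offset=upper, mz=np.asarray(mz, dtype=float),
            intensity=np.asarray(intensity, dtype=float),
            cycle_index=cycle_index,
        )

    return _make


@pytest.fixture
def spectrum_for(predictor, make_spectrum):
    """A pure (single-peptide) spectrum scaled by a total ion current."""

    def _make(sequence: str, charge: int = 2, scale: float = 1000.0, **kw):
        ps = predictor.predict_fragments(Peptide(sequence=sequence), charge)
        kw.setdefault("center", ps.mono_mz)
        return ps, make_spectrum(ps.mz.copy(), ps.intensity * scale, **kw)

    return _make


def minimal_mzml(spectra_spec) -> str:
    """Hand-assembled minimal mzML document for reader tests.

    ``spectra_spec``: list of dicts with keys ms_level, rt_s, mz, intensity
    and optionally precursor=(center, lower, upper).
    """

    def b64(arr):
        return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()

    parts = []
    for i, s in enumerate(spectra_spec):
        prec = ""
        if s.get("precursor"):
            c, lo, up = s["precursor"]
            prec = (
                '<precursorList count="1"><precursor><isolationWindow>'
                f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{c}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{lo}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{up}"/>'
                "</isolationWindow></precursor></precursorList>"
            )
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s["mz"])}">'
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s["ms_level"]}"/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s["rt_s"]}" unitName="second"/>'
            "</scan></scanList>"
            f"{prec}"
            '<binaryDataArrayList count="2">'
            '<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>'
            f'<binary>{b64(s["mz"])}</binary></binaryDataArray>'
            '<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>'
            f'<binary>{b64(s["intensity"])}</binary></binaryDataArray>'
            "</binaryDataArrayList></spectrum>"
        )
    return (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        f'<run id="testrun"><spectrumList count="{len(parts)}">{"".join(parts)}'
        "</spectrumList></run></mzML>"
    )
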