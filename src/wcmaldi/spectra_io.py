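"""Spectrum and sample-sheet I/O.

Every downstream stage (preprocessing, multivariate scoring, dose-response
analysis) consumes only the containers defined here: :class:`Spectrum` for a
single profile-mode mass spectrum and :class:`SampleSheet` for the mapping of
spectra to compound, concentration and replicate structure.

Supported on-disk formats:

* two-column text profiles (m/z, intensity), whitespace- or comma-separated,
  with ``#``-prefixed comment lines — the dialect produced by vendor
  text-export batch tools;
* a minimal self-contained subset of mzML (profile spectra, 32/64-bit float
  arrays, uncompressed or zlib), read and written without external parsers;
* CSV sample sheets with columns ``sample_id, compound, concentration_molar,
  tech_rep, bio_rep`` (an optional ``group`` column is carried through).

Concentrations are stored in molar units throughout the package.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

_MZML_NS = "http://psi.hupo.org/ms/mzml"


@dataclass
class Spectrum:
    """One profile-mode mass spectrum.

    ``mz`` is strictly increasing (Thomson); ``intensity`` is the same length
    and non-negative in arbitrary units. ``sample_id`` is an opaque string
    linking the spectrum to its sample-sheet row.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise DataError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise DataError(
                f"mz ({len(self.mz)}) and intensity ({len(self.intensity)}) "
                "differ in length"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise DataError("mz values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all intensities."""
        return float(np.sum(self.intensity))

    @classmethod
    def from_pairs(cls, mz, intensity, sample_id: str = "", metadata=None) -> "Spectrum":
        """Build a spectrum from unordered (m/z, intensity) pairs.

        Pairs are sorted by m/z; duplicate m/z values collapse by summing
        their intensities (profile accumulation). The pairing is never
        reordered relative to itself.
        """
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if len(mz) != len(intensity):
            raise DataError("mz/intensity length mismatch")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
        if len(uniq) < len(mz):
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, intensity)
            n_dup = int(len(mz) - len(uniq))
            logger.info("collapsed %d duplicate m/z values by summing", n_dup)
            mz, intensity = uniq, summed
        return cls(mz, intensity, sample_id=sample_id, metadata=metadata or {})


def read_spectrum_text(path) -> Spectrum:
    """Read a two-column text profile (m/z, intensity).

    Accepts whitespace- or comma-separated columns; lines starting with ``#``
    and blank lines are skipped. Output is sorted by m/z with duplicate m/z
    collapsed by summing. Requires at least two data rows.
    """
    path = Path(path)
    mzs: list[float] = []
    ints: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if not mzs:
        raise ParseError(f"{path}: empty spectrum file")
    if len(mzs) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, got {len(mzs)}")
    return Spectrum.from_pairs(mzs, ints, sample_id=path.stem)


def write_spectrum_text(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two whitespace-separated columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {spectrum.sample_id}\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.17g} {i:.17g}\n")


# ---------------------------------------------------------------------------
# Minimal mzML support.
#
# No full-featured mzML backend is used; the subset written here is a valid
# mzML skeleton (profile spectra, base64 little-endian float arrays) and the
# reader accepts 32/64-bit floats with or without zlib compression, which
# covers converter output for simple profile data.
# ---------------------------------------------------------------------------

def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def _decode_binary(binary_el, n_points: int, cvs: set) -> np.ndarray:
    data = base64.b64decode(binary_el.text or "")
    if "MS:1000574" in cvs:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in cvs else "<f8"
    arr = np.frombuffer(data, dtype=dtype).astype(float)
    if n_points and len(arr) != n_points:
        raise ParseError(
            f"binary array length {len(arr)} != defaultArrayLength {n_points}"
        )
    return arr


def write_mzml(spectra, path) -> None:
    """Write spectra to a minimal mzML file.

    Arrays are stored as uncompressed little-endian 64-bit floats; each
    spectrum's ``id`` attribute carries its ``sample_id``.
    """
    spectra = list(spectra)
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0">',
        ' <cvList count="1">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
        ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        "</cvList>",
        ' <run id="run0">',
        f'  <spectrumList count="{len(spectra)}">',
    ]
    for idx, s in enumerate(spectra):
        enc_mz = _encode_array(s.mz)
        enc_int = _encode_array(s.intensity)
        lines += [
            f'   <spectrum index="{idx}" id="{s.sample_id or f"scan={idx}"}"'
            f' defaultArrayLength="{len(s)}">',
            '    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>',
            '    <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>',
            '    <binaryDataArrayList count="2">',
        ]
        for enc, acc, name, unit in (
            (enc_mz, "MS:1000514", "m/z array",
             ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'),
            (enc_int, "MS:1000515", "intensity array",
             ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"'),
        ):
            lines += [
                f'     <binaryDataArray encodedLength="{len(enc)}">',
                '      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
                '      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
                f'      <cvParam cvRef="MS" accession="{acc}" name="{name}" value=""{unit}/>',
                f"      <binary>{enc}</binary>",
                "     </binaryDataArray>",
            ]
        lines += ["    </binaryDataArrayList>", "   </spectrum>"]
    lines += ["  </spectrumList>", " </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))


def _iter_mzml_spectra(path):
    tag = f"{{{_MZML_NS}}}spectrum"
    for _event, el in ElementTree.iterparse(str(path), events=("end",)):
        if el.tag == tag:
            yield el
            el.clear()


def read_spectrum_mzml(path, index: int = 0) -> Spectrum:
    """Read the ``index``-th spectrum of an mzML file.

    Centroid-only spectra are accepted with a logged warning (downstream
    binning still operates on them); a missing index raises an error.
    """
    path = Path(path)
    ns = f"{{{_MZML_NS}}}"
    for i, el in enumerate(_iter_mzml_spectra(path)):
        if i != index:
            continue
        n_points = int(el.get("defaultArrayLength", 0))
        spec_cvs = {cv.get("accession") for cv in el.findall(f"{ns}cvParam")}
        if "MS:1000127" in spec_cvs:
            logger.warning("%s[%d]: centroid spectrum, expected profile", path, index)
        mz = inten = None
        for bda in el.iter(f"{ns}binaryDataArray"):
            cvs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
            arr = _decode_binary(bda.find(f"{ns}binary"), n_points, cvs)
            if "MS:1000514" in cvs:
                mz = arr
            elif "MS:1000515" in cvs:
                inten = arr
        if mz is None or inten is None:
            raise ParseError(f"{path}: spectrum {index} lacks m/z or intensity array")
        return Spectrum.from_pairs(mz, inten, sample_id=el.get("id", f"scan={index}"))
    raise DataError(f"{path}: spectrum index {index} out of range")


def count_mzml_spectra(path) -> int:
    """Number of spectra in an mzML file."""
    return sum(1 for _ in _iter_mzml_spectra(path))


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample_id", "compound", "concentration_molar", "tech_rep", "bio_rep")


@dataclass
class SampleSheet:
    """Per-sample metadata: compound, molar concentration, replicate labels.

    Backed by a DataFrame with one row per ``sample_id``. Concentration 0
    marks vehicle controls.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"sample sheet missing columns: {missing}")
        ids = self.table["sample_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise DataError(f"duplicate sample_id: {dup.iloc[0]!r}")
        conc = pd.to_numeric(self.table["concentration_molar"], errors="coerce")
        if conc.isna().any():
            bad = self.table.loc[conc.isna(), "sample_id"].iloc[0]
            raise DataError(f"non-numeric concentration for sample {bad!r}")
        if (conc < 0).any():
            bad = self.table.loc[conc < 0, "sample_id"].iloc[0]
            raise DataError(f"negative concentration for sample {bad!r}")
        for col in ("tech_rep", "bio_rep"):
            vals = pd.to_numeric(self.table[col], errors="coerce")
            if vals.isna().any() or not np.allclose(vals, np.round(vals)):
                raise DataError(f"{col} must contain integers")
            self.table[col] = vals.astype(int)
        self.table = self.table.assign(concentration_molar=conc.astype(float)).reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def row(self, sample_id: str) -> pd.Series:
        hit = self.table[self.table["sample_id"] == sample_id]
        if hit.empty:
            raise DataError(f"sample {sample_id!r} not in sample sheet")
        return hit.iloc[0]

    def reindex(self, sample_ids) -> "SampleSheet":
        """Return a sheet whose row order follows ``sample_ids``."""
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(sub)


def read_sample_sheet(path) -> SampleSheet:
    """Read and validate a CSV sample sheet (concentrations in molar)."""
    df = pd.read_csv(path)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)
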