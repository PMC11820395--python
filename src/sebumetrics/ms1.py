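"""Centroid MS1 spectra: in-memory container plus MS1-text and mzML I/O.

The MS1 text dialect is the one emitted by raw-file converters: ``H`` header
lines, ``S <num> <num>`` scan starts, ``I RTime <minutes>`` per scan, then
whitespace-separated ``<m/z> <intensity>`` peak lines.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree

import numpy as np

from .errors import ParseError, UnsupportedContentError, ValidationError

__all__ = [
    "CentroidSpectrum",
    "read_ms1",
    "write_ms1",
    "read_mzml",
    "write_mzml",
]


@dataclass
class CentroidSpectrum:
    """One centroided MS1 scan.

    Parameters
    ----------
    retention_time : float
        Scan retention time in minutes.
    mz : ndarray
        Peak m/z values in Da, strictly increasing.
    intensity : ndarray
        Non-negative peak intensities, same length as ``mz``.
    """

    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValidationError("m/z values must be strictly increasing within a scan")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)


def read_ms1(path: str | Path) -> list[CentroidSpectrum]:
    """Parse an MS1 text file into a list of :class:`CentroidSpectrum`.

    Scans appear in file order. A scan with peaks but no ``I RTime`` line is a
    :class:`ParseError`; so is a non-numeric peak line (reported with its line
    number). An empty file yields an empty list.
    """
    path = Path(path)
    spectra: list[CentroidSpectrum] = []
    scan_id: str | None = None
    rtime: float | None = None
    mzs: list[float] = []
    intens: list[float] = []

    def flush() -> None:
        nonlocal rtime, mzs, intens
        if scan_id is None:
            return
        if rtime is None:
            raise ParseError(f"{path.name}: scan {scan_id} has no RTime header")
        spectra.append(
            CentroidSpectrum(retention_time=rtime, mz=np.array(mzs), intensity=np.array(intens))
        )
        rtime, mzs, intens = None, [], []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("H"):
                continue
            fields = line.split()
            if fields[0] == "S":
                flush()
                scan_id = fields[1] if len(fields) > 1 else str(lineno)
            elif fields[0] == "I":
                if len(fields) >= 3 and fields[1] == "RTime":
                    try:
                        rtime = float(fields[2])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path.name}:{lineno}: bad RTime value {fields[2]!r}"
                        ) from exc
            elif fields[0] == "Z":
                continue  # charge lines are legal but unused
            else:
                try:
                    mz, inten = float(fields[0]), float(fields[1])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path.name}:{lineno}: bad peak line {line!r}") from exc
                mzs.append(mz)
                intens.append(inten)
    flush()
    return spectra


def write_ms1(path: str | Path, spectra: Sequence[CentroidSpectrum]) -> None:
    """Write spectra as MS1 text. Output is byte-stable for identical input."""
    path = Path(path)
    lines = [
        "H\tExtractor\tsebumetrics",
        "H\tComment\tsimulated centroid MS1 spectra",
    ]
    for i, spec in enumerate(spectra, start=1):
        lines.append(f"S\t{i:06d}\t{i:06d}")
        lines.append(f"I\tRTime\t{spec.retention_time:.6f}")
        for mz, inten in zip(spec.mz, spec.intensity):
            lines.append(f"{mz:.5f} {inten:.4f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mzML


def _b64(arr: np.ndarray) -> str:
    data = struct.pack(f"<{arr.size}d", *np.asarray(arr, dtype=np.float64))
    return base64.b64encode(data).decode("ascii")


_MZML_SPECTRUM = """\
      <spectrum index="{index}" id="scan={num}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_DOC = """\
<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="sebumetrics" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="sebumetrics"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="dp1">
      <processingMethod order="1" softwareRef="sebumetrics">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="dp1">
{spectra}    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(path: str | Path, spectra: Sequence[CentroidSpectrum]) -> None:
    """Write a minimal centroided MS1-only mzML file (uncompressed 64-bit)."""
    blocks = []
    for i, spec in enumerate(spectra):
        mz_b64 = _b64(spec.mz)
        int_b64 = _b64(spec.intensity)
        blocks.append(
            _MZML_SPECTRUM.format(
                index=i,
                num=i + 1,
                n=len(spec),
                rt=spec.retention_time,
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    Path(path).write_text(_MZML_DOC.format(count=len(spectra), spectra="".join(blocks)))


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit float, plain or zlib."""
    import zlib

    accessions = {cv.get("accession") for cv in elem.iter(f"{_NS}cvParam")}
    binary = elem.find(f"{_NS}binary")
    data = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(data, dtype=dtype).astype(np.float64)


def read_mzml(path: str | Path) -> list[CentroidSpectrum]:
    """Read centroided MS1 spectra from an mzML file.

    Supports uncompressed or zlib-compressed 32/64-bit float arrays. Raises
    :class:`UnsupportedContentError` for profile-mode spectra or files with
    no MS1 scans.
    """
    path = Path(path)
    try:
        root = ElementTree.parse(path).getroot()
    except ElementTree.ParseError as exc:
        raise ParseError(f"{path.name}: not well-formed XML: {exc}") from exc
    spectra: list[CentroidSpectrum] = []
    for spectrum in root.iter(f"{_NS}spectrum"):
        params = {
            cv.get("accession"): cv
            for cv in spectrum.findall(f"{_NS}cvParam")
        }
        ms_level = params.get("MS:1000511")
        if ms_level is not None and ms_level.get("value") != "1":
            continue
        if "MS:1000128" in params:  # profile spectrum
            raise UnsupportedContentError(
                f"{path.name}: profile-mode spectra are not supported"
            )
        rt_min = None
        for cv in spectrum.iter(f"{_NS}cvParam"):
            if cv.get("accession") == "MS:1000016":
                value = float(cv.get("value"))
                rt_min = value / 60.0 if cv.get("unitName") == "second" else value
        if rt_min is None:
            raise ParseError(f"{path.name}: spectrum {spectrum.get('id')!r} has no scan start time")
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall(f"{_NS}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary_array(bda)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary_array(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise ParseError(f"{path.name}: spectrum {spectrum.get('id')!r} lacks m/z or intensity arrays")
        order = np.argsort(arrays["mz"], kind="stable")
        spectra.append(
            CentroidSpectrum(rt_min, arrays["mz"][order], arrays["intensity"][order])
        )
    if not spectra:
        raise UnsupportedContentError(f"{path.name}: no centroided MS1 spectra found")
    return spectra
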