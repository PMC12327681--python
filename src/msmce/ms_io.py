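"""Reading and writing mass-spectrometry runs.

Two formats are supported:

* **mzML** (read-only): a self-contained reader for MS1 spectra built on the
  standard-library XML parser.  Binary arrays may be 32- or 64-bit floats,
  raw or zlib-compressed.  Retention times are converted to seconds.
* **fixture** (read/write): one JSON object per line — a header with the run
  label and file id, then one line per scan.  Floats round-trip exactly
  through ``repr``-based JSON encoding, which makes the format suitable for
  golden tests and synthetic data.
"""

from __future__ import annotations

import base64
import json
import logging
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Spectrum", "Run", "read_run", "write_fixture", "write_mzml"]


@dataclass
class Spectrum:
    """One scan: parallel m/z (Da) and intensity arrays plus a retention time (s)."""

    mz: np.ndarray
    intensity: np.ndarray
    rt: float

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError(
                f"mz and intensity must be equal-length 1-D arrays, "
                f"got {self.mz.shape} and {self.intensity.shape}")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum arrays")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity values")
        if self.rt < 0:
            raise ValueError(f"negative retention time: {self.rt}")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            # repairable: sort peaks by m/z (keeps pairing with intensities)
            logger.warning("spectrum at rt=%.3f s has non-monotone m/z; sorting", self.rt)
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError("duplicate m/z values within one scan")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (self.rt == other.rt
                and np.array_equal(self.mz, other.mz)
                and np.array_equal(self.intensity, other.intensity))


@dataclass
class Run:
    """Ordered spectra from one file plus its class label."""

    spectra: list[Spectrum]
    label: str
    file_id: str = ""

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError(f"empty run: {self.file_id!r}")
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Run):
            return NotImplemented
        return (self.label == other.label and self.file_id == other.file_id
                and len(self.spectra) == len(other.spectra)
                and all(a == b for a, b in zip(self.spectra, other.spectra)))


def read_run(path: str | Path, format: str | None = None) -> Run:
    """Read one run; ``format`` is ``"mzml"``, ``"fixture"``, or ``None`` to
    infer from the file extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "fixture"
    if format == "mzml":
        return _read_mzml(path)
    if format == "fixture":
        return _read_fixture(path)
    raise ValueError(f"unknown format {format!r}")


def write_fixture(run: Run, path: str | Path) -> Path:
    """Write a run as line-oriented JSON; exact numeric round trip."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"label": run.label, "file_id": run.file_id}) + "\n")
        for s in run.spectra:
            fh.write(json.dumps({
                "rt": s.rt,
                "mz": s.mz.tolist(),
                "intensity": s.intensity.tolist(),
            }) + "\n")
    return path


def _read_fixture(path: Path) -> Run:
    with path.open() as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty run: {path}")
    header = json.loads(lines[0])
    spectra = []
    for ln in lines[1:]:
        rec = json.loads(ln)
        spectra.append(Spectrum(np.array(rec["mz"], dtype=np.float64),
                                np.array(rec["intensity"], dtype=np.float64),
                                float(rec["rt"])))
    if not spectra:
        raise ValueError(f"empty run: {path}")
    return Run(spectra, label=str(header.get("label", "")),
               file_id=str(header.get("file_id", path.stem)))


# --------------------------------------------------------------------------
# mzML
# --------------------------------------------------------------------------

_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(elem) -> np.ndarray:
    dtype = np.float64
    compressed = False
    text = ""
    for child in elem.iter():
        t = _strip_ns(child.tag)
        if t == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = np.float32
            elif acc == _ACC_F64:
                dtype = np.float64
            elif acc == _ACC_ZLIB:
                compressed = True
        elif t == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _read_mzml(path: Path) -> Run:
    spectra: list[Spectrum] = []
    skipped_msn = 0
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if _strip_ns(elem.tag) != "spectrum":
            continue
        ms_level = 1
        rt = None
        arrays: dict[str, np.ndarray] = {}
        for child in elem.iter():
            t = _strip_ns(child.tag)
            if t == "cvParam":
                acc = child.get("accession", "")
                if acc == _ACC_MS_LEVEL:
                    ms_level = int(child.get("value", "1"))
                elif acc == _ACC_SCAN_START:
                    value = float(child.get("value", "0"))
                    unit = child.get("unitName", "second").lower()
                    rt = value * 60.0 if unit == "minute" else value
            elif t == "binaryDataArray":
                kind = None
                for cv in child.iter():
                    if _strip_ns(cv.tag) == "cvParam":
                        if cv.get("accession") == _ACC_MZ_ARRAY:
                            kind = "mz"
                        elif cv.get("accession") == _ACC_INTENSITY_ARRAY:
                            kind = "intensity"
                if kind:
                    arrays[kind] = _decode_binary(child)
        if ms_level != 1:
            skipped_msn += 1
        elif "mz" in arrays and "intensity" in arrays:
            spectra.append(Spectrum(arrays["mz"], arrays["intensity"],
                                    rt if rt is not None else float(len(spectra))))
        elem.clear()
    if skipped_msn:
        logger.warning("%s: ignored %d MSn spectra (only MS1 is read)", path, skipped_msn)
    if not spectra:
        raise ValueError(f"empty run: {path}")
    spectra.sort(key=lambda s: s.rt)
    return Run(spectra, label="", file_id=path.stem)


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{n}">
        <cvParam accession="MS:1000511" name="ms level" value="1"/>
        <scanList count="1">
          <scan>
            <cvParam accession="MS:1000016" name="scan start time" value="{rt}" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray>
            <cvParam accession="MS:1000523" name="64-bit float"/>
            <cvParam accession="MS:1000576" name="no compression"/>
            <cvParam accession="MS:1000514" name="m/z array"/>
            <binary>{mz}</binary>
          </binaryDataArray>
          <binaryDataArray>
            <cvParam accession="MS:1000523" name="64-bit float"/>
            <cvParam accession="MS:1000576" name="no compression"/>
            <cvParam accession="MS:1000515" name="intensity array"/>
            <binary>{intensity}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: Run, path: str | Path) -> Path:
    """Write a minimal-but-valid mzML file (uncompressed 64-bit arrays).

    Intended for reader integration tests, not archival use.
    """
    path = Path(path)

    def b64(arr: np.ndarray) -> str:
        return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode()

    with path.open("w") as fh:
        fh.write(_MZML_HEADER.format(run_id=run.file_id or "run", count=len(run.spectra)))
        for i, s in enumerate(run.spectra):
            fh.write(_MZML_SPECTRUM.format(index=i, n=s.mz.size, rt=repr(s.rt),
                                           mz=b64(s.mz), intensity=b64(s.intensity)))
        fh.write(_MZML_FOOTER)
    return path
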