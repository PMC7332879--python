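"""Run containers and on-disk formats.

A :class:`CentroidRun` is one centroided LC-MS1 acquisition: ordered scans
of (m/z, intensity) centroids with retention times and sample metadata
(sample id, role, solvent extract, species).  Two interchangeable disk
formats are supported:

* the package's tabular scan CSV (``scan,rt_min,mz,intensity`` with ``#``
  metadata header lines) — the default, diffable format;
* mzML 1.1 centroid MS1 — written by a minimal in-package writer
  (64-bit little-endian, base64, uncompressed) and read by a
  namespace-agnostic ElementTree parser that also accepts 32-bit and
  zlib-compressed arrays from other producers.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

__all__ = [
    "RunMetadata",
    "CentroidScan",
    "CentroidRun",
    "write_scan_csv",
    "read_scan_csv",
    "write_mzml",
    "read_mzml",
]

#: Allowed run roles: species reference, blank pipe, QC pool, ancient sample.
ROLES = ("species_ref", "blank", "qc", "ancient")


@dataclass(frozen=True)
class RunMetadata:
    run_id: str
    sample: str = ""
    role: str = "species_ref"
    solvent: str = ""
    species: str = ""
    replicate: int = 0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass
class CentroidScan:
    """One MS1 scan: 1-based index, retention time (min), sorted centroids."""

    index: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z must be strictly increasing within a scan")

    @property
    def n_centroids(self) -> int:
        return int(self.mz.size)


@dataclass
class CentroidRun:
    metadata: RunMetadata
    scans: list[CentroidScan] = field(default_factory=list)

    def __post_init__(self):
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")

    @property
    def run_id(self) -> str:
        return self.metadata.run_id

    def n_centroids(self) -> int:
        return sum(s.n_centroids for s in self.scans)


# ---------------------------------------------------------------- scan CSV

_META_FIELDS = ("run_id", "sample", "role", "solvent", "species", "replicate")


def write_scan_csv(run: CentroidRun, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key in _META_FIELDS:
            fh.write(f"# {key}={getattr(run.metadata, key)}\n")
        fh.write("scan,rt_min,mz,intensity\n")
        for scan in run.scans:
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{scan.index},{scan.rt:.6f},{mz:.6f},{inten:.3f}\n")


def read_scan_csv(path: str | Path) -> CentroidRun:
    path = Path(path)
    meta: dict[str, str] = {}
    scans: dict[int, tuple[float, list[float], list[float]]] = {}
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("scan,"):
                continue
            idx_s, rt_s, mz_s, int_s = line.split(",")
            idx = int(idx_s)
            entry = scans.setdefault(idx, (float(rt_s), [], []))
            entry[1].append(float(mz_s))
            entry[2].append(float(int_s))
    metadata = RunMetadata(
        run_id=meta.get("run_id", path.stem),
        sample=meta.get("sample", ""),
        role=meta.get("role", "species_ref"),
        solvent=meta.get("solvent", ""),
        species=meta.get("species", ""),
        replicate=int(meta.get("replicate", 0) or 0),
    )
    scan_list = [
        CentroidScan(index=i, rt=rt, mz=np.array(mzs), intensity=np.array(ints))
        for i, (rt, mzs, ints) in sorted(scans.items())
    ]
    return CentroidRun(metadata=metadata, scans=scan_list)


# ------------------------------------------------------------------- mzML

def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    ).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index0}" id="scan={index}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def write_mzml(run: CentroidRun, path: str | Path) -> None:
    """Write a centroid MS1 mzML file readable by pyteomics/ProteoWizard.

    Sample metadata beyond the run id is not representable in plain mzML;
    pair the file with a manifest row when roles matter downstream.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_MZML_HEADER.format(run_id=escape(run.run_id), count=len(run.scans)))
        for i, scan in enumerate(run.scans):
            mz_b64 = _b64(scan.mz)
            int_b64 = _b64(scan.intensity)
            fh.write(_MZML_SPECTRUM.format(
                index0=i, index=scan.index, n=scan.n_centroids, rt=f"{scan.rt:.6f}",
                mz_len=len(mz_b64), mz_b64=mz_b64,
                int_len=len(int_b64), int_b64=int_b64,
            ))
        fh.write("    </spectrumList>\n  </run>\n</mzML>\n")


def read_mzml(path: str | Path, metadata: RunMetadata | None = None) -> CentroidRun:
    """Read centroid MS1 spectra from an mzML file.

    A namespace-agnostic ElementTree parser covering the common dialect:
    64-/32-bit float binary arrays, optionally zlib-compressed.  Scan
    start times in seconds (unitName="second") are converted to minutes.
    """
    import xml.etree.ElementTree as ET
    import zlib as _zlib

    path = Path(path)

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    scans = []
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        params = {}
        for cv in elem.iter():
            if local(cv.tag) == "cvParam":
                params.setdefault(cv.get("accession"), cv)
        if params.get("MS:1000511") is not None and \
                params["MS:1000511"].get("value") not in ("1", 1, None):
            elem.clear()
            continue
        rt, rt_unit = None, ""
        arrays: dict[str, np.ndarray] = {}
        for sub in elem.iter():
            tag = local(sub.tag)
            if tag == "scan":
                for cv in sub:
                    if local(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000016":
                        rt = float(cv.get("value"))
                        rt_unit = cv.get("unitName", "")
            elif tag == "binaryDataArray":
                kind, dtype, compressed, payload = None, "<d", False, ""
                for cv in sub:
                    ctag = local(cv.tag)
                    if ctag == "cvParam":
                        acc = cv.get("accession")
                        if acc == "MS:1000514":
                            kind = "mz"
                        elif acc == "MS:1000515":
                            kind = "intensity"
                        elif acc == "MS:1000521":
                            dtype = "<f"
                        elif acc == "MS:1000574":
                            compressed = True
                    elif ctag == "binary":
                        payload = cv.text or ""
                if kind:
                    raw = base64.b64decode(payload)
                    if compressed:
                        raw = _zlib.decompress(raw)
                    arrays[kind] = np.frombuffer(raw, dtype=np.dtype(dtype)).astype(float)
        scan_id = elem.get("id", "")
        idx = len(scans) + 1
        if "scan=" in scan_id:
            idx = int(scan_id.split("scan=")[1].split()[0])
        if rt is None:
            rt = float(len(scans))
        elif rt_unit == "second":
            rt /= 60.0
        scans.append(CentroidScan(
            index=idx, rt=rt,
            mz=arrays.get("mz", np.empty(0)),
            intensity=arrays.get("intensity", np.empty(0)),
        ))
        elem.clear()
    scans.sort(key=lambda s: s.index)
    if metadata is None:
        metadata = RunMetadata(run_id=path.stem)
    return CentroidRun(metadata=metadata, scans=scans)
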