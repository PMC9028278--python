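"""Centroided LC-MS data model, mzML 1.1 read/write, and XIC extraction.

The in-memory model is deliberately small: a :class:`Run` is a time-ordered
list of :class:`Spectrum` objects holding numpy peak arrays. Each spectrum is
classified into one of three scan functions used by the multi-scan soft-spot
workflow:

``full``
    MS1 survey scan (ms level 1).
``aif``
    All-ion fragmentation: ms level 2 with no selected precursor, or an
    isolation window spanning >= 100 m/z (the whole range is fragmented).
``targeted_msms``
    Precursor-selected MS/MS (PRM/DDA).

The mzML layer reads and writes uncompressed 64-bit-float centroid mzML via
lxml. Retention times are minutes throughout.
"""

from __future__ import annotations

import base64
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from lxml import etree

__all__ = [
    "Spectrum",
    "Run",
    "XIC",
    "ChromPeak",
    "classify_scan_function",
    "read_run",
    "write_run",
    "extract_xic",
    "find_peaks",
    "xic_to_tsv",
]

FULL = "full"
AIF = "aif"
TARGETED = "targeted_msms"

_MZML_NS = "http://psi.hupo.org/ms/mzml"

# isolation windows at least this wide (m/z) are treated as all-ion fragmentation
AIF_ISOLATION_WIDTH = 100.0


@dataclass
class Spectrum:
    """One centroided scan: retention time (minutes), peak arrays, metadata."""

    scan_id: str
    time: float
    ms_level: int
    scan_function: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    isolation_width: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.time < 0:
            raise ValueError("scan time must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Run:
    """A time-ordered collection of spectra plus free-form metadata."""

    spectra: list[Spectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: s.time)

    def __len__(self) -> int:
        return len(self.spectra)

    def select(self, scan_function: Optional[str] = None) -> list[Spectrum]:
        if scan_function is None:
            return list(self.spectra)
        return [s for s in self.spectra if s.scan_function == scan_function]


@dataclass
class XIC:
    """Extracted ion chromatogram: one point per contributing scan."""

    target_mz: float
    ppm_tol: float
    times: np.ndarray
    intensities: np.ndarray


@dataclass(frozen=True)
class ChromPeak:
    """A chromatographic peak found in an XIC."""

    apex_time: float
    apex_intensity: float
    start_time: float
    end_time: float


def classify_scan_function(
    ms_level: int,
    precursor_mz: Optional[float],
    isolation_width: Optional[float],
) -> str:
    """Scan-function label from mzML-level metadata (see module docstring)."""
    if ms_level == 1:
        return FULL
    if precursor_mz is None:
        return AIF
    if isolation_width is not None and isolation_width >= AIF_ISOLATION_WIDTH:
        return AIF
    return TARGETED


# ----------------------------------------------------------------------------
# mzML writing


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    etree.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value, **attrs
    )


def write_run(run: Run, path: str) -> None:
    """Write a Run as centroid mzML 1.1 (uncompressed 64-bit floats)."""
    root = etree.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    run_el = etree.SubElement(root, "run", id=str(run.metadata.get("id", "run")))
    slist = etree.SubElement(run_el, "spectrumList", count=str(len(run.spectra)))
    for idx, s in enumerate(run.spectra):
        sp = etree.SubElement(
            slist,
            "spectrum",
            index=str(idx),
            id=s.scan_id or f"scan={idx + 1}",
            defaultArrayLength=str(len(s)),
        )
        _cv(sp, "MS:1000511", "ms level", str(s.ms_level))
        _cv(sp, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(sp, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            repr(float(s.time)),
            unitCvRef="UO",
            unitAccession="UO:0000031",
            unitName="minute",
        )
        if s.ms_level >= 2:
            plist = etree.SubElement(sp, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            iso = etree.SubElement(prec, "isolationWindow")
            width = s.isolation_width
            if width is None:
                width = 1.0 if s.precursor_mz is not None else 1400.0
            target = s.precursor_mz if s.precursor_mz is not None else 800.0
            _cv(iso, "MS:1000827", "isolation window target m/z", repr(float(target)))
            _cv(iso, "MS:1000828", "isolation window lower offset", repr(width / 2))
            _cv(iso, "MS:1000829", "isolation window upper offset", repr(width / 2))
            if s.precursor_mz is not None:
                silist = etree.SubElement(prec, "selectedIonList", count="1")
                si = etree.SubElement(silist, "selectedIon")
                _cv(si, "MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)))
        balist = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (s.mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z")),
            (s.intensity, "MS:1000515", "intensity array", ("MS:1000131", "number of detector counts")),
        ):
            payload = _b64(arr)
            ba = etree.SubElement(balist, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, acc, name, unitCvRef="MS", unitAccession=unit[0], unitName=unit[1])
            etree.SubElement(ba, "binary").text = payload
    etree.ElementTree(root).write(
        path, xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ----------------------------------------------------------------------------
# mzML reading


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(el) -> dict[str, tuple[str, dict]]:
    out = {}
    for child in el:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = (child.get("value", ""), dict(child.attrib))
    return out


def _find(el, name: str):
    for child in el.iter():
        if _local(child.tag) == name:
            return child
    return None


def _decode_binary_arrays(sp) -> tuple[np.ndarray, np.ndarray]:
    mz_arr = np.empty(0)
    int_arr = np.empty(0)
    for ba in sp.iter():
        if _local(ba.tag) != "binaryDataArray":
            continue
        params = _cv_params(ba)
        binary = _find(ba, "binary")
        raw = base64.b64decode(binary.text or "") if binary is not None else b""
        if "MS:1000574" in params:
            import zlib

            raw = zlib.decompress(raw)
        dtype = "<f4" if "MS:1000521" in params else "<f8"
        arr = np.frombuffer(raw, dtype=dtype).astype(float)
        if "MS:1000514" in params:
            mz_arr = arr
        elif "MS:1000515" in params:
            int_arr = arr
    return mz_arr, int_arr


def _naive_centroid(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local-maxima centroiding for profile data (fallback only)."""
    if len(mz) < 3:
        return mz, intensity
    keep = np.zeros(len(mz), dtype=bool)
    keep[1:-1] = (intensity[1:-1] >= intensity[:-2]) & (intensity[1:-1] > intensity[2:]) & (
        intensity[1:-1] > 0
    )
    return mz[keep], intensity[keep]


def _parse_spectrum(sp) -> Spectrum:
    params = _cv_params(sp)
    ms_level = int(params.get("MS:1000511", ("1",))[0] or 1)
    scan_id = sp.get("id", "")
    time = 0.0
    scan = _find(sp, "scan")
    if scan is not None:
        sparams = _cv_params(scan)
        if "MS:1000016" in sparams:
            value, attrs = sparams["MS:1000016"]
            time = float(value)
            if attrs.get("unitName", "minute").startswith("second"):
                time /= 60.0
    precursor_mz = None
    isolation_width = None
    plist = None
    for child in sp:
        if _local(child.tag) == "precursorList":
            plist = child
            break
    if plist is not None:
        iso = _find(plist, "isolationWindow")
        if iso is not None:
            ip = _cv_params(iso)
            lo = float(ip.get("MS:1000828", ("0",))[0] or 0)
            hi = float(ip.get("MS:1000829", ("0",))[0] or 0)
            if lo or hi:
                isolation_width = lo + hi
        si = _find(plist, "selectedIon")
        if si is not None:
            sip = _cv_params(si)
            if "MS:1000744" in sip:
                precursor_mz = float(sip["MS:1000744"][0])
    mz_arr, int_arr = _decode_binary_arrays(sp)
    if "MS:1000128" in params:  # profile spectrum
        warnings.warn(
            f"spectrum {scan_id!r} is profile mode; applying naive local-maxima "
            "centroiding",
            stacklevel=2,
        )
        mz_arr, int_arr = _naive_centroid(mz_arr, int_arr)
    return Spectrum(
        scan_id=scan_id,
        time=time,
        ms_level=ms_level,
        scan_function=classify_scan_function(ms_level, precursor_mz, isolation_width),
        mz=mz_arr,
        intensity=int_arr,
        precursor_mz=precursor_mz,
        isolation_width=isolation_width,
    )


def read_run(path: str) -> Run:
    """Read a centroided mzML file into a Run.

    Scan functions are inferred from ms level, presence of a selected
    precursor, and isolation-window width. Profile spectra trigger a warning
    and naive centroiding. Malformed XML raises ``lxml.etree.XMLSyntaxError``.
    """
    tree = etree.parse(path)
    root = tree.getroot()
    if _local(root.tag) == "indexedmzML":
        root = _find(root, "mzML") or root
    if _local(root.tag) != "mzML":
        raise ValueError(f"{path}: not an mzML document (root <{_local(root.tag)}>)")
    spectra = []
    for el in root.iter():
        if _local(el.tag) == "spectrum":
            spectra.append(_parse_spectrum(el))
    return Run(spectra=spectra, metadata={"source": path})


# ----------------------------------------------------------------------------
# chromatogram extraction


def extract_xic(
    run: Run,
    target_mz: float,
    ppm_tol: float,
    scan_function: Optional[str] = None,
) -> XIC:
    """Extracted ion chromatogram at ``target_mz`` ± ``ppm_tol`` (symmetric,
    computed on the target). Each contributing scan yields one point whose
    intensity is the sum of all peaks inside the window (0 when none)."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    half = target_mz * ppm_tol * 1e-6
    lo, hi = target_mz - half, target_mz + half
    times, intensities = [], []
    for s in run.select(scan_function):
        i0 = np.searchsorted(s.mz, lo, side="left")
        i1 = np.searchsorted(s.mz, hi, side="right")
        times.append(s.time)
        intensities.append(float(s.intensity[i0:i1].sum()))
    return XIC(
        target_mz=target_mz,
        ppm_tol=ppm_tol,
        times=np.asarray(times),
        intensities=np.asarray(intensities),
    )


def find_peaks(xic: XIC, min_intensity: float, min_points: int = 3) -> list[ChromPeak]:
    """Chromatographic peaks: maximal contiguous runs of XIC points with
    intensity >= ``min_intensity`` spanning >= ``min_points`` scans; the apex
    is the run maximum (earliest scan on ties). Deterministic."""
    peaks: list[ChromPeak] = []
    above = xic.intensities >= min_intensity
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= min_points:
            seg = xic.intensities[i:j]
            k = int(np.argmax(seg))
            peaks.append(
                ChromPeak(
                    apex_time=float(xic.times[i + k]),
                    apex_intensity=float(seg[k]),
                    start_time=float(xic.times[i]),
                    end_time=float(xic.times[j - 1]),
                )
            )
        i = j
    return peaks


def xic_to_tsv(xic: XIC, path: str) -> None:
    """Two-column TSV export (time_min, intensity)."""
    with open(path, "w") as fh:
        fh.write("time_min\tintensity\n")
        for t, y in zip(xic.times, xic.intensities):
            fh.write(f"{t:.6f}\t{y:.6f}\n")
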