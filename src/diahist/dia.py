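"""Cycle-structured model of a DIA run and its file formats.

A DIA run is a time-ordered sequence of acquisition cycles, each one MS1
survey spectrum followed by one MS2 spectrum per isolation window in a fixed
order.  This module reads centroided mzML/mzXML into that model, writes
standard mzML, and converts runs to the plain-text "ms1"/"ms2" dialect
(H header, ``S`` scan, ``I RTime``, ``Z`` charge lines, then m/z-intensity
pairs) consumed by EpiProfile-style targeted search tools.

The mzML/mzXML readers are deliberately narrow: centroided peak lists,
retention times, ms levels and isolation windows — the fields the quant
engine needs — parsed with lxml.  Profile-mode data is rejected.
"""

from __future__ import annotations

import base64
import gzip
import re
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np

from .chemistry import PROTON_MASS

__all__ = [
    "Spectrum",
    "DIARun",
    "read_dia_run",
    "write_mzml",
    "write_ms1_ms2",
    "read_ms1_ms2",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_MZXML_NS_RE = re.compile(r"\{[^}]*\}")


@dataclass
class Spectrum:
    """One centroided scan: peak arrays plus acquisition metadata."""

    scan: int
    ms_level: int
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float] | None = None
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(f"scan {self.scan}: mz/intensity length mismatch")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError(f"scan {self.scan}: m/z not strictly increasing")
        if self.rt_min < 0:
            raise ValueError(f"scan {self.scan}: negative retention time")
        if self.ms_level == 2 and self.window is None:
            raise ValueError(f"scan {self.scan}: MS2 scan without isolation window")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


class DIARun:
    """Ordered spectra with derived cycle structure.

    A cycle starts at each MS1 scan and contains the following MS2 window
    scans.  Window identity is keyed on (low, high) rounded to 2 decimals;
    every complete cycle must present the windows in the same order.
    """

    def __init__(self, spectra: Sequence[Spectrum], metadata: dict | None = None):
        self.spectra = list(spectra)
        self.metadata = dict(metadata or {})
        self._validate()
        self._ms1: list[Spectrum] | None = None
        self._by_window: dict[tuple[float, float], list[Spectrum]] | None = None

    def _validate(self) -> None:
        last_rt = -np.inf
        for s in self.spectra:
            if s.rt_min < last_rt - 1e-9:
                raise ValueError(f"retention time decreases at scan {s.scan}")
            last_rt = s.rt_min
            if s.ms_level == 2 and s.window is None:
                raise ValueError(f"MS2 scan {s.scan} lacks an isolation window")

    def __len__(self) -> int:
        return len(self.spectra)

    @staticmethod
    def _window_key(window: tuple[float, float]) -> tuple[float, float]:
        return (round(window[0], 2), round(window[1], 2))

    # -- cycle structure -------------------------------------------------
    @property
    def cycles(self) -> list[list[Spectrum]]:
        cycles: list[list[Spectrum]] = []
        for s in self.spectra:
            if s.ms_level == 1 or not cycles:
                cycles.append([])
            cycles[-1].append(s)
        return cycles

    @property
    def n_cycles(self) -> int:
        return sum(1 for s in self.spectra if s.ms_level == 1) or (
            1 if self.spectra else 0
        )

    def scheme_windows(self) -> list[tuple[float, float]]:
        """Isolation windows in acquisition order, from the first full cycle."""
        seen: dict[tuple[float, float], tuple[float, float]] = {}
        order: list[tuple[float, float]] = []
        for s in self.spectra:
            if s.ms_level != 2:
                continue
            key = self._window_key(s.window)
            if key not in seen:
                seen[key] = s.window
                order.append(s.window)
            elif order and self._window_key(order[0]) == key:
                break  # wrapped around to the first window again
        return order

    def ms1_spectra(self) -> list[Spectrum]:
        if self._ms1 is None:
            self._ms1 = [s for s in self.spectra if s.ms_level == 1]
        return self._ms1

    def ms2_spectra(self, window: tuple[float, float]) -> list[Spectrum]:
        """MS2 scans whose isolation window matches within 0.01 m/z."""
        if self._by_window is None:
            by: dict[tuple[float, float], list[Spectrum]] = {}
            for s in self.spectra:
                if s.ms_level == 2:
                    by.setdefault(self._window_key(s.window), []).append(s)
            self._by_window = by
        key = self._window_key(window)
        if key in self._by_window:
            return self._by_window[key]
        for (lo, hi), specs in self._by_window.items():
            if abs(lo - window[0]) <= 0.01 and abs(hi - window[1]) <= 0.01:
                return specs
        raise KeyError(f"no MS2 scans for isolation window {window}")

    def window_for(self, mz: float) -> tuple[float, float]:
        """The acquired window containing mz (center-closest in overlaps)."""
        hits = [w for w in self.scheme_windows() if w[0] <= mz <= w[1]]
        if not hits:
            raise KeyError(f"m/z {mz} not covered by any acquired window")
        return min(hits, key=lambda w: abs((w[0] + w[1]) / 2 - mz))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path) -> IO[bytes]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rb")
    return open(path, "rb")


def read_dia_run(path) -> DIARun:
    """Read a centroided mzML or mzXML file into a :class:`DIARun`."""
    name = Path(path).name.lower()
    stem = name[:-3] if name.endswith(".gz") else name
    if stem.endswith(".mzml"):
        spectra = list(_iter_mzml(path))
    elif stem.endswith(".mzxml"):
        spectra = list(_iter_mzxml(path))
    else:
        raise ValueError(f"unrecognized DIA file extension: {name}")
    return DIARun(spectra, metadata={"source": str(path)})


def _decode_binary(text: str, dtype: str, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_mzml(path) -> Iterator[Spectrum]:
    from lxml import etree

    tag = f"{{{_MZML_NS}}}spectrum"
    with _open_maybe_gzip(path) as fh:
        for _, elem in etree.iterparse(fh, events=("end",), tag=tag):
            yield _parse_mzml_spectrum(elem)
            elem.clear()
            parent = elem.getparent()
            if parent is not None:
                while elem.getprevious() is not None:
                    del parent[0]


def _cv_params(elem) -> dict[str, str]:
    out = {}
    for cv in elem.iter(f"{{{_MZML_NS}}}cvParam"):
        out[cv.get("accession")] = cv.get("value", "")
    return out


def _parse_mzml_spectrum(elem) -> Spectrum:
    ns = f"{{{_MZML_NS}}}"
    params = {
        cv.get("accession"): (cv.get("value", ""), cv)
        for cv in elem.findall(f"{ns}cvParam")
    }
    if "MS:1000128" in params:
        raise ValueError("profile-mode spectra are not supported; centroid first")
    ms_level = int(params.get("MS:1000511", ("1", None))[0])

    sid = elem.get("id", "")
    m = re.search(r"scan=(\d+)", sid)
    scan = int(m.group(1)) if m else int(elem.get("index", "0")) + 1

    rt_min = 0.0
    scan_el = elem.find(f"{ns}scanList/{ns}scan")
    if scan_el is not None:
        for cv in scan_el.findall(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                unit = (cv.get("unitName") or "").lower()
                rt_min = rt / 60.0 if unit.startswith("second") else rt

    window = None
    precursor = None
    prec_el = elem.find(f"{ns}precursorList/{ns}precursor")
    if prec_el is not None:
        iso = prec_el.find(f"{ns}isolationWindow")
        if iso is not None:
            p = _cv_params(iso)
            if "MS:1000827" in p:
                target = float(p["MS:1000827"])
                lo_off = float(p.get("MS:1000828", "nan"))
                hi_off = float(p.get("MS:1000829", "nan"))
                if np.isfinite(lo_off) and np.isfinite(hi_off):
                    window = (target - lo_off, target + hi_off)
                precursor = target
        sel = prec_el.find(f"{ns}selectedIonList/{ns}selectedIon")
        if sel is not None:
            p = _cv_params(sel)
            if "MS:1000744" in p:
                precursor = float(p["MS:1000744"])

    mz = np.array([])
    intensity = np.array([])
    for arr in elem.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
        p = _cv_params(arr)
        dtype = "<f4" if "MS:1000521" in p else "<f8"
        compressed = "MS:1000574" in p
        binary = arr.find(f"{ns}binary")
        text = binary.text or "" if binary is not None else ""
        values = _decode_binary(text, dtype, compressed) if text else np.array([])
        if "MS:1000514" in p:
            mz = values
        elif "MS:1000515" in p:
            intensity = values
    return Spectrum(
        scan=scan,
        ms_level=ms_level,
        rt_min=rt_min,
        mz=mz,
        intensity=intensity,
        window=window,
        precursor_mz=precursor,
    )


def _iter_mzxml(path) -> Iterator[Spectrum]:
    from lxml import etree

    with _open_maybe_gzip(path) as fh:
        for _, elem in etree.iterparse(fh, events=("end",)):
            if _MZXML_NS_RE.sub("", elem.tag) != "scan":
                continue
            yield _parse_mzxml_scan(elem)
            elem.clear()


def _parse_mzxml_scan(elem) -> Spectrum:
    def find(child_tag):
        for ch in elem:
            if _MZXML_NS_RE.sub("", ch.tag) == child_tag:
                return ch
        return None

    if (elem.get("centroided") or "1") in ("0", "false"):
        raise ValueError("profile-mode spectra are not supported; centroid first")
    scan = int(elem.get("num"))
    ms_level = int(elem.get("msLevel", "1"))
    rt_attr = elem.get("retentionTime", "PT0S")
    m = re.match(r"PT([0-9.eE+-]+)S", rt_attr)
    rt_min = float(m.group(1)) / 60.0 if m else float(rt_attr)

    window = None
    precursor = None
    prec = find("precursorMz")
    if prec is not None and prec.text:
        precursor = float(prec.text)
        wideness = prec.get("windowWideness")
        if wideness is not None:
            half = float(wideness) / 2.0
            window = (precursor - half, precursor + half)

    mz = np.array([])
    intensity = np.array([])
    peaks = find("peaks")
    if peaks is not None and peaks.text:
        raw = base64.b64decode(peaks.text)
        if (peaks.get("compressionType") or "none") == "zlib":
            raw = zlib.decompress(raw)
        precision = peaks.get("precision", "32")
        big_endian = (peaks.get("byteOrder") or "network") == "network"
        dtype = (">" if big_endian else "<") + ("f4" if precision == "32" else "f8")
        pairs = np.frombuffer(raw, dtype=dtype).astype(float)
        mz = pairs[0::2]
        intensity = pairs[1::2]
    return Spectrum(
        scan=scan,
        ms_level=ms_level,
        rt_min=rt_min,
        mz=mz,
        intensity=intensity,
        window=window,
        precursor_mz=precursor,
    )


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")


_MZML_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    f'<mzML xmlns="{_MZML_NS}" version="1.1.0">\n'
    '<cvList count="2">\n'
    '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
    'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
    '<cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>\n'
    "</cvList>\n"
    '<run id="run">\n'
)


def _mzml_spectrum_xml(s: Spectrum, index: int) -> str:
    mz_b64 = _b64(s.mz)
    int_b64 = _b64(s.intensity)
    parts = [
        f'<spectrum index="{index}" id="scan={s.scan}" defaultArrayLength="{s.n_peaks}">\n',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>\n',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n',
        '<scanList count="1"><scan>\n',
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt_min:.6f}" '
        'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n',
        "</scan></scanList>\n",
    ]
    if s.ms_level == 2:
        lo, hi = s.window
        target = s.precursor_mz if s.precursor_mz is not None else (lo + hi) / 2
        parts += [
            '<precursorList count="1"><precursor>\n<isolationWindow>\n',
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{target:.6f}"/>\n',
            f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{target - lo:.6f}"/>\n',
            f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{hi - target:.6f}"/>\n',
            "</isolationWindow>\n",
            '<selectedIonList count="1"><selectedIon>\n',
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{target:.6f}"/>\n',
            "</selectedIon></selectedIonList>\n<activation/>\n</precursor></precursorList>\n",
        ]
    parts.append('<binaryDataArrayList count="2">\n')
    for accession, name, b64 in (
        ("MS:1000514", "m/z array", mz_b64),
        ("MS:1000515", "intensity array", int_b64),
    ):
        parts += [
            f'<binaryDataArray encodedLength="{len(b64)}">\n',
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n',
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n',
            f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n',
            f"<binary>{b64}</binary>\n</binaryDataArray>\n",
        ]
    parts.append("</binaryDataArrayList>\n</spectrum>\n")
    return "".join(parts)


def write_mzml(run: DIARun, path) -> None:
    """Write the run as plain (non-indexed) mzML 1.1; gzip if path ends .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER)
        fh.write(f'<spectrumList count="{len(run.spectra)}">\n')
        for i, s in enumerate(run.spectra):
            fh.write(_mzml_spectrum_xml(s, i))
        fh.write("</spectrumList>\n</run>\n</mzML>\n")


# ---------------------------------------------------------------------------
# ms1/ms2 text dialect
# ---------------------------------------------------------------------------

_MS_HEADER_LINES = (
    "H\tExtractor\tdiahist\n"
    "H\tExtractorVersion\t0.1.0\n"
    "H\tComments\tconverted DIA run; RTime in minutes\n"
)


def write_ms1_ms2(run: DIARun, out_prefix, charges: tuple[int, ...] = (2, 3, 4)) -> tuple[Path, Path]:
    """Split a run into ``<prefix>.ms1`` and ``<prefix>.ms2`` text files.

    MS2 ``S`` records carry the isolation-window center as precursor m/z plus
    an ``I IsoWindow`` line with the exact bounds; since DIA has no assigned
    precursor charge, ``Z`` lines are emitted for every charge in the search
    space with the corresponding (M+H) value.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ms1_path = prefix.with_suffix(".ms1")
    ms2_path = prefix.with_suffix(".ms2")
    with open(ms1_path, "w") as f1, open(ms2_path, "w") as f2:
        f1.write(_MS_HEADER_LINES)
        f2.write(_MS_HEADER_LINES)
        for s in run.spectra:
            if s.ms_level == 1:
                f1.write(f"S\t{s.scan:06d}\t{s.scan:06d}\n")
                f1.write(f"I\tRTime\t{s.rt_min:.4f}\n")
                _write_peaks(f1, s)
            else:
                lo, hi = s.window
                center = s.precursor_mz if s.precursor_mz is not None else (lo + hi) / 2
                f2.write(f"S\t{s.scan:06d}\t{s.scan:06d}\t{center:.5f}\n")
                f2.write(f"I\tRTime\t{s.rt_min:.4f}\n")
                f2.write(f"I\tIsoWindow\t{lo:.5f} {hi:.5f}\n")
                for z in charges:
                    mh = center * z - (z - 1) * PROTON_MASS
                    f2.write(f"Z\t{z}\t{mh:.5f}\n")
                _write_peaks(f2, s)
    return ms1_path, ms2_path


def _write_peaks(fh, s: Spectrum) -> None:
    for mz, inten in zip(s.mz, s.intensity):
        fh.write(f"{mz:.5f} {inten:.4f}\n")


def read_ms1_ms2(out_prefix) -> DIARun:
    """Re-assemble a :class:`DIARun` from a ``.ms1``/``.ms2`` file pair.

    Uses the package's own line parser so that empty scans (an MS1 survey
    with no signal, a quiet DIA window) survive the round trip intact.
    """
    prefix = Path(out_prefix)
    spectra: list[Spectrum] = []
    ms1_path = prefix.with_suffix(".ms1")
    ms2_path = prefix.with_suffix(".ms2")
    if ms1_path.exists():
        for entry in _iter_ms_text(ms1_path):
            spectra.append(_spectrum_from_text(entry, ms_level=1))
    if ms2_path.exists():
        for entry in _iter_ms_text(ms2_path):
            spectra.append(_spectrum_from_text(entry, ms_level=2))
    spectra.sort(key=lambda s: s.scan)
    return DIARun(spectra, metadata={"source": str(prefix)})


def _iter_ms_text(path) -> Iterator[dict]:
    """Minimal ms1/ms2 dialect parser yielding pyteomics-style entries."""
    current: dict | None = None
    peaks_mz: list[float] = []
    peaks_int: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("H"):
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                for entry in _flush_entry(current, peaks_mz, peaks_int):
                    yield entry
                params: dict = {"scan": (fields[1], fields[2])}
                if len(fields) > 3:
                    params["precursor m/z"] = float(fields[3])
                current = {"params": params}
                peaks_mz, peaks_int = [], []
            elif fields[0] == "I" and current is not None:
                current["params"][fields[1]] = (
                    float(fields[2]) if fields[1] == "RTime" else fields[2]
                )
            elif fields[0] == "Z" and current is not None:
                current["params"].setdefault("charge", []).append(int(fields[1]))
                current["params"].setdefault("neutral mass", []).append(
                    float(fields[2])
                )
            elif current is not None:
                mz_s, int_s = line.split()
                peaks_mz.append(float(mz_s))
                peaks_int.append(float(int_s))
    for entry in _flush_entry(current, peaks_mz, peaks_int):
        yield entry


def _flush_entry(current, peaks_mz, peaks_int):
    if current is None:
        return
    current = dict(current)
    current["m/z array"] = np.array(peaks_mz)
    current["intensity array"] = np.array(peaks_int)
    yield current


def _spectrum_from_text(entry: dict, ms_level: int) -> Spectrum:
    params = entry["params"]
    scan = int(params["scan"][0])
    rt = float(params.get("RTime", 0.0))
    window = None
    precursor = None
    if ms_level == 2:
        precursor = float(params.get("precursor m/z", np.nan))
        iso = params.get("IsoWindow")
        if iso is not None:
            lo_s, hi_s = str(iso).split()
            window = (float(lo_s), float(hi_s))
        elif np.isfinite(precursor):
            window = (precursor, precursor)  # width unknown in bare ms2 files
    mz = np.asarray(entry["m/z array"], dtype=float)
    intensity = np.asarray(entry["intensity array"], dtype=float)
    if mz.size > 1:
        # peaks printed at fixed precision may collide; merge duplicates
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size < mz.size:
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, intensity)
            mz, intensity = uniq, summed
    return Spectrum(
        scan=scan,
        ms_level=ms_level,
        rt_min=rt,
        mz=mz,
        intensity=intensity,
        window=window,
        precursor_mz=precursor,
    )
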