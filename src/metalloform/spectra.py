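"""Spectrum container, mzML/peak-list I/O, centroiding, CSV tables.

mzML support is a compact self-contained reader/writer pair covering the
standard's common core: 32/64-bit float binary arrays, base64 encoding
with optional zlib compression, profile/centroid representation cvParams,
and the precursor-activation collision-energy cvParam.  Vendor exotica
(numpress compression, chromatograms, indexed wrappers beyond skipping the
index) are out of scope.
"""

from __future__ import annotations

import base64
import struct
import warnings
import xml.etree.ElementTree as _ET
import xml.sax.saxutils as _sax
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "read_mzml",
    "write_mzml",
    "read_peaklist",
    "write_peaklist",
    "centroid",
    "noise_level",
    "write_annotations",
    "read_annotations",
    "write_fragmap",
]

PROFILE = "profile"
CENTROID = "centroid"


@dataclass
class Spectrum:
    """One mass spectrum: parallel m/z and intensity arrays plus metadata.

    ``metadata`` keys used by the toolkit: ``label`` (str), ``collision_voltage``
    (V, float), ``charge_window`` ((lo, hi) m/z of quadrupole selection),
    ``polarity`` ('+'/'-').
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = CENTROID
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mode not in (PROFILE, CENTROID):
            raise ValueError(f"mode must be 'profile' or 'centroid', got {self.mode!r}")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        v = self.metadata.get("collision_voltage")
        if v is not None and v < 0:
            raise ValueError("collision voltage must be >= 0")

    def __len__(self) -> int:
        return self.mz.size

    def slice(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum restricted to [lo, hi] m/z."""
        sel = (self.mz >= lo) & (self.mz <= hi)
        return Spectrum(self.mz[sel], self.intensity[sel], self.mode, dict(self.metadata))

    def total_intensity(self, lo: float | None = None, hi: float | None = None) -> float:
        if lo is None and hi is None:
            return float(self.intensity.sum())
        sel = np.ones_like(self.mz, bool)
        if lo is not None:
            sel &= self.mz >= lo
        if hi is not None:
            sel &= self.mz <= hi
        return float(self.intensity[sel].sum())


# ---------------------------------------------------------------------------
# mzML


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    dtype = "<d"
    compressed = False
    payload = ""
    for child in elem:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f"
            elif acc == "MS:1000523":
                dtype = "<d"
            elif acc == "MS:1000574":
                compressed = True
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    itemsize = struct.calcsize(dtype)
    n = len(raw) // itemsize
    return np.asarray(struct.unpack(f"{dtype[0]}{n}{dtype[1]}", raw[: n * itemsize]), float)


def _parse_spectrum_element(elem, index: int) -> tuple[Spectrum, dict]:
    mode = CENTROID
    meta: dict = {"label": elem.get("id", f"scan={index}")}
    arrays: dict[str, np.ndarray] = {}
    raw_params: dict[str, str] = {}
    for node in elem.iter():
        name = _local(node.tag)
        if name == "cvParam":
            acc = node.get("accession", "")
            raw_params[acc] = node.get("value", "")
            if acc == "MS:1000128":
                mode = PROFILE
            elif acc == "MS:1000045":  # collision energy
                meta["collision_voltage"] = float(node.get("value", "0"))
        elif name == "binaryDataArray":
            kind = None
            for child in node:
                if _local(child.tag) == "cvParam":
                    if child.get("accession") == "MS:1000514":
                        kind = "mz"
                    elif child.get("accession") == "MS:1000515":
                        kind = "intensity"
            if kind:
                arrays[kind] = _decode_binary_array(node)
    mz = arrays.get("mz", np.array([]))
    inten = arrays.get("intensity", np.array([]))
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    keep = np.concatenate(([True], np.diff(mz) > 0)) if mz.size else np.array([], bool)
    return Spectrum(mz[keep], inten[keep], mode, meta), raw_params


def read_mzml(
    path: str | Path,
    selector: Callable[[int, dict], bool] | Sequence[int] | None = None,
) -> list[Spectrum]:
    """Read spectra from an mzML file (plain or indexed wrapper).

    ``selector`` is either a list of 0-based scan indices or a predicate
    ``f(index, cv_param_dict) -> bool``; ``None`` selects everything.  Mode
    is inferred from the spectrum-representation cvParam; a collision
    voltage is taken from the activation collision-energy cvParam when
    present.  A selector matching nothing returns an empty list with a
    warning; a malformed file raises with the scan index reached.
    """
    wanted: Callable[[int, dict], bool]
    if selector is None:
        wanted = lambda i, s: True  # noqa: E731
    elif callable(selector):
        wanted = selector
    else:
        indices = set(int(i) for i in selector)
        wanted = lambda i, s: i in indices  # noqa: E731

    out: list[Spectrum] = []
    index = -1
    try:
        for _, elem in _ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) != "spectrum":
                continue
            index += 1
            spectrum, raw_params = _parse_spectrum_element(elem, index)
            if wanted(index, raw_params):
                out.append(spectrum)
            elem.clear()
    except _ET.ParseError as exc:
        raise ValueError(
            f"malformed mzML {path} (after scan index {index}): {exc}"
        ) from exc
    if not out:
        warnings.warn(f"no scans selected from {path}", stacklevel=2)
    return out


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{arr.size}d", *np.asarray(arr, float))
    ).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(path: str | Path, spectra: Iterable[Spectrum]) -> None:
    """Write spectra to a minimal mzML file readable by pyteomics.

    64-bit little-endian, no compression.  Collision voltage (when present
    in metadata) is emitted as a precursor-activation collision-energy
    cvParam so it survives a round trip through :func:`read_mzml`.
    """
    spectra = list(spectra)
    chunks = [_MZML_HEADER.format(count=len(spectra))]
    for i, s in enumerate(spectra):
        mode_acc, mode_name = (
            ("MS:1000128", "profile spectrum")
            if s.mode == PROFILE
            else ("MS:1000127", "centroid spectrum")
        )
        sid = _sax.escape(str(s.metadata.get("label", f"scan={i}")), {'"': "&quot;"})
        mz64, in64 = _b64(s.mz), _b64(s.intensity)
        chunks.append(
            f'      <spectrum index="{i}" id="{sid}" defaultArrayLength="{len(s)}">\n'
            f'        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
        )
        v = s.metadata.get("collision_voltage")
        if v is not None:
            chunks.append(
                "        <precursorList count=\"1\">\n"
                "          <precursor>\n"
                "            <activation>\n"
                f'              <cvParam cvRef="MS" accession="MS:1000133" name="collision-induced dissociation"/>\n'
                f'              <cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="{float(v)}" unitName="electronvolt"/>\n'
                "            </activation>\n"
                "          </precursor>\n"
                "        </precursorList>\n"
            )
        chunks.append(
            '        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(mz64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" unitName="m/z"/>\n'
            f"            <binary>{mz64}</binary>\n"
            "          </binaryDataArray>\n"
            f'          <binaryDataArray encodedLength="{len(in64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" unitName="number of detector counts"/>\n'
            f"            <binary>{in64}</binary>\n"
            "          </binaryDataArray>\n"
            "        </binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    chunks.append(_MZML_FOOTER)
    Path(path).write_text("".join(chunks), encoding="utf-8")


# ---------------------------------------------------------------------------
# peak lists


def read_peaklist(path: str | Path, **metadata) -> Spectrum:
    """Read a two-column tab-separated peak list (m/z, intensity).

    Comment lines start with '#'; no header required (a header line is
    tolerated and skipped).  Returns a centroid-mode spectrum.
    """
    mzs: list[float] = []
    intens: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t")
        parts = [p for p in (q.strip() for q in parts) if p]
        try:
            m, i = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if lineno == 1:  # tolerated header
                continue
            raise ValueError(f"{path}:{lineno}: cannot parse peak line {line!r}")
        mzs.append(m)
        intens.append(i)
    order = np.argsort(mzs, kind="stable")
    mz = np.asarray(mzs, float)[order]
    inten = np.asarray(intens, float)[order]
    keep = np.concatenate(([True], np.diff(mz) > 0)) if mz.size else np.array([], bool)
    return Spectrum(mz[keep], inten[keep], CENTROID, dict(metadata))


def write_peaklist(path: str | Path, s: Spectrum) -> None:
    lines = ["# m/z\tintensity"]
    lines += [f"{float(m)!r}\t{float(i)!r}" for m, i in zip(s.mz, s.intensity)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# centroiding


def noise_level(intensity: np.ndarray) -> float:
    """Robust noise estimate: 1.4826 * MAD of the sub-median intensities."""
    intensity = np.asarray(intensity, float)
    low = intensity[intensity <= np.percentile(intensity, 50)]
    if low.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(low - np.median(low))))


def centroid(s: Spectrum, snr_min: float = 3.0, window: int = 0) -> Spectrum:
    """Peak-pick a profile spectrum into centroids.

    Local maxima above ``snr_min`` times the robust noise level are kept;
    each centroid is the intensity-weighted mean m/z over the peak's
    monotone flanks (optionally truncated to ``window`` points per side
    when ``window`` > 0).  Centroid intensity is the apex intensity.
    """
    if s.mode != PROFILE:
        raise ValueError("centroid() requires a profile-mode spectrum")
    y = s.intensity
    n = y.size
    if n < 3:
        return Spectrum(np.array([]), np.array([]), CENTROID, dict(s.metadata))
    sigma = noise_level(y)
    threshold = snr_min * sigma if sigma > 0 else 0.0
    cm: list[float] = []
    ci: list[float] = []
    for k in range(1, n - 1):
        if y[k] <= threshold or y[k] == 0:
            continue
        if not (y[k] > y[k - 1] and y[k] >= y[k + 1]):
            continue
        lo = k
        while lo > 0 and y[lo - 1] < y[lo] and (window <= 0 or k - lo < window):
            lo -= 1
        hi = k
        while hi < n - 1 and y[hi + 1] < y[hi] and (window <= 0 or hi - k < window):
            hi += 1
        seg = slice(lo, hi + 1)
        w = y[seg]
        cm.append(float(np.dot(s.mz[seg], w) / w.sum()))
        ci.append(float(y[k]))
    if not cm:
        return Spectrum(np.array([]), np.array([]), CENTROID, dict(s.metadata))
    order = np.argsort(cm, kind="stable")
    cm_arr = np.asarray(cm)[order]
    ci_arr = np.asarray(ci)[order]
    keep = np.concatenate(([True], np.diff(cm_arr) > 0))
    return Spectrum(cm_arr[keep], ci_arr[keep], CENTROID, dict(s.metadata))


# ---------------------------------------------------------------------------
# tables

#: Stable column schema of assignment tables written by the annotator.
ANNOTATION_COLUMNS = ["species", "z", "theo_mz", "score", "abundance", "group_id"]

#: Stable column schema of fragment-annotation tables.
FRAGMENT_COLUMNS = [
    "type", "index", "z", "adducts", "theo_mz", "obs_mz", "ppm", "intensity",
]


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation/fragment table as CSV (bit-exact round trip)."""
    table.to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fragmap(map_table: pd.DataFrame, path: str | Path) -> None:
    map_table.to_csv(path, index=False)
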