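"""LC-MS run input, extracted ion chromatograms and feature detection.

Runs are centroided mzML; profile-mode data is rejected because all
downstream pairing logic operates on centroid peaks.  The mzML parser
is a compact lxml one handling the format's core vocabulary (64/32-bit
base64 binary arrays, optional zlib compression, scan start time in
minutes or seconds, MS2 precursor linkage).  Retention times are
minutes everywhere, m/z tolerances are ppm.  MS/MS spectra can
additionally be read from a two-column text peak list with a
``precursor=<m/z> rt=<minutes>`` header line.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from scipy.signal import find_peaks

__all__ = [
    "Scan",
    "Run",
    "Feature",
    "MsmsSpectrum",
    "ProfileModeError",
    "read_run",
    "read_peaklist",
    "write_peaklist",
    "xic",
    "detect_features",
    "extract_features",
]


class ProfileModeError(ValueError):
    """Raised when an input run contains profile-mode spectra."""


@dataclass
class Scan:
    """One MS1 scan: retention time (minutes) and sorted centroids."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class MsmsSpectrum:
    """A product-ion spectrum keyed by its precursor m/z."""

    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class Run:
    """A time-ordered centroided LC-MS run."""

    scans: list[Scan]
    polarity: str = "positive"
    provenance: str = ""
    msms: list[MsmsSpectrum] = field(default_factory=list)

    def __post_init__(self):
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")
        self._index = None

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def rt_span(self) -> tuple[float, float]:
        return (self.scans[0].rt, self.scans[-1].rt) if self.scans else (0.0, 0.0)

    # Flat centroid index sorted by m/z: makes each XIC an O(log n + hits)
    # slice instead of a per-scan search.
    def _centroid_index(self):
        if self._index is None:
            if self.scans:
                mz = np.concatenate([s.mz for s in self.scans])
                inten = np.concatenate([s.intensity for s in self.scans])
                scan_idx = np.concatenate(
                    [np.full(s.mz.size, i, dtype=np.int64) for i, s in enumerate(self.scans)]
                )
                order = np.argsort(mz, kind="stable")
                self._index = (mz[order], inten[order], scan_idx[order])
            else:
                self._index = (np.empty(0), np.empty(0), np.empty(0, dtype=np.int64))
        return self._index


@dataclass
class Feature:
    """A chromatographic peak picked from an extracted ion chromatogram."""

    mz: float
    rt_apex: float
    area: float
    fwhm: float
    max_intensity: float
    rt_start: float = 0.0
    rt_end: float = 0.0
    snr: float = float("inf")


# ---------------------------------------------------------------------------
# input


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, str]:
    """accession -> value for every cvParam directly inside ``element``
    and its non-spectrum descendants."""
    out = {}
    for cv in element.iter():
        if _local(cv.tag) == "cvParam":
            out[cv.get("accession", cv.get("name", ""))] = cv.get("value", "")
    return out


def _decode_binary_arrays(spectrum_el, path: str) -> tuple[np.ndarray, np.ndarray]:
    mz = inten = None
    for arr in spectrum_el.iter():
        if _local(arr.tag) != "binaryDataArray":
            continue
        params = {
            cv.get("accession"): cv
            for cv in arr
            if _local(cv.tag) == "cvParam"
        }
        binary = next((c for c in arr if _local(c.tag) == "binary"), None)
        if binary is None:
            continue
        raw = base64.b64decode(binary.text or "")
        if "MS:1000574" in params:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = "<f4" if "MS:1000521" in params else "<f8"
        data = np.frombuffer(raw, dtype=dtype).astype(float)
        if "MS:1000514" in params:
            mz = data
        elif "MS:1000515" in params:
            inten = data
    if mz is None or inten is None:
        raise ValueError(f"{path}: spectrum without m/z or intensity array")
    return mz, inten


def _scan_rt_minutes(spectrum_el) -> float:
    for cv in spectrum_el.iter():
        if _local(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000016":
            rt = float(cv.get("value"))
            unit = (cv.get("unitName") or cv.get("unitAccession") or "").lower()
            if "second" in unit or unit == "uo:0000010":
                rt /= 60.0
            return rt
    return 0.0


def _precursor_mz(spectrum_el) -> float:
    for cv in spectrum_el.iter():
        if _local(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000744":
            return float(cv.get("value"))
    raise ValueError("MS2 spectrum without selected ion m/z")


def read_run(path, provenance: str = "") -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    MS2 spectra are routed to ``run.msms``.  Profile-mode spectra raise
    :class:`ProfileModeError`; malformed XML raises ``ValueError``
    carrying the XML parser's reported position.
    """
    path = str(path)
    scans: list[Scan] = []
    msms: list[MsmsSpectrum] = []
    polarity = "positive"
    try:
        context = etree.iterparse(path, events=("end",))
        for _, el in context:
            if _local(el.tag) != "spectrum":
                continue
            params = _cv_params(el)
            if "MS:1000128" in params:
                raise ProfileModeError(
                    f"{path}: profile-mode spectrum {el.get('id')!r}; "
                    "centroid the data first"
                )
            if "MS:1000129" in params:
                polarity = "negative"
            ms_level = int(params.get("MS:1000511", "1") or "1")
            rt = _scan_rt_minutes(el)
            mz, inten = _decode_binary_arrays(el, path)
            if ms_level >= 2:
                msms.append(
                    MsmsSpectrum(
                        precursor_mz=_precursor_mz(el), rt=rt, mz=mz, intensity=inten
                    )
                )
            else:
                scans.append(Scan(rt=rt, mz=mz, intensity=inten))
            el.clear(keep_tail=True)
    except ProfileModeError:
        raise
    except etree.XMLSyntaxError as exc:  # includes line/column position
        raise ValueError(f"failed to parse mzML {path}: {exc}") from exc
    if not scans and not msms:
        raise ValueError(f"{path}: run contains no spectra")
    scans.sort(key=lambda s: s.rt)
    return Run(scans=scans, polarity=polarity, provenance=provenance, msms=msms)


def read_peaklist(path) -> MsmsSpectrum:
    """Read an MS/MS spectrum from a two-column text peak list.

    Format: header line ``precursor=<m/z> rt=<minutes>`` followed by
    ``m/z<TAB>intensity`` lines.
    """
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty peak list")
    header = dict(
        kv.split("=", 1) for kv in lines[0].replace("\t", " ").split() if "=" in kv
    )
    if "precursor" not in header:
        raise ValueError(f"{path}: header must contain precursor=<m/z>")
    mzs, intens = [], []
    for line in lines[1:]:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        mzs.append(float(parts[0]))
        intens.append(float(parts[1]))
    return MsmsSpectrum(
        precursor_mz=float(header["precursor"]),
        rt=float(header.get("rt", 0.0)),
        mz=np.array(mzs),
        intensity=np.array(intens),
    )


def write_peaklist(spectrum: MsmsSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"precursor={spectrum.precursor_mz:.4f} rt={spectrum.rt:.4f}\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.6f}\t{i:.4f}\n")


# ---------------------------------------------------------------------------
# chromatograms


def xic(run: Run, target_mz: float, tol_ppm: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Extracted ion chromatogram: per-scan summed intensity within
    +/-``tol_ppm`` of ``target_mz`` (zero where nothing matches)."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = tol_ppm * 1e-6 * target_mz
    mz, inten, scan_idx = run._centroid_index()
    lo = np.searchsorted(mz, target_mz - half, side="left")
    hi = np.searchsorted(mz, target_mz + half, side="right")
    trace = np.zeros(len(run.scans))
    if hi > lo:
        np.add.at(trace, scan_idx[lo:hi], inten[lo:hi])
    return run.rts, trace


def detect_features(
    rts: np.ndarray,
    trace: np.ndarray,
    min_sn: float = 3.0,
    min_run_scans: int = 5,
) -> list[Feature]:
    """Pick chromatographic peaks from an XIC trace.

    Noise is the scaled median absolute deviation of the trace; peaks
    must clear the baseline by ``min_sn`` x noise in both height and
    prominence, and must persist: at least ``min_run_scans`` consecutive
    scans around the apex above baseline + (2/3) min_sn x noise.  White
    noise practically never sustains such a run, while any
    chromatographic peak sampled at a sane acquisition rate does —
    this is what rejects single-scan spikes and noise excursions.  The
    apex is refined by parabolic interpolation, the area is the
    trapezoidal integral of the contiguous above-baseline region, and
    peaks closer than one FWHM are merged (the taller survives).
    """
    rts = np.asarray(rts, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if rts.size < 5:
        raise ValueError("trace must span at least 5 scans")
    baseline = float(np.median(trace))
    sigma = 1.4826 * float(np.median(np.abs(trace - baseline)))
    ymax = float(trace.max(initial=0.0))
    if ymax <= baseline:
        return []
    eps = 1e-12 + 1e-9 * ymax
    height = max(baseline + min_sn * sigma, baseline + eps)
    prominence = max(min_sn * sigma, eps)
    idx, _ = find_peaks(trace, height=height, prominence=prominence, width=2)
    if idx.size == 0:
        return []

    # persistence gate: a run of min_run_scans consecutive scans above
    # baseline + (2/3) min_sn sigma containing the apex
    run_level = baseline + (2.0 / 3.0) * min_sn * sigma + eps
    n_pts = trace.size

    def _persists(p: int) -> bool:
        l = p
        while l > 0 and trace[l - 1] > run_level:
            l -= 1
        r = p
        while r < n_pts - 1 and trace[r + 1] > run_level:
            r += 1
        return r - l + 1 >= min_run_scans

    idx = np.array([p for p in idx if _persists(p)], dtype=int)
    if idx.size == 0:
        return []

    feats: list[Feature] = []
    n = trace.size
    for p in idx:
        apex_rt, apex_y = rts[p], trace[p]
        if 0 < p < n - 1:
            y0, y1, y2 = trace[p - 1 : p + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                shift = 0.5 * (y0 - y2) / denom
                shift = float(np.clip(shift, -0.5, 0.5))
                apex_rt = rts[p] + shift * (rts[min(p + 1, n - 1)] - rts[max(p - 1, 0)]) / 2
                apex_y = y1 - 0.25 * (y0 - y2) * shift
        stop = max(baseline + 0.5 * sigma, baseline + 1e-3 * (apex_y - baseline))

        def walk(start: int, step: int) -> int:
            # extend over the descending flank; tolerate point noise by
            # tracking the running minimum and stopping only on a clear
            # rise out of a valley (the next peak)
            i = start
            run_min = trace[start]
            while 0 < i < n - 1 or (i == 0 and step < 0) or (i == n - 1 and step > 0):
                j = i + step
                if j < 0 or j > n - 1:
                    break
                y = trace[j]
                if y <= stop:
                    break
                if y > 1.5 * (run_min - baseline) + baseline + 3 * sigma + eps:
                    break
                i = j
                run_min = min(run_min, y)
            return i

        left = walk(p, -1)
        right = walk(p, +1)
        seg = np.clip(trace[left : right + 1] - baseline, 0.0, None)
        area = float(np.trapezoid(seg, rts[left : right + 1]))
        if area <= 0:
            continue
        half_level = baseline + 0.5 * (apex_y - baseline)
        fwhm = _fwhm(rts, trace, p, left, right, half_level)
        feats.append(
            Feature(
                mz=float("nan"),
                rt_apex=float(apex_rt),
                area=area,
                fwhm=fwhm,
                max_intensity=float(apex_y),
                rt_start=float(rts[left]),
                rt_end=float(rts[right]),
                snr=(apex_y - baseline) / sigma if sigma > 0 else float("inf"),
            )
        )

    # merge peaks closer than one FWHM: keep the taller
    feats.sort(key=lambda f: -f.max_intensity)
    kept: list[Feature] = []
    for f in feats:
        if all(abs(f.rt_apex - k.rt_apex) > max(f.fwhm, k.fwhm) for k in kept):
            kept.append(f)
    kept.sort(key=lambda f: f.rt_apex)
    return kept


def _fwhm(rts, trace, p, left, right, half_level) -> float:
    def cross(i, j):
        # linear interpolation of the half-level crossing between scans i, j
        y0, y1 = trace[i], trace[j]
        if y1 == y0:
            return rts[j]
        t = (half_level - y0) / (y1 - y0)
        return rts[i] + t * (rts[j] - rts[i])

    lo = rts[left]
    for i in range(p, left, -1):
        if trace[i - 1] < half_level <= trace[i]:
            lo = cross(i - 1, i)
            break
    hi = rts[right]
    for i in range(p, right):
        if trace[i + 1] < half_level <= trace[i]:
            hi = cross(i + 1, i)
            break
    width = float(hi - lo)
    if width <= 0:
        width = float(rts[min(p + 1, len(rts) - 1)] - rts[max(p - 1, 0)]) / 2
    return width


def extract_features(
    run: Run,
    target_mz: float,
    tol_ppm: float = 5.0,
    min_sn: float = 3.0,
) -> list[Feature]:
    """XIC + feature detection at one m/z, with the intensity-weighted
    mean centroid m/z filled in over each feature's RT span."""
    rts, trace = xic(run, target_mz, tol_ppm)
    if rts.size < 5:
        return []
    feats = detect_features(rts, trace, min_sn=min_sn)
    if not feats:
        return feats
    half = tol_ppm * 1e-6 * target_mz
    mz, inten, scan_idx = run._centroid_index()
    lo = np.searchsorted(mz, target_mz - half, side="left")
    hi = np.searchsorted(mz, target_mz + half, side="right")
    sel_mz, sel_int, sel_scan = mz[lo:hi], inten[lo:hi], scan_idx[lo:hi]
    scan_rts = run.rts
    for f in feats:
        mask = (scan_rts[sel_scan] >= f.rt_start) & (scan_rts[sel_scan] <= f.rt_end)
        w = sel_int[mask]
        f.mz = float(np.average(sel_mz[mask], weights=w)) if w.sum() > 0 else target_mz
    return feats
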