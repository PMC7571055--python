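"""Peak-list and profile-spectrum I/O, peak detection and mass calibration.

Input formats are deliberately minimal: two- or three-column delimited text
(m/z in Da, intensity, optional signal-to-noise), either as a sparse peak
list or as a densely sampled raw profile. Masses are treated as singly
charged [M+H]+ ~ M; at 60-110 kDa the proton is far below measurement error
and no charge deconvolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks as _find_local_maxima

from .errors import CalibrationError, ParseError, ValidationError
from .reference import ACQUISITION_RANGE

#: Average mass of the external calibration standard (bovine serum albumin).
BSA_MASS = 66_463.0


@dataclass(frozen=True)
class Peak:
    mass: float
    intensity: float
    snr: float | None = None


@dataclass
class PeakList:
    """Sparse (mass, intensity[, snr]) peaks for one acquisition."""

    peaks: list[Peak]
    sample_id: str = ""
    replicate_id: str = ""
    calibrated: bool = False

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mass)
        masses = self.masses
        if np.any(np.diff(masses) <= 0):
            raise ValidationError("peak masses must be strictly increasing")

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ProfileSpectrum:
    """Densely sampled (m/z, intensity) trace."""

    mz: np.ndarray
    intensity: np.ndarray
    acquisition_range: tuple[float, float] = ACQUISITION_RANGE

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValidationError("mz and intensity must be 1-D and equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValidationError("m/z values must be strictly increasing")


@dataclass(frozen=True)
class CalibrationModel:
    kind: str                      # "one-point" | "two-point"
    scale: float
    offset: float = 0.0
    reference: tuple[str, float] = ("BSA", BSA_MASS)


def _split_line(line: str) -> list[str]:
    for sep in ("\t", ",", ";"):
        if sep in line:
            return [f.strip() for f in line.split(sep)]
    return line.split()


def _read_columns(path, dialect=None) -> list[tuple[int, list[float]]]:
    path = Path(path)
    rows: list[tuple[int, list[float]]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = (line.split(",") if dialect == "csv"
                      else line.split("\t") if dialect == "tsv"
                      else _split_line(line))
            fields = [f.strip() for f in fields if f.strip() != ""]
            try:
                values = [float(f) for f in fields]
            except ValueError:
                if not rows and not header_seen:
                    header_seen = True  # tolerate one leading header line
                    continue
                raise ParseError("non-numeric cell", file=str(path),
                                 line=lineno) from None
            if len(values) not in (2, 3):
                raise ParseError(f"expected 2 or 3 columns, got {len(values)}",
                                 file=str(path), line=lineno)
            rows.append((lineno, values))
    if not rows:
        raise ValidationError(f"no data rows in {path}")
    return rows


def read_peaklist(path, dialect: str | None = None,
                  sample_id: str | None = None) -> PeakList:
    """Read a delimited peak list (mass, intensity[, snr]); returns sorted,
    deduplicated peaks with ``calibrated=False``.

    Duplicate masses keep the row with the highest intensity.
    """
    rows = _read_columns(path, dialect)
    best: dict[float, Peak] = {}
    for _, vals in rows:
        mass, intensity = vals[0], vals[1]
        snr = vals[2] if len(vals) == 3 else None
        prior = best.get(mass)
        if prior is None or intensity > prior.intensity:
            best[mass] = Peak(mass, intensity, snr)
    sid = sample_id if sample_id is not None else Path(path).stem
    return PeakList(peaks=list(best.values()), sample_id=sid, calibrated=False)


def write_peaklist(peaklist: PeakList, path) -> None:
    """Canonical TSV output: ``mass_da  intensity  snr`` sorted by mass."""
    with open(path, "w") as fh:
        fh.write("mass_da\tintensity\tsnr\n")
        for p in peaklist.peaks:
            snr = "" if p.snr is None else f"{p.snr:.3f}"
            fh.write(f"{p.mass:.3f}\t{p.intensity:.3f}\t{snr}\n")


def read_profile(path, dialect: str | None = None,
                 acquisition_range=ACQUISITION_RANGE) -> ProfileSpectrum:
    rows = _read_columns(path, dialect)
    arr = np.array([v[:2] for _, v in rows], dtype=float)
    order = np.argsort(arr[:, 0])
    return ProfileSpectrum(arr[order, 0], arr[order, 1], acquisition_range)


def detect_peaks(spectrum: ProfileSpectrum, min_snr: float = 6.0,
                 min_spacing_da: float = 400.0,
                 smooth_window_da: float = 60.0) -> PeakList:
    """Pick peaks from a raw profile trace.

    The trace is smoothed with a moving average of width
    ``smooth_window_da``; candidate peaks are local maxima of the smoothed
    trace. Noise is estimated as the median absolute deviation of the
    baseline-subtracted smoothed trace scaled to a Gaussian SD (x1.4826),
    with the baseline taken as the trace median. Candidates below
    ``min_snr`` are dropped, no two kept peaks lie closer than
    ``min_spacing_da`` (the higher one wins), and the reported mass is the
    intensity-weighted centroid over the half-height region.
    """
    if min_snr <= 0 or min_spacing_da <= 0 or smooth_window_da <= 0:
        raise ValidationError("peak-picking parameters must be positive")
    mz, inten = spectrum.mz, spectrum.intensity
    if mz.size < 50:
        raise ValidationError(f"profile too sparse ({mz.size} points, need >= 50)")
    step = float(np.median(np.diff(mz)))
    width = max(1, int(round(smooth_window_da / step)))
    if width % 2 == 0:
        width += 1   # odd width keeps the moving average phase-neutral
    smooth = uniform_filter1d(inten, size=width, mode="nearest")
    baseline = float(np.median(smooth))
    resid = smooth - baseline
    noise = 1.4826 * float(np.median(np.abs(resid)))
    noise = max(noise, 1e-12)

    # prominence keeps noise ripple riding on another peak's tail from
    # registering as a peak of its own
    idx, _ = _find_local_maxima(smooth, prominence=min_snr * noise)
    idx = [i for i in idx if resid[i] / noise >= min_snr]
    # enforce minimum spacing, highest apex first
    kept: list[int] = []
    for i in sorted(idx, key=lambda i: smooth[i], reverse=True):
        if all(abs(mz[i] - mz[j]) >= min_spacing_da for j in kept):
            kept.append(i)

    peaks = []
    for i in kept:
        half = resid[i] / 2.0
        # walk down each flank to the half height; rises above the noise
        # ripple mean another peak's flank, which bounds the region
        rise = 3.0 * noise
        lo = i
        while lo > 0 and half <= resid[lo - 1] <= resid[lo] + rise:
            lo -= 1
        hi = i
        while hi < len(mz) - 1 and half <= resid[hi + 1] <= resid[hi] + rise:
            hi += 1
        w = np.clip(resid[lo:hi + 1], 0.0, None)
        if w.sum() <= 0:
            centroid = float(mz[i])
        else:
            centroid = float(np.sum(mz[lo:hi + 1] * w) / np.sum(w))
        peaks.append(Peak(mass=centroid, intensity=float(smooth[i]),
                          snr=float(resid[i] / noise)))
    # spacing filter guarantees distinct masses; keep construction safe anyway
    uniq: dict[float, Peak] = {}
    for p in peaks:
        if p.mass not in uniq or p.intensity > uniq[p.mass].intensity:
            uniq[p.mass] = p
    return PeakList(peaks=list(uniq.values()), calibrated=False)


def calibrate(peaklist: PeakList, observed_standard: float,
              true_standard: float = BSA_MASS,
              standard_name: str = "BSA") -> tuple[PeakList, CalibrationModel]:
    """One-point multiplicative mass calibration against an external
    standard (default BSA, 66,463 Da).

    Every peak mass is multiplied by ``true/observed``. Scales outside
    [0.95, 1.05] are rejected as implausible.
    """
    if observed_standard <= 0:
        raise ValidationError("observed standard mass must be positive")
    scale = true_standard / observed_standard
    if not 0.95 <= scale <= 1.05:
        raise CalibrationError(
            f"calibration scale {scale:.4f} outside [0.95, 1.05]")
    model = CalibrationModel(kind="one-point", scale=scale,
                             reference=(standard_name, true_standard))
    peaks = [replace(p, mass=p.mass * scale) for p in peaklist.peaks]
    out = PeakList(peaks=peaks, sample_id=peaklist.sample_id,
                   replicate_id=peaklist.replicate_id, calibrated=True)
    return out, model


def calibrate_two_point(peaklist: PeakList,
                        observed: Sequence[float],
                        true: Sequence[float]) -> tuple[PeakList, CalibrationModel]:
    """Two-point linear calibration ``m' = scale * m + offset``."""
    (o1, o2), (t1, t2) = observed, true
    if o1 == o2:
        raise ValidationError("two-point calibration needs distinct standards")
    scale = (t2 - t1) / (o2 - o1)
    offset = t1 - scale * o1
    if not 0.95 <= scale <= 1.05:
        raise CalibrationError(
            f"calibration scale {scale:.4f} outside [0.95, 1.05]")
    model = CalibrationModel(kind="two-point", scale=scale, offset=offset,
                             reference=("two-point", t1))
    peaks = [replace(p, mass=p.mass * scale + offset) for p in peaklist.peaks]
    out = PeakList(peaks=peaks, sample_id=peaklist.sample_id,
                   replicate_id=peaklist.replicate_id, calibrated=True)
    return out, model
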