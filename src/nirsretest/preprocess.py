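"""Preprocessing chain for raw CW-fNIRS intensities.

Stage order is fixed: SNR-based channel pruning -> optical density ->
spline motion correction -> wavelet motion correction -> Beer-Lambert
inversion to hemoglobin concentrations -> zero-phase bandpass.  Each
stage records its parameters in the output's ``log`` so a processed
recording carries its own provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from scipy.interpolate import make_smoothing_spline

from .extinction import extinction_matrix
from .probe import ProbeLayout
from .synth import DPF, RawRecording, StimSchedule

__all__ = [
    "ODRecording", "HbRecording", "PreprocessParams",
    "compute_snr", "prune_channels", "intensity_to_od",
    "spline_correct", "wavelet_correct", "od_to_hb", "bandpass",
    "preprocess_recording",
]


class EmptyRecordingError(RuntimeError):
    """All channels were pruned; nothing left to analyse."""


@dataclass
class ODRecording:
    """Optical-density recording (channel x wavelength x time)."""

    od: np.ndarray
    fs: float
    probe: ProbeLayout
    schedule: StimSchedule
    channel_idx: np.ndarray            # indices into probe.channels
    pruned: dict[int, str] = field(default_factory=dict)  # channel -> reason
    meta: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


@dataclass
class HbRecording:
    """Hemoglobin concentration changes, uM (channel x time)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    probe: ProbeLayout
    schedule: StimSchedule
    channel_idx: np.ndarray
    pruned: dict[int, str] = field(default_factory=dict)
    band: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def series(self, channel: int, chromophore: str) -> np.ndarray:
        """Time series of one probe channel by its probe index."""
        pos = np.where(self.channel_idx == channel)[0]
        if len(pos) == 0:
            raise KeyError(f"channel {channel} not present (pruned?)")
        arr = self.hbo if chromophore == "hbo" else self.hbr
        return arr[pos[0]]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable parameters of the preprocessing chain."""

    snr_threshold: float = 8.0
    # spline (MARA-style) motion correction
    motion_window: float = 1.0       # s
    motion_sd_mult: float = 13.5     # multiples of the baseline diff noise
    motion_amp_thresh: float = 0.2   # OD
    spline_lam: float | None = None  # smoothing penalty; None -> auto (GCV)
    # wavelet correction
    wavelet: str = "db2"
    wavelet_level: int | None = None  # None -> depth keeping details above ~0.03 Hz
    wavelet_alpha: float = 1.5        # IQR fence multiplier
    # Beer-Lambert
    dpf: float = 6.0
    # bandpass
    band_low: float = 0.005          # Hz
    band_high: float = 0.5           # Hz
    filter_order: int = 3


def compute_snr(raw: RawRecording) -> np.ndarray:
    """Per-channel, per-wavelength SNR = mean / population SD of intensity."""
    if raw.n_times < 2:
        raise ValueError("need at least 2 time points for SNR")
    mean = raw.intensity.mean(axis=2)
    sd = raw.intensity.std(axis=2)  # population SD
    with np.errstate(divide="ignore"):
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    return snr


def prune_channels(raw: RawRecording, threshold: float = 8.0
                   ) -> tuple[np.ndarray, dict[int, str]]:
    """Indices of channels to keep, and removal reasons for the rest.

    A channel is removed iff SNR < threshold at either wavelength
    (strict inequality: SNR exactly at the threshold is kept).
    """
    snr = compute_snr(raw)
    bad = (snr < threshold).any(axis=1)
    keep = np.where(~bad)[0]
    pruned = {
        int(i): (f"SNR {snr[i, 0]:.2f}/{snr[i, 1]:.2f} < {threshold:g}")
        for i in np.where(bad)[0]
    }
    return keep, pruned


def intensity_to_od(raw: RawRecording, threshold: float = 8.0,
                    prune: bool = True) -> ODRecording:
    """Convert intensity to optical density, pruning low-SNR channels.

    dOD(t) = -log10(I(t) / mean(I)), per channel and wavelength; the
    reference I0 is the mean intensity over the full recording.
    """
    if prune:
        keep, pruned = prune_channels(raw, threshold)
    else:
        keep, pruned = np.arange(raw.n_channels), {}
    if len(keep) == 0:
        raise EmptyRecordingError("all channels pruned by the SNR criterion")
    inten = raw.intensity[keep]
    if np.any(inten <= 0):
        ch, wl, tt = np.argwhere(inten <= 0)[0]
        raise ValueError(
            f"non-positive intensity at channel {int(keep[ch])}, "
            f"wavelength index {int(wl)}, sample {int(tt)}")
    od = -np.log10(inten / inten.mean(axis=2, keepdims=True))
    return ODRecording(
        od=od, fs=raw.fs, probe=raw.probe, schedule=raw.schedule,
        channel_idx=keep, pruned=pruned, meta=dict(raw.meta),
        log=[("prune", {"threshold": threshold, "removed": sorted(pruned)}),
             ("od", {"reference": "mean"})],
    )


def _motion_flags(x: np.ndarray, fs: float, window: float,
                  sd_mult: float, amp_thresh: float) -> np.ndarray:
    """Boolean mask of samples inside a detected motion segment.

    A window is flagged when its peak-to-peak excursion exceeds either
    ``amp_thresh`` (absolute OD) or ``sd_mult`` times the baseline noise
    level, estimated robustly from the first differences.
    """
    n = len(x)
    w = int(round(window * fs))
    if w < 2:
        w = 2
    if w > n:
        raise ValueError("motion-detection window longer than the recording")
    d = np.diff(x)
    # robust point-noise scale: MAD of the first differences / sqrt(2)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    thresh = max(sd_mult * sigma, 1e-300)
    # peak-to-peak over a sliding window
    from scipy.ndimage import maximum_filter1d, minimum_filter1d
    ptp = maximum_filter1d(x, w) - minimum_filter1d(x, w)
    flagged = (ptp > thresh) | (ptp > amp_thresh)
    # expand by half a window so segment edges are included
    flagged = maximum_filter1d(flagged.astype(np.uint8), w).astype(bool)
    return flagged


def _segments(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Contiguous runs of (start, stop, flagged)."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        out.append((i, j, bool(mask[i])))
        i = j
    return out


def _spline_correct_1d(x: np.ndarray, fs: float, p: PreprocessParams
                       ) -> np.ndarray:
    flags = _motion_flags(x, fs, p.motion_window, p.motion_sd_mult,
                          p.motion_amp_thresh)
    if not flags.any():
        return x.copy()
    segs = _segments(flags)
    y = x.copy()
    m = max(2, int(round(p.motion_window * fs)))  # realignment support
    for i0, i1, flagged in segs:
        if flagged:
            t = np.arange(i0, i1) / fs
            seg = x[i0:i1]
            if i1 - i0 >= 4:
                lam = p.spline_lam
                fit = make_smoothing_spline(t, seg, lam=lam)(t)
            else:
                fit = np.full(i1 - i0, seg.mean())
            y[i0:i1] = seg - fit
        # realign this segment's level to the preceding one
        if i0 > 0:
            prev = y[max(0, i0 - m):i0]
            cur = y[i0:min(len(y), i0 + m)]
            y[i0:] += prev.mean() - cur.mean()
    return y


def spline_correct(od: ODRecording, params: PreprocessParams = PreprocessParams()
                   ) -> ODRecording:
    """MARA-style spline motion correction, per channel and wavelength.

    Motion segments are replaced by their residual around a smoothing
    spline; every following segment is re-levelled to keep the trace
    continuous, which also removes persistent baseline shifts.
    Artifact-free traces pass through unchanged.
    """
    out = np.empty_like(od.od)
    for i in range(od.od.shape[0]):
        for j in range(od.od.shape[1]):
            out[i, j] = _spline_correct_1d(od.od[i, j], od.fs, params)
    rec = ODRecording(
        od=out, fs=od.fs, probe=od.probe, schedule=od.schedule,
        channel_idx=od.channel_idx, pruned=dict(od.pruned),
        meta=dict(od.meta), log=list(od.log))
    rec.log.append(("spline", {
        "window": params.motion_window, "sd_mult": params.motion_sd_mult,
        "amp_thresh": params.motion_amp_thresh}))
    return rec


def _wavelet_correct_1d(x: np.ndarray, wavelet: str, level: int,
                        alpha: float) -> np.ndarray:
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    for k in range(1, len(coeffs)):
        c = coeffs[k]
        q1, q3 = np.percentile(c, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - alpha * iqr, q3 + alpha * iqr
        coeffs[k] = np.where((c < lo) | (c > hi), 0.0, c)
    rec = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return rec[: len(x)]


def wavelet_correct(od: ODRecording, params: PreprocessParams = PreprocessParams()
                    ) -> ODRecording:
    """Wavelet motion correction: zero detail coefficients outside an
    IQR fence, per decomposition level.

    The default depth leaves untouched the approximation band below
    ~0.03 Hz, so slow hemodynamics and drifts are never thresholded and
    narrow transients (which spread across many detail scales) are
    suppressed.
    """
    n = od.od.shape[2]
    wav = pywt.Wavelet(params.wavelet)
    if n < wav.dec_len:
        raise ValueError("recording shorter than one wavelet filter length")
    max_level = pywt.dwt_max_level(n, wav.dec_len)
    if params.wavelet_level is not None:
        level = min(params.wavelet_level, max_level)
    else:
        # deepest detail band [fs/2^(L+1), fs/2^L] stays above ~0.03 Hz
        level = max(1, min(max_level, int(np.floor(np.log2(od.fs / 0.06)))))
    out = np.empty_like(od.od)
    for i in range(od.od.shape[0]):
        for j in range(od.od.shape[1]):
            out[i, j] = _wavelet_correct_1d(
                od.od[i, j], params.wavelet, level, params.wavelet_alpha)
    rec = ODRecording(
        od=out, fs=od.fs, probe=od.probe, schedule=od.schedule,
        channel_idx=od.channel_idx, pruned=dict(od.pruned),
        meta=dict(od.meta), log=list(od.log))
    rec.log.append(("wavelet", {
        "wavelet": params.wavelet, "level": level,
        "alpha": params.wavelet_alpha}))
    return rec


def od_to_hb(od: ODRecording, dpf: float = DPF,
             extinction: np.ndarray | None = None) -> HbRecording:
    """Invert the modified Beer-Lambert law per channel and time point.

    dOD_lambda = (eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR) * d * DPF
    with d the source-detector separation in cm and concentrations in
    uM; solved with the shared 2x2 extinction matrix.
    """
    ext = extinction if extinction is not None else extinction_matrix(
        od.probe.wavelengths)
    if abs(np.linalg.det(ext)) < 1e-16:
        raise ValueError("extinction matrix is singular")
    seps = od.probe.separations[od.channel_idx]
    if np.any(~np.isfinite(seps)) or np.any(seps <= 0):
        raise ValueError("missing or invalid source-detector separation")
    inv = np.linalg.inv(ext)
    conc = np.einsum("cw,nwt->nct", inv, od.od) / (
        seps[:, None, None] * dpf)
    rec = HbRecording(
        hbo=conc[:, 0], hbr=conc[:, 1], fs=od.fs, probe=od.probe,
        schedule=od.schedule, channel_idx=od.channel_idx,
        pruned=dict(od.pruned), meta=dict(od.meta), log=list(od.log))
    rec.log.append(("mbll", {"dpf": dpf}))
    return rec


def bandpass(hb: HbRecording, low: float = 0.005, high: float = 0.5,
             order: int = 3) -> HbRecording:
    """Zero-phase Butterworth bandpass of the concentration series.

    Removes slow drifts below ``low`` and cardiac/high-frequency
    physiology above ``high``; applied forward-backward so the
    hemodynamic response suffers no group delay.
    """
    nyq = hb.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=hb.fs,
                        output="sos")
    rec = HbRecording(
        hbo=signal.sosfiltfilt(sos, hb.hbo, axis=-1),
        hbr=signal.sosfiltfilt(sos, hb.hbr, axis=-1),
        fs=hb.fs, probe=hb.probe, schedule=hb.schedule,
        channel_idx=hb.channel_idx, pruned=dict(hb.pruned),
        band=(low, high), meta=dict(hb.meta), log=list(hb.log))
    rec.log.append(("bandpass", {"low": low, "high": high, "order": order}))
    return rec


def preprocess_recording(raw: RawRecording,
                         params: PreprocessParams = PreprocessParams(),
                         motion_correction: bool = True,
                         apply_bandpass: bool = True) -> HbRecording:
    """Run the full chain: prune -> OD -> spline -> wavelet -> MBLL -> bandpass."""
    od = intensity_to_od(raw, threshold=params.snr_threshold)
    if motion_correction:
        od = spline_correct(od, params)
        od = wavelet_correct(od, params)
    hb = od_to_hb(od, dpf=params.dpf)
    if apply_bandpass:
        hb = bandpass(hb, params.band_low, params.band_high,
                      params.filter_order)
    return hb
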