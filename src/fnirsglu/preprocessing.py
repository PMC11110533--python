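"""Raw intensity → artifact-corrected ΔHbO/ΔHbR concentration changes.

Re-implements the Homer2-style chain: channel pruning → optical density →
motion-artifact detection → wavelet correction → band-pass filtering →
MBLL inversion → correlation-based signal improvement (CBSI).

Note on the band: the filter op supports any (low, high) combination and
meets the usual pass/stop-band contract when configured as a 0.01–0.1 Hz
band-pass.  The pipeline default applies only the 0.1 Hz low-pass, because
glucose-coupled hemodynamics evolve over tens of minutes (fundamental
~3·10⁻⁴ Hz) and a 0.01 Hz high-pass would remove both the trend and every
state-level mean difference downstream stages analyse; see docs/methods.md.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pywt
from scipy import signal as sps

from .config import OpticsModel
from .errors import ConfigError, DataError, StageError
from .synthetic import RawRecording


@dataclass
class ODSeries:
    """Optical-density change series, ΔOD = −log10(I/Ī), unitless."""

    od: np.ndarray                 # (T, C, 2)
    times: np.ndarray
    sampling_rate: float
    channel_mask: np.ndarray       # (C,) True = kept
    subject_id: str = ""
    state_labels: np.ndarray | None = None


@dataclass
class HemoTimeSeries:
    """Per-channel ΔHbO/ΔHbR concentration changes in μM."""

    dhbo: np.ndarray               # (T, C)
    dhbr: np.ndarray               # (T, C)
    times: np.ndarray
    sampling_rate: float
    channel_mask: np.ndarray
    subject_id: str = ""
    state_labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dhbo.shape != self.dhbr.shape:
            raise DataError("ΔHbO and ΔHbR must have identical shapes")


@dataclass
class PreprocessParams:
    """Tunable parameters of the preprocessing chain."""

    d_range: tuple = (1e-2, 1.0)       # intensity pruning range
    snr_thresh: float = 2.0            # mean/std threshold
    t_motion: float = 1.0              # s, detection window
    t_mask: float = 1.0                # s, mask extension
    std_thresh: float = 5.0            # × channel-median windowed std
    amp_thresh: float = 0.02           # OD peak-to-peak threshold
    od_baseline: str = "fasting"       # OD reference: pre-load block
    wavelet: str = "db2"
    wavelet_level: int | None = None   # None → automatic
    iqr_factor: float = 1.5
    low_hz: float | None = None        # pipeline default: no high-pass
    high_hz: float | None = 0.1
    filter_order: int = 3
    do_prune: bool = True
    do_motion_detect: bool = True
    do_wavelet: bool = True
    do_bandpass: bool = True
    do_cbsi: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# individual stages


def prune_channels(recording: RawRecording, d_range: tuple = (1e-2, 1.0),
                   snr_thresh: float = 2.0) -> np.ndarray:
    """Keep a channel iff, at both wavelengths, the mean intensity falls in
    d_range and mean/std ≥ snr_thresh (a constant channel has infinite SNR).
    The data are not modified; a boolean mask is returned."""
    if recording.n_samples == 0:
        raise DataError("empty recording")
    I = recording.intensity                       # (T, C, 2)
    mean = I.mean(axis=0)                         # (C, 2)
    std = I.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(std > 0, mean / std, np.inf)
    ok = (mean >= d_range[0]) & (mean <= d_range[1]) & (snr >= snr_thresh)
    mask = ok.all(axis=1)
    if not mask.any():
        raise DataError("no usable channels: all pruned by dRange/SNR criteria")
    return mask


def intensity_to_od(recording: RawRecording,
                    channel_mask: np.ndarray | None = None,
                    baseline: str = "mean") -> ODSeries:
    """ΔOD(t) = −log10(I(t)/Ī) per channel and wavelength.

    baseline="mean" (default) takes Ī as the temporal mean of the whole
    recording.  baseline="fasting" takes Ī over the pre-load fasting
    samples only (block-design referencing), so the glucose block's ΔOD —
    and hence ΔHbO — is expressed relative to the fasting state; this is
    what the state-contrast and energy-feature analyses assume.  Falls back
    to the temporal mean when the recording carries no fasting samples.
    """
    if baseline not in ("mean", "fasting"):
        raise ConfigError(f"unknown OD baseline '{baseline}'")
    I = recording.intensity
    if np.any(I <= 0):
        t_idx, c_idx, w_idx = np.argwhere(I <= 0)[0]
        raise DataError(
            f"non-positive intensity at channel {c_idx + 1}, "
            f"wavelength {recording.wavelengths_nm[w_idx]} nm, sample {t_idx}")
    ref = np.asarray(recording.state_labels) == "fasting"
    if baseline == "fasting" and ref.any():
        mean = I[ref].mean(axis=0, keepdims=True)
    else:
        mean = I.mean(axis=0, keepdims=True)
    od = -np.log10(I / mean)
    mask = (np.ones(recording.n_channels, dtype=bool)
            if channel_mask is None else np.asarray(channel_mask, dtype=bool))
    return ODSeries(od=od, times=recording.times,
                    sampling_rate=recording.sampling_rate, channel_mask=mask,
                    subject_id=recording.subject_id,
                    state_labels=recording.state_labels)


def _window_view(x: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, w)


def detect_motion_artifacts(od: ODSeries, t_motion: float = 1.0,
                            t_mask: float = 1.0, std_thresh: float = 5.0,
                            amp_thresh: float = 0.02) -> np.ndarray:
    """Flag motion-contaminated samples per channel.

    Within each sliding window of t_motion seconds a channel/wavelength is
    flagged when the peak-to-peak change exceeds amp_thresh or the windowed
    std exceeds std_thresh × the channel's median windowed std; flags are
    extended by t_mask seconds on both sides.  Returns a (T, C) boolean mask.
    """
    if t_motion <= 0 or t_mask < 0 or std_thresh <= 0 or amp_thresh <= 0:
        raise ConfigError("detection thresholds must be positive")
    fs = od.sampling_rate
    T, C, _ = od.od.shape
    w = max(int(round(t_motion * fs)), 2)
    if w > T:
        raise DataError(f"detection window ({w} samples) longer than series ({T})")
    pad = int(round(t_mask * fs))
    mask = np.zeros((T, C), dtype=bool)
    win_kernel = np.ones(w)
    dil_kernel = np.ones(2 * pad + 1) if pad > 0 else None
    for c in range(C):
        flagged = np.zeros(T - w + 1, dtype=bool)
        for wl in range(2):
            view = _window_view(od.od[:, c, wl], w)
            amp = view.max(axis=1) - view.min(axis=1)
            sd = view.std(axis=1)
            med = np.median(sd)
            flagged |= (amp > amp_thresh)
            if med > 0:
                flagged |= (sd > std_thresh * med)
        samples = np.convolve(flagged.astype(float), win_kernel, mode="full")[:T] > 0
        if dil_kernel is not None:
            samples = np.convolve(samples.astype(float), dil_kernel, mode="same") > 0
        mask[:, c] = samples
    return mask


def _wavelet_correct_1d(x: np.ndarray, wavelet: str, level: int,
                        iqr_factor: float) -> np.ndarray:
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        q1, q3 = np.percentile(detail, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        d = detail.copy()
        d[(d < lo) | (d > hi)] = 0.0
        out.append(d)
    return pywt.waverec(out, wavelet, mode="symmetric")[: x.size]


def default_wavelet_level(n_samples: int, sampling_rate: float,
                          wavelet: str = "db2", low_cut: float = 0.01) -> int:
    """⌊log2(fs/low_cut)⌋ capped by the data length."""
    target = int(np.floor(np.log2(sampling_rate / low_cut)))
    cap = pywt.dwt_max_level(n_samples, pywt.Wavelet(wavelet).dec_len)
    return max(min(target, cap), 1)


def wavelet_motion_correct(od: ODSeries, wavelet: str = "db2",
                           level: int | None = None,
                           iqr_factor: float = 1.5) -> ODSeries:
    """Zero outlying detail coefficients of a per-channel DWT.

    Detail coefficients outside [Q1 − f·IQR, Q3 + f·IQR] at each level are
    set to zero (the statistical-dispersion criterion); the approximation
    band is untouched, so in-band slow structure survives while spike-like
    transients are removed.
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ConfigError(f"unsupported wavelet '{wavelet}'")
    T = od.od.shape[0]
    if level is None:
        level = default_wavelet_level(T, od.sampling_rate, wavelet)
    if level < 1 or T < 2 ** level:
        raise ConfigError(f"series length {T} too short for level {level}")
    corrected = np.empty_like(od.od)
    for c in range(od.od.shape[1]):
        for wl in range(2):
            corrected[:, c, wl] = _wavelet_correct_1d(od.od[:, c, wl],
                                                      wavelet, level, iqr_factor)
    return ODSeries(od=corrected, times=od.times, sampling_rate=od.sampling_rate,
                    channel_mask=od.channel_mask, subject_id=od.subject_id,
                    state_labels=od.state_labels)


def bandpass_filter(x: np.ndarray, low_hz: float | None, high_hz: float | None,
                    sampling_rate: float, order: int = 3,
                    axis: int = 0) -> np.ndarray:
    """Zero-phase Butterworth filter (applied forward–backward).

    low_hz=None/0 gives a pure low-pass, high_hz=None a pure high-pass;
    configured as (0.01, 0.1) it is the classical fNIRS band-pass with
    passband gain ≥0.9 at 0.05 Hz and stopband gain ≤0.1 at DC and 0.5 Hz.
    """
    nyq = sampling_rate / 2.0
    lo = None if (low_hz is None or low_hz == 0) else float(low_hz)
    hi = None if high_hz is None else float(high_hz)
    if lo is None and hi is None:
        raise ConfigError("at least one band edge must be given")
    for edge in (lo, hi):
        if edge is not None and not 0 < edge < nyq:
            raise ConfigError(f"band edge {edge} Hz outside (0, Nyquist={nyq} Hz)")
    if lo is not None and hi is not None and lo >= hi:
        raise ConfigError("low edge must be below high edge")
    if lo is None:
        sos = sps.butter(order, hi, btype="lowpass", fs=sampling_rate, output="sos")
    elif hi is None:
        sos = sps.butter(order, lo, btype="highpass", fs=sampling_rate, output="sos")
    else:
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sampling_rate,
                         output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def mbll_invert(od: np.ndarray, optics: OpticsModel | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Solve the per-sample 2×2 MBLL system for (ΔHbO, ΔHbR) in μM.

    ``od`` has the wavelength on its trailing axis; the exact linear
    inverse of the forward model in :mod:`fnirsglu.synthetic`.
    """
    optics = (optics or OpticsModel()).validate()
    Minv = np.linalg.inv(optics.pathlength_matrix())
    conc_mM = np.asarray(od, dtype=float) @ Minv.T
    return conc_mM[..., 0] * 1000.0, conc_mM[..., 1] * 1000.0


def od_to_hemo(od: ODSeries, optics: OpticsModel | None = None) -> HemoTimeSeries:
    dhbo, dhbr = mbll_invert(od.od, optics)
    return HemoTimeSeries(dhbo=dhbo, dhbr=dhbr, times=od.times,
                          sampling_rate=od.sampling_rate,
                          channel_mask=od.channel_mask,
                          subject_id=od.subject_id,
                          state_labels=od.state_labels)


def cbsi_correct(hemo: HemoTimeSeries) -> HemoTimeSeries:
    """Correlation-based signal improvement.

    Per channel, with α = std(ΔHbO)/std(ΔHbR):
        ΔHbO′ = (ΔHbO − α·ΔHbR)/2,   ΔHbR′ = −ΔHbO′/α,
    which makes corr(ΔHbO′, ΔHbR′) = −1 exactly.  Channels with zero
    variance in either series are left unchanged and flagged.
    """
    dhbo = hemo.dhbo.copy()
    dhbr = hemo.dhbr.copy()
    skipped = []
    for c in range(dhbo.shape[1]):
        sh = hemo.dhbo[:, c].std()
        sr = hemo.dhbr[:, c].std()
        if sr == 0 or sh == 0:
            skipped.append(c + 1)
            continue
        alpha = sh / sr
        hbo2 = (hemo.dhbo[:, c] - alpha * hemo.dhbr[:, c]) / 2.0
        dhbo[:, c] = hbo2
        dhbr[:, c] = -hbo2 / alpha
    if skipped:
        warnings.warn(f"CBSI skipped zero-variance channels {skipped}")
    prov = dict(hemo.provenance)
    prov["cbsi_skipped_channels"] = skipped
    return HemoTimeSeries(dhbo=dhbo, dhbr=dhbr, times=hemo.times,
                          sampling_rate=hemo.sampling_rate,
                          channel_mask=hemo.channel_mask,
                          subject_id=hemo.subject_id,
                          state_labels=hemo.state_labels, provenance=prov)


# ---------------------------------------------------------------------------
# full chain


def run_preprocessing(recording: RawRecording,
                      params: PreprocessParams | None = None,
                      optics: OpticsModel | None = None) -> HemoTimeSeries:
    """Apply the full chain in order: prune → OD → artifact detection →
    wavelet correction → band-pass → MBLL → CBSI, recording which stages
    ran (and stage-level counts) in the provenance dict."""
    params = params or PreprocessParams()
    stages: list[str] = []
    counts: dict = {}

    def _run(stage, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, str(exc)) from exc
        stages.append(stage)
        return out

    if params.do_prune:
        mask = _run("prune_channels",
                    lambda: prune_channels(recording, params.d_range,
                                           params.snr_thresh))
        counts["channels_pruned"] = int((~mask).sum())
    else:
        mask = np.ones(recording.n_channels, dtype=bool)

    od = _run("intensity_to_od",
              lambda: intensity_to_od(recording, mask, params.od_baseline))

    if params.do_motion_detect:
        motion = _run("detect_motion_artifacts",
                      lambda: detect_motion_artifacts(od, params.t_motion,
                                                      params.t_mask,
                                                      params.std_thresh,
                                                      params.amp_thresh))
        counts["motion_flagged_fraction"] = float(motion.mean())
    if params.do_wavelet:
        od = _run("wavelet_motion_correct",
                  lambda: wavelet_motion_correct(od, params.wavelet,
                                                 params.wavelet_level,
                                                 params.iqr_factor))
    if params.do_bandpass:
        def _bp():
            filtered = bandpass_filter(od.od, params.low_hz, params.high_hz,
                                       od.sampling_rate, params.filter_order,
                                       axis=0)
            return ODSeries(od=filtered, times=od.times,
                            sampling_rate=od.sampling_rate,
                            channel_mask=od.channel_mask,
                            subject_id=od.subject_id,
                            state_labels=od.state_labels)
        od = _run("bandpass_filter", _bp)

    hemo = _run("mbll", lambda: od_to_hemo(od, optics))
    if params.do_cbsi:
        hemo = _run("cbsi", lambda: cbsi_correct(hemo))

    hemo.provenance.update({"stages": stages, "params": params.to_dict(),
                            "counts": counts})
    return hemo
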