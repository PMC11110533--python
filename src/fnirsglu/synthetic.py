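"""Seeded synthetic fNIRS cohort generator.

Emulates the study design: per subject, a fasting block followed by a
glucose-loaded block, recorded continuously over 21 source–detector
channels at two wavelengths.  The forward chain is

    glucose curve G(t)
      → hemodynamics  ΔHbO = β·(G − G_fast) + oscillations + noise,
                      ΔHbR = −r·ΔHbO + noise
      → MBLL          ΔOD(λ) = [ε_HbO ΔHbO + ε_HbR ΔHbR]·d·DPF(λ)
      → intensity     I = I0·10^(−ΔOD)
      → motion artifacts (spike transients, baseline shifts)

and every intermediate quantity is retained as ground truth so that the
preprocessing and modeling stages can be tested for parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (FASTING, GLUCOSE, WAVELENGTHS_NM, OpticsModel,
                     SyntheticConfig)
from .errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawRecording:
    """Raw dual-wavelength intensity for one subject and one state.

    ``intensity`` has shape (T, n_channels, 2) with the wavelength axis
    ordered (760, 830) nm; ``times`` is on the continuous session clock so
    fasting and glucose recordings of the same subject can be concatenated.
    """

    subject_id: str
    state: str
    times: np.ndarray
    intensity: np.ndarray
    sampling_rate: float
    geometry: list = field(default_factory=list)
    wavelengths_nm: tuple = WAVELENGTHS_NM
    state_labels: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise DataError("intensity must have shape (T, n_channels, 2)")
        if self.intensity.shape[0] != self.times.shape[0]:
            raise DataError("times and intensity lengths differ")
        if self.state_labels is None:
            self.state_labels = np.full(self.times.shape[0], self.state, dtype=object)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]


@dataclass
class GroundTruth:
    """Noise-free generative state of one synthetic subject."""

    times: np.ndarray              # (T,) session clock, s
    glucose: np.ndarray            # (T,) mmol/L, true curve
    dhbo: np.ndarray               # (T, C) μM, true ΔHbO (signal + noise terms)
    dhbr: np.ndarray               # (T, C) μM
    betas: np.ndarray              # (C,) coupling coefficient per channel
    fasting_level: float           # mmol/L
    events: list = field(default_factory=list)  # artifact log


@dataclass
class SubjectRecord:
    subject_id: str
    fasting: RawRecording
    glucose: RawRecording
    glucose_refs: pd.DataFrame     # time_s, state, glucose_mmol_per_l
    truth: GroundTruth | None = None

    def session(self) -> RawRecording:
        """Concatenate fasting and glucose blocks into one continuous
        recording (the monitoring is continuous; states are label metadata)."""
        return RawRecording(
            subject_id=self.subject_id,
            state="session",
            times=np.concatenate([self.fasting.times, self.glucose.times]),
            intensity=np.concatenate([self.fasting.intensity, self.glucose.intensity]),
            sampling_rate=self.fasting.sampling_rate,
            geometry=self.fasting.geometry,
            state_labels=np.concatenate(
                [np.asarray(self.fasting.state_labels), np.asarray(self.glucose.state_labels)]
            ),
        )


@dataclass
class Cohort:
    config: SyntheticConfig
    subjects: list

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


# ---------------------------------------------------------------------------
# generator stages


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_glucose_curve(config: SyntheticConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample one subject's true glucose curve on the session time grid.

    Fasting block: a stationary level F (drawn once per subject) plus small
    jitter.  Post-load: sin²-shaped rise to F+Δ at the drawn peak time,
    then exponential decay toward the plateau F + plateau_fraction·Δ.  The
    curve is continuous at the state boundary and peaks exactly at
    fasting_duration + peak_time.
    """
    config.validate()
    rng = _as_rng(rng)
    fs = config.sampling_rate
    n_f = config.n_samples(config.fasting_duration)
    n_g = config.n_samples(config.glucose_duration)
    t = np.arange(n_f + n_g) / fs

    level = rng.normal(config.fasting_glucose_mean, config.fasting_glucose_sd)
    delta = max(rng.normal(config.peak_delta_mean, config.peak_delta_sd), 0.0)
    peak_time = max(rng.normal(config.peak_time_mean, config.peak_time_sd),
                    10.0 / fs)

    rel = t - config.fasting_duration
    g = np.full(t.shape, level, dtype=float)
    rise = (rel >= 0) & (rel <= peak_time)
    g[rise] = level + delta * np.sin(0.5 * np.pi * rel[rise] / peak_time) ** 2
    fall = rel > peak_time
    plateau = config.plateau_fraction * delta
    g[fall] = level + plateau + (delta - plateau) * np.exp(
        -(rel[fall] - peak_time) / config.decay_tau)
    if config.glucose_curve_noise_sd > 0:
        g = g + rng.normal(0.0, config.glucose_curve_noise_sd, size=g.shape)
    return t, g


def hemo_forward_model(times: np.ndarray, glucose: np.ndarray,
                       config: SyntheticConfig, channel: int, rng,
                       beta: float | None = None,
                       fasting_level: float | None = None
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Map a glucose curve to one channel's (ΔHbO, ΔHbR) in μM.

    ΔHbO couples linearly to the glucose excursion above the fasting level
    on coupled channels (β = 0 elsewhere), on top of cardiac, respiratory
    and Mayer-wave sinusoids and white noise.  ΔHbR is anti-correlated
    scaled ΔHbO plus independent noise.  Returns (ΔHbO, ΔHbR, β).
    """
    config.validate()
    if not 1 <= channel <= config.n_channels:
        raise ConfigError(f"channel {channel} outside 1..{config.n_channels}")
    rng = _as_rng(rng)
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if beta is None:
        if channel in config.coupled_channels:
            beta = max(rng.normal(config.coupling_beta_mean, config.coupling_beta_sd), 0.0)
        else:
            beta = 0.0
    if fasting_level is None:
        mask = t < config.fasting_duration
        fasting_level = float(np.mean(g[mask])) if mask.any() else float(g[0])

    dhbo = beta * (g - fasting_level)
    for freq, amp in ((config.cardiac_hz, config.cardiac_amp),
                      (config.respiratory_hz, config.respiratory_amp),
                      (config.mayer_hz, config.mayer_amp)):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        if amp > 0:
            dhbo = dhbo + amp * np.sin(2.0 * np.pi * freq * t + phase)
    # slow systemic drift (vasomotion): random low-frequency sinusoids
    if config.vlf_amp > 0 and config.vlf_components > 0:
        lo, hi = config.vlf_band
        comp_amp = config.vlf_amp / np.sqrt(config.vlf_components)
        for _ in range(config.vlf_components):
            freq = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            dhbo = dhbo + comp_amp * np.sin(2.0 * np.pi * freq * t + phase)
    if config.noise_sd > 0:
        dhbo = dhbo + rng.normal(0.0, config.noise_sd, size=t.shape)
    dhbr = -config.hbr_ratio * dhbo
    if config.hbr_noise_sd > 0:
        dhbr = dhbr + rng.normal(0.0, config.hbr_noise_sd, size=t.shape)
    return dhbo, dhbr, float(beta)


def forward_mbll_od(dhbo: np.ndarray, dhbr: np.ndarray,
                    optics: OpticsModel | None = None) -> np.ndarray:
    """Forward MBLL: ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ).

    Inputs in μM; trailing output axis is the wavelength (760, 830).
    """
    optics = (optics or OpticsModel()).validate()
    M = optics.pathlength_matrix()          # ΔOD = M @ conc_mM
    conc_mM = np.stack([np.asarray(dhbo, float), np.asarray(dhbr, float)],
                       axis=-1) / 1000.0    # μM → mM
    return conc_mM @ M.T


def forward_mbll_intensity(dhbo: np.ndarray, dhbr: np.ndarray,
                           optics: OpticsModel | None = None,
                           baseline_intensity: float = 0.1) -> np.ndarray:
    """Forward model to raw intensity: I(t) = I0·10^(−ΔOD(t))."""
    if baseline_intensity <= 0:
        raise ConfigError("baseline_intensity must be positive")
    od = forward_mbll_od(dhbo, dhbr, optics)
    return baseline_intensity * 10.0 ** (-od)


def inject_artifacts(intensity: np.ndarray, config: SyntheticConfig, rng,
                     channel: int | None = None) -> tuple[np.ndarray, list]:
    """Add spike transients and step baseline shifts at Poisson times.

    Spikes are multiplicative exponential-decay transients (signed, a few
    tenths of a second); shifts multiply the remainder of the series by a
    constant factor.  Works on (T,) or (T, K) arrays (the trailing axes are
    affected jointly, emulating an optode-level event).  Returns the
    modified copy and an event log.
    """
    config.validate()
    rng = _as_rng(rng)
    x = np.array(intensity, dtype=float, copy=True)
    T = x.shape[0]
    fs = config.sampling_rate
    minutes = T / fs / 60.0
    events: list[dict] = []

    n_spikes = rng.poisson(config.artifact_spike_rate * minutes)
    tail_n = max(int(round(10 * config.spike_tau * fs)), 1)
    rel_t = np.arange(tail_n) / fs
    for _ in range(int(n_spikes)):
        i0 = int(rng.integers(0, T))
        amp = rng.uniform(*config.spike_amp_range) * rng.choice([-1.0, 1.0])
        n = min(tail_n, T - i0)
        factor = 1.0 + amp * np.exp(-rel_t[:n] / config.spike_tau)
        x[i0:i0 + n] = (x[i0:i0 + n].T * factor).T
        events.append({"channel": channel, "time_s": i0 / fs,
                       "kind": "spike", "magnitude": float(amp)})

    n_shifts = rng.poisson(config.artifact_shift_rate * minutes)
    for _ in range(int(n_shifts)):
        i0 = int(rng.integers(0, T))
        amp = rng.uniform(*config.shift_amp_range) * rng.choice([-1.0, 1.0])
        x[i0:] = x[i0:] * (1.0 + amp)
        events.append({"channel": channel, "time_s": i0 / fs,
                       "kind": "shift", "magnitude": float(amp)})
    return x, events


def default_geometry(n_channels: int, separation_mm: float = 30.0) -> list:
    """Nominal montage metadata: source/detector index and separation."""
    return [{"channel": c + 1, "source": c // 2 + 1, "detector": c // 2 + 1 + (c % 2),
             "separation_mm": separation_mm} for c in range(n_channels)]


def generate_subject(config: SyntheticConfig, index: int,
                     optics: OpticsModel | None = None) -> SubjectRecord:
    """Generate one subject (deterministic in (config.rng_seed, index))."""
    config.validate()
    optics = (optics or OpticsModel()).validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), int(index)]))
    subject_id = f"S{index + 1:02d}"
    fs = config.sampling_rate
    n_f = config.n_samples(config.fasting_duration)

    t, g = generate_glucose_curve(config, rng)
    fast_level = float(np.mean(g[:n_f]))

    # One β per subject, shared by all coupled channels.
    beta_subject = max(rng.normal(config.coupling_beta_mean, config.coupling_beta_sd), 0.0)

    C = config.n_channels
    dhbo = np.empty((t.size, C))
    dhbr = np.empty((t.size, C))
    betas = np.empty(C)
    for c in range(1, C + 1):
        b = beta_subject if c in config.coupled_channels else 0.0
        dhbo[:, c - 1], dhbr[:, c - 1], betas[c - 1] = hemo_forward_model(
            t, g, config, c, rng, beta=b, fasting_level=fast_level)

    intensity = forward_mbll_intensity(dhbo, dhbr, optics,
                                       config.baseline_intensity)  # (T, C, 2)
    events: list[dict] = []
    for c in range(C):
        intensity[:, c, :], ev = inject_artifacts(intensity[:, c, :], config,
                                                  rng, channel=c + 1)
        events.extend(ev)

    geometry = default_geometry(C, separation_mm=optics.separation_cm * 10.0)
    state_f = np.full(n_f, FASTING, dtype=object)
    state_g = np.full(t.size - n_f, GLUCOSE, dtype=object)
    fasting_rec = RawRecording(subject_id, FASTING, t[:n_f], intensity[:n_f],
                               fs, geometry, state_labels=state_f)
    glucose_rec = RawRecording(subject_id, GLUCOSE, t[n_f:], intensity[n_f:],
                               fs, geometry, state_labels=state_g)

    # Fingertip reference samples on a regular schedule, with meter noise.
    ref_times = np.arange(0.0, config.session_duration - 1e-9,
                          config.glucose_sample_interval)
    idx = np.clip(np.round(ref_times * fs).astype(int), 0, t.size - 1)
    ref_vals = g[idx] + rng.normal(0.0, config.glucose_meter_sd, size=idx.shape)
    refs = pd.DataFrame({
        "subject_id": subject_id,
        "state": np.where(ref_times < config.fasting_duration, FASTING, GLUCOSE),
        "time_s": ref_times,
        "glucose_mmol_per_l": ref_vals,
    })

    truth = GroundTruth(times=t, glucose=g, dhbo=dhbo, dhbr=dhbr, betas=betas,
                        fasting_level=fast_level, events=events)
    return SubjectRecord(subject_id, fasting_rec, glucose_rec, refs, truth)


def generate_cohort(config: SyntheticConfig | None = None,
                    optics: OpticsModel | None = None) -> Cohort:
    """Generate the full cohort: n_subjects × {fasting, glucose} recordings
    with reference glucose and retained ground truth.  Identical config and
    seed give bit-identical output."""
    config = (config or SyntheticConfig()).validate()
    subjects = [generate_subject(config, i, optics)
                for i in range(config.n_subjects)]
    return Cohort(config=config, subjects=subjects)
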