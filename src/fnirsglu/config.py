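"""Configuration objects: cohort generator settings and the optical model.

Units follow fNIRS conventions: hemoglobin concentration changes in μM,
glucose in mmol/L, extinction coefficients in 1/(mM·cm), source–detector
separation in cm, time in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, OpticsError

#: Wavelengths of the dual-wavelength montage, nm.
WAVELENGTHS_NM = (760, 830)

FASTING = "fasting"
GLUCOSE = "glucose"
STATES = (FASTING, GLUCOSE)


@dataclass(frozen=True)
class OpticsModel:
    """Optical model for the modified Beer–Lambert law (MBLL).

    Parameters
    ----------
    extinction:
        2×2 matrix of extinction coefficients, rows = wavelengths
        (760, 830 nm), columns = chromophores (HbO, HbR), in 1/(mM·cm).
        Defaults are the Gratzer compilation values used by common fNIRS
        toolchains.
    dpf:
        Differential pathlength factor per wavelength (unitless).
    separation_cm:
        Source–detector separation in cm (30 mm montage → 3.0 cm).
    """

    extinction: tuple = ((0.5860, 1.5485), (0.9740, 0.6930))
    dpf: tuple = (6.0, 6.0)
    separation_cm: float = 3.0

    def validate(self) -> "OpticsModel":
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2):
            raise OpticsError("extinction matrix must be 2x2 (wavelength x chromophore)")
        if abs(np.linalg.det(E)) < 1e-12:
            raise OpticsError("extinction coefficient matrix is singular")
        if len(self.dpf) != 2 or any(d <= 0 for d in self.dpf):
            raise OpticsError("DPF must be positive at both wavelengths")
        if self.separation_cm <= 0:
            raise OpticsError("source-detector separation must be positive")
        return self

    def pathlength_matrix(self) -> np.ndarray:
        """2×2 matrix M with ΔOD(λ) = M @ [ΔHbO_mM, ΔHbR_mM]."""
        self.validate()
        E = np.asarray(self.extinction, dtype=float)
        L = np.asarray(self.dpf, dtype=float) * self.separation_cm
        return E * L[:, None]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort generator.

    The defaults emulate the study conditions: 15 subjects, 21 channels at
    10 Hz, a 10 min fasting block followed by 60 min after a glucose load,
    glucose-coupled HbO responses confined to channels {7, 12, 15, 18, 19},
    cardiac/respiratory/Mayer oscillations, white noise and spike/shift
    motion artifacts.
    """

    n_subjects: int = 15
    n_channels: int = 21
    sampling_rate: float = 10.0          # Hz
    fasting_duration: float = 600.0      # s
    glucose_duration: float = 3600.0     # s

    # Glucose curve (mmol/L): stationary fasting level, sin² rise to
    # fasting+Δ at peak_time after the load, exponential decay toward a
    # plateau at fasting + plateau_fraction·Δ.
    fasting_glucose_mean: float = 5.0
    fasting_glucose_sd: float = 0.3
    peak_delta_mean: float = 3.0
    peak_delta_sd: float = 0.5
    peak_time_mean: float = 1500.0       # s after the load
    peak_time_sd: float = 200.0
    decay_tau: float = 800.0             # s
    plateau_fraction: float = 0.3
    glucose_curve_noise_sd: float = 0.05     # mmol/L, curve jitter
    glucose_meter_sd: float = 0.1            # mmol/L, fingertip meter noise
    glucose_sample_interval: float = 300.0   # s between reference samples

    # Hemodynamic coupling: ΔHbO = β·(G − G_fast) on coupled channels.
    coupled_channels: frozenset = frozenset({7, 12, 15, 18, 19})  # 1-based
    coupling_beta_mean: float = 0.08     # μM per mmol/L
    coupling_beta_sd: float = 0.02
    hbr_ratio: float = 0.3               # ΔHbR = −ratio·ΔHbO + noise

    # Physiological oscillations (amplitudes in μM).
    cardiac_hz: float = 1.1
    respiratory_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp: float = 0.05
    respiratory_amp: float = 0.04
    mayer_amp: float = 0.05
    # Optional very-low-frequency systemic drift: sum of vlf_components
    # random-phase sinusoids with frequencies log-uniform in vlf_band and
    # total amplitude vlf_amp.  Off by default (the reference noise model
    # is cardiac/respiratory/Mayer + white); enable it to stress-test
    # analyses against slow vasomotor drift, which real recordings carry
    # and which inflates naive state-mean contrasts.
    vlf_band: tuple = (0.002, 0.02)      # Hz
    vlf_amp: float = 0.0                 # μM
    vlf_components: int = 5
    noise_sd: float = 0.03               # μM white noise on ΔHbO
    hbr_noise_sd: float = 0.01           # μM independent noise on ΔHbR

    # Intensity-domain motion artifacts.
    artifact_spike_rate: float = 0.5     # events/min
    artifact_shift_rate: float = 0.1     # events/min
    spike_amp_range: tuple = (0.05, 0.2)     # fractional intensity change
    spike_tau: float = 0.3               # s, spike decay constant
    shift_amp_range: tuple = (0.02, 0.05)    # fractional baseline shift

    baseline_intensity: float = 0.1      # I0, within the pruning dRange
    rng_seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ConfigError("n_subjects and n_channels must be >= 1")
        for name in ("sampling_rate", "fasting_duration", "glucose_duration",
                     "peak_time_mean", "decay_tau", "glucose_sample_interval",
                     "baseline_intensity"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("fasting_glucose_sd", "peak_delta_sd", "peak_time_sd",
                     "glucose_curve_noise_sd", "glucose_meter_sd",
                     "coupling_beta_sd", "noise_sd", "hbr_noise_sd",
                     "artifact_spike_rate", "artifact_shift_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        bad = set(self.coupled_channels) - set(range(1, self.n_channels + 1))
        if bad:
            raise ConfigError(f"coupled_channels {sorted(bad)} outside 1..{self.n_channels}")
        if not 0 <= self.plateau_fraction <= 1:
            raise ConfigError("plateau_fraction must lie in [0, 1]")
        return self

    @property
    def session_duration(self) -> float:
        return self.fasting_duration + self.glucose_duration

    def n_samples(self, duration: float) -> int:
        return int(round(duration * self.sampling_rate))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupled_channels"] = sorted(self.coupled_channels)
        d["spike_amp_range"] = list(self.spike_amp_range)
        d["shift_amp_range"] = list(self.shift_amp_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "coupled_channels" in d:
            d["coupled_channels"] = frozenset(d["coupled_channels"])
        for key in ("spike_amp_range", "shift_amp_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


def substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic named RNG substream derived from a root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
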