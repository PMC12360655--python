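"""Synthetic validation data for the wave-fit and projection chain.

Two generators make every downstream stage testable without running the
network model:

* ideal planar scalp waves written directly into the electrode space, with
  known direction, spatial frequency and temporal frequency;
* phase-lagged oscillatory dipoles at the template source positions,
  projected through the production lead field, with a known forward or
  backward ordering.

Both are seed-deterministic and carry their ground truth in the returned
spec objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg import EEGRecord, EEG_SFREQ, Montage, project, standard_montage


@dataclass(frozen=True)
class PlanarWaveSpec:
    """Ground truth of an ideal planar scalp wave.

    ``direction`` is the phase-gradient angle alpha (rad) in the 2D layout,
    ``spatial_freq`` the gradient magnitude xi (rad per layout unit).
    Channel i carries sin(2*pi*f*t + a*x_i + b*y_i) with
    (a, b) = xi*(cos(alpha), sin(alpha)).
    """

    direction: float
    spatial_freq: float
    temporal_freq: float = 10.0
    amplitude: float = 1.0
    noise_sd: float = 0.0

    @property
    def gradient(self) -> tuple[float, float]:
        return (
            self.spatial_freq * np.cos(self.direction),
            self.spatial_freq * np.sin(self.direction),
        )


def make_planar_scalp_wave(
    spec: PlanarWaveSpec,
    duration: float,
    rng: np.random.Generator | None = None,
    montage: Montage | None = None,
    sfreq: float = EEG_SFREQ,
) -> EEGRecord:
    """Ideal planar traveling wave in electrode space."""
    mont = montage or standard_montage()
    t = np.arange(int(round(duration * sfreq))) / sfreq
    a, b = spec.gradient
    phase_xy = mont.pos2d[:, 0] * a + mont.pos2d[:, 1] * b
    data = spec.amplitude * np.sin(
        2.0 * np.pi * spec.temporal_freq * t[None, :] + phase_xy[:, None]
    )
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required for noisy fixtures")
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    return EEGRecord(data, sfreq, mont.ch_names, mont)


@dataclass(frozen=True)
class LaggedDipoleSpec:
    """Oscillatory sources at the template positions with fixed phase lags.

    ``phase_offsets`` holds one phase (rad) per area, ordered from the
    lowest (occipital) to the highest (frontal) area.  A *forward* wave has
    the occipital source leading, i.e. offsets decreasing along the
    hierarchy (higher areas reach the same phase later).
    """

    phase_offsets: tuple[float, ...]
    temporal_freq: float = 10.0

    @property
    def n_sources(self) -> int:
        return len(self.phase_offsets)

    @property
    def ordering(self) -> str:
        d = np.diff(self.phase_offsets)
        if np.all(d < 0):
            return "FW"
        if np.all(d > 0):
            return "BW"
        return "mixed"


def make_lagged_dipole_eeg(
    spec: LaggedDipoleSpec,
    duration: float,
    rng: np.random.Generator,
    noise_sources: int = 0,
    montage: Montage | None = None,
) -> EEGRecord:
    """Project phase-lagged sinusoidal sources through the lead field."""
    t = np.arange(int(round(duration * EEG_SFREQ))) / EEG_SFREQ
    sources = np.array(
        [
            np.sin(2.0 * np.pi * spec.temporal_freq * t + off)
            for off in spec.phase_offsets
        ]
    )
    return project(sources, rng, noise_sources=noise_sources, montage=montage)
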