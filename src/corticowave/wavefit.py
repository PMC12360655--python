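"""Phase-gradient quantification of traveling waves.

For each 100 ms sliding window, the relative alpha-band phase across an
electrode ROI is fit with a planar wave model

    theta_hat(x, y) = a*x + b*y + vartheta,

by exhaustive search over a polar grid of (direction, spatial frequency)
pairs, maximising the resultant length of the circular residuals

    rbar = | mean( exp( i*(theta - theta_hat) ) ) |.

The phase-gradient direction is alpha = atan2(b, a) and the spatial
frequency xi = sqrt(a^2 + b^2).  Goodness of fit is the circular
(Fisher-Lee) correlation rho between observed and predicted phases,
thresholded against a null distribution built by refitting with permuted
electrode positions.  Significant windows whose gradient lies within
0.5 rad of the forward/backward reference axis are classified FW or BW;
everything else is Null.

Sign convention: the 2D layout has +y anterior.  A forward (posterior ->
anterior propagating) wave has its *leading* phase anterior-ward, i.e. the
fitted phase gradient (a, b) points posterior; the FW reference direction
for the gradient angle alpha is therefore -pi/2, and +pi/2 for BW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg import EEGRecord, roi_channel_lists, standard_montage, Montage

#: gradient angle corresponding to a forward wave on the standard layout
FW_AXIS_ANGLE = -np.pi / 2.0
#: angular tolerance of the FW/BW classification (rad)
AXIS_TOLERANCE = 0.5

DEFAULT_BAND = (7.0, 13.0)
WINDOW_S = 0.1


def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(a, dtype=float)))


# --------------------------------------------------------------------------
# ROIs


@dataclass(frozen=True)
class ElectrodeROI:
    name: str
    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_elec, 2)

    @property
    def n_electrodes(self) -> int:
        return len(self.ch_names)


def get_roi(name: str, montage: Montage | None = None) -> ElectrodeROI:
    """Preset ROIs: 'midline' (38 electrodes), 'left'/'right' (20 each)."""
    mont = montage or standard_montage()
    lists = roi_channel_lists()
    if name not in ("midline", "left", "right"):
        raise ValueError(f"unknown ROI {name!r}")
    chs = lists[name]
    picks = mont.picks(chs)
    return ElectrodeROI(name, tuple(chs), mont.pos2d[picks])


# --------------------------------------------------------------------------
# phase maps


@dataclass
class PhaseMap:
    """Windowed relative phase per electrode: (n_windows, n_electrodes)."""

    phases: np.ndarray
    times: np.ndarray
    roi: ElectrodeROI
    band: tuple[float, float]


def compute_phase(
    eeg: EEGRecord,
    roi: ElectrodeROI,
    band: tuple[float, float] = DEFAULT_BAND,
    window: float = WINDOW_S,
    hop: int = 1,
) -> PhaseMap:
    """Relative alpha phase per electrode in sliding windows.

    Band-pass FIR (order three cycles of the low band edge, zero-phase),
    analytic Hilbert phase, referenced to the circular mean phase across the
    ROI at each sample, then circularly averaged within a sliding window.
    """
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import filtfilt, firwin, hilbert

    fs = eeg.sfreq
    if band[1] * 2.0 >= fs:
        raise ValueError("band upper edge above Nyquist")
    if eeg.data.shape[1] < fs:
        raise ValueError("need at least 1 s of data")
    picks = eeg.montage.picks(list(roi.ch_names))
    x = eeg.data[picks]

    numtaps = int(round(3.0 * fs / band[0])) | 1
    b = firwin(numtaps, band, pass_zero=False, fs=fs)
    xf = filtfilt(b, 1, x, axis=1)
    phase = np.angle(hilbert(xf, axis=1))

    z = np.exp(1j * phase)
    ref = z.mean(axis=0)
    ref = ref / np.maximum(np.abs(ref), 1e-12)
    z_rel = z * np.conj(ref)[None, :]

    n_win = max(int(round(window * fs)), 1)
    z_avg = uniform_filter1d(z_rel.real, n_win, axis=1) + 1j * uniform_filter1d(
        z_rel.imag, n_win, axis=1
    )
    # valid region only (full windows)
    half = n_win // 2
    sl = slice(half, z_avg.shape[1] - (n_win - 1 - half))
    phases = np.angle(z_avg[:, sl]).T[::hop]
    times = (np.arange(eeg.data.shape[1])[sl] / fs)[::hop]
    return PhaseMap(phases, times, roi, tuple(band))


# --------------------------------------------------------------------------
# plane fit


@dataclass(frozen=True)
class PlaneFitGrid:
    """Polar search grid: directions x spatial frequencies (plus xi = 0)."""

    n_directions: int = 60
    n_frequencies: int = 30
    max_distance: float = field(default=None)  # type: ignore[assignment]

    def vectors(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Grid of (a, b) coefficients with their (alpha, xi) labels."""
        D = self.max_distance
        if D is None:
            diff = positions[:, None, :] - positions[None, :, :]
            D = float(np.sqrt((diff**2).sum(-1)).max())
        xi_max = 2.0 * np.pi / D
        dirs = np.linspace(0.0, 2.0 * np.pi, self.n_directions, endpoint=False)
        xis = np.linspace(0.0, xi_max, self.n_frequencies)[1:]  # xi=0 added once
        A = np.concatenate([[0.0], (xis[None, :] * np.cos(dirs)[:, None]).ravel()])
        B = np.concatenate([[0.0], (xis[None, :] * np.sin(dirs)[:, None]).ravel()])
        alpha = np.concatenate([[np.nan], np.repeat(dirs, len(xis))])
        xi = np.hypot(A, B)
        return np.column_stack([A, B]), alpha, xi


@dataclass
class WaveFitResult:
    """Best planar fit per window plus the FW/BW/Null classification."""

    times: np.ndarray
    alpha: np.ndarray
    xi: np.ndarray
    rbar: np.ndarray
    rho: np.ndarray
    state: np.ndarray  # 'FW' | 'BW' | 'Null'

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "alpha": self.alpha,
                "xi": self.xi,
                "rbar": self.rbar,
                "rho": self.rho,
                "state": self.state,
            }
        )


def _resultant(phases: np.ndarray, positions: np.ndarray, AB: np.ndarray) -> np.ndarray:
    """rbar for every (window, grid point): (n_win, n_grid)."""
    pred = positions @ AB.T  # (n_elec, n_grid)
    E = np.exp(1j * phases)  # (n_win, n_elec)
    P = np.exp(-1j * pred)  # (n_elec, n_grid)
    return np.abs(E @ P) / phases.shape[1]


def plane_fit(
    phases: np.ndarray,
    positions: np.ndarray,
    grid: PlaneFitGrid = PlaneFitGrid(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive grid fit of the planar phase model.

    ``phases``: (n_windows, n_electrodes) relative phases; ``positions``:
    (n_electrodes, 2).  Returns (alpha, xi, rbar) arrays per window; alpha
    is NaN where the best fit is the spatially uniform model (xi = 0).
    """
    phases = np.atleast_2d(phases)
    if positions.shape[0] < 3:
        raise ValueError("need at least 3 electrodes")
    if np.linalg.matrix_rank(positions - positions.mean(0)) < 2:
        raise ValueError("electrode layout is collinear")
    AB, alpha_g, xi_g = grid.vectors(positions)
    R = _resultant(phases, positions, AB)
    best = R.argmax(axis=1)
    return alpha_g[best], xi_g[best], R[np.arange(len(best)), best]


def predicted_phases(positions: np.ndarray, alpha: float, xi: float) -> np.ndarray:
    a, b = xi * np.cos(alpha), xi * np.sin(alpha)
    return positions[:, 0] * a + positions[:, 1] * b


def circ_corr(theta: np.ndarray, theta_hat: np.ndarray) -> float:
    """Circular (Fisher-Lee) correlation of two phase samples."""
    theta = np.asarray(theta, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta.shape != theta_hat.shape or theta.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    tm = np.angle(np.mean(np.exp(1j * theta)))
    hm = np.angle(np.mean(np.exp(1j * theta_hat)))
    s1 = np.sin(theta - tm)
    s2 = np.sin(theta_hat - hm)
    denom = np.sqrt(np.sum(s1**2) * np.sum(s2**2))
    if denom == 0:
        return 0.0
    return float(np.sum(s1 * s2) / denom)


def _rho_per_window(phases: np.ndarray, positions: np.ndarray,
                    alpha: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """Vectorised circular correlation between each window's phases and its
    best-fit plane."""
    n_win, n_elec = phases.shape
    a = np.where(np.isnan(alpha), 0.0, xi * np.cos(alpha))
    b = np.where(np.isnan(alpha), 0.0, xi * np.sin(alpha))
    pred = positions[:, 0][None, :] * a[:, None] + positions[:, 1][None, :] * b[:, None]
    tm = np.angle(np.exp(1j * phases).mean(axis=1))
    hm = np.angle(np.exp(1j * pred).mean(axis=1))
    s1 = np.sin(phases - tm[:, None])
    s2 = np.sin(pred - hm[:, None])
    denom = np.sqrt((s1**2).sum(axis=1) * (s2**2).sum(axis=1))
    denom[denom == 0] = np.inf
    return (s1 * s2).sum(axis=1) / denom


# --------------------------------------------------------------------------
# null distribution & classification


@dataclass
class NullDistribution:
    rhos: np.ndarray
    quantile: float = 0.95

    @property
    def threshold(self) -> float:
        return float(np.quantile(self.rhos, self.quantile))


def build_null(
    phase_maps: list[PhaseMap],
    rng: np.random.Generator,
    grid: PlaneFitGrid = PlaneFitGrid(),
    n_permutations: int = 10,
    stride: int = 5,
) -> NullDistribution:
    """Chance-level rho distribution for a dataset.

    The fit is repeated ``n_permutations`` times with randomly permuted
    electrode positions, at reduced temporal resolution (every ``stride``-th
    window), collating best-fit rho values over trials and windows.
    """
    rhos = []
    for _ in range(n_permutations):
        for pm in phase_maps:
            perm = rng.permutation(pm.roi.positions.shape[0])
            pos = pm.roi.positions[perm]
            ph = pm.phases[::stride]
            alpha, xi, _ = plane_fit(ph, pos, grid)
            rhos.append(_rho_per_window(ph, pos, alpha, xi))
    return NullDistribution(np.concatenate(rhos))


def classify(
    alpha: np.ndarray,
    rho: np.ndarray,
    null: NullDistribution | float,
    reference_axis: float = FW_AXIS_ANGLE,
    tolerance: float = AXIS_TOLERANCE,
) -> np.ndarray:
    """FW/BW/Null state per window.

    FW: rho above the null threshold and the gradient angle within
    ``tolerance`` of ``reference_axis``; BW: within tolerance of the
    opposite direction; Null otherwise (including undefined alpha).
    """
    thr = null.threshold if isinstance(null, NullDistribution) else float(null)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    state = np.full(alpha.shape, "Null", dtype=object)
    ok = (rho > thr) & ~np.isnan(alpha)
    d_fw = np.abs(wrap_angle(alpha - reference_axis))
    d_bw = np.abs(wrap_angle(alpha - reference_axis - np.pi))
    state[ok & (d_fw <= tolerance)] = "FW"
    state[ok & (d_bw <= tolerance)] = "BW"
    return state.astype("U4")


def fit_waves(
    eeg: EEGRecord,
    roi: ElectrodeROI | str = "midline",
    band: tuple[float, float] = DEFAULT_BAND,
    grid: PlaneFitGrid = PlaneFitGrid(),
    null: NullDistribution | float | None = None,
    reference_axis: float = FW_AXIS_ANGLE,
    hop: int = 1,
    rng: np.random.Generator | None = None,
) -> WaveFitResult:
    """Complete wave fit for one recording.

    If ``null`` is None a per-recording null distribution is built (for
    datasets of many trials, build one null over the dataset and pass it).
    """
    if isinstance(roi, str):
        roi = get_roi(roi, eeg.montage)
    pm = compute_phase(eeg, roi, band, hop=hop)
    alpha, xi, rbar = plane_fit(pm.phases, roi.positions, grid)
    rho = _rho_per_window(pm.phases, roi.positions, alpha, xi)
    if null is None:
        null = build_null([pm], rng or np.random.default_rng(0), grid)
    state = classify(alpha, rho, null, reference_axis)
    return WaveFitResult(pm.times, alpha, xi, rbar, rho, state)


# --------------------------------------------------------------------------
# lateralized reference axis


def circular_median(angles: np.ndarray) -> float:
    """Angle among the samples minimising total circular distance."""
    angles = np.asarray(angles, dtype=float)
    d = np.abs(wrap_angle(angles[:, None] - angles[None, :])).sum(axis=0)
    return float(angles[np.argmin(d)])


def lateral_reference_axis(alpha: np.ndarray, state: np.ndarray) -> float:
    """Reference axis for lateralized data.

    FW and BW directions are merged into one distribution by reflecting BW
    fits through pi (collapsing the two propagation senses onto one axis),
    and the circular median of the merged distribution is returned.
    """
    alpha = np.asarray(alpha, dtype=float)
    state = np.asarray(state)
    keep = (state == "FW") | (state == "BW")
    if keep.sum() < 1:
        raise ValueError("no classified windows to estimate an axis from")
    merged = np.where(state[keep] == "BW", wrap_angle(alpha[keep] + np.pi), alpha[keep])
    return circular_median(merged)
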