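"""IR and Raman spectra from tensor time series.

Line shapes are cosine transforms of time-origin-averaged autocorrelation
functions (ACFs).  The IR line shape M(omega) is one third of the trace of
the dipole time correlation; in ``classical_ir`` mode it is multiplied by
the classical prefactor obtained from a first-order expansion of the
Boltzmann factor,

    I(omega) = beta * omega^2 * M(omega) / (6 * c * n),

with beta = 1/(k_B T) in eV^-1, omega in rad/fs and c in Angstrom/fs, so
intensities are on a fixed (arbitrary but reproducible) scale.  Stokes
Raman spectra come from the polarizability/susceptibility ACF; writing
alpha = gamma I + beta_t with gamma = Tr(alpha)/3 and beta_t traceless
gives the isotropic (polarized) channel <gamma(0) gamma(t)> and the
anisotropic (depolarized) channel (2/15) <Tr[beta_t(0) beta_t(t)]>; the
full channel Tr<alpha(0) alpha(t)> satisfies exactly

    full = 3 * iso + (15/2) * aniso

because the gamma/beta cross terms vanish (Tr beta_t = 0).  Quantum
correction factors are deliberately not applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import TensorTrajectory
from .units import FS_INV_IN_CM, KB_EV, SPEED_OF_LIGHT_ANG_FS

#: fixed coefficient of the anisotropic (depolarized) Raman channel
ANISO_COEFF = 2.0 / 15.0

_PAIRS = {"x": 0, "y": 1, "z": 2}


@dataclass
class SpectrumConfig:
    """Settings shared by all spectral estimators.

    ``max_lag`` is in number of samples (converted from fs by the caller if
    needed); ``zero_pad_factor`` pads the ACF before the transform to
    refine the frequency grid; the Hann window suppresses leakage from the
    truncated ACF.  ``refractive_index`` and ``temperature`` only enter the
    classical IR prefactor.
    """

    temperature: float | None = None
    refractive_index: float = 1.0
    max_lag: int | None = None
    window: str = "hann"
    zero_pad_factor: int = 4
    subtract_mean: bool = True
    prefactor_mode: str = "raw"

    def __post_init__(self):
        if self.window not in ("none", "hann"):
            raise ValueError("window must be 'none' or 'hann'")
        if self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be >= 1")
        if self.prefactor_mode not in ("raw", "classical_ir"):
            raise ValueError("prefactor_mode must be 'raw' or 'classical_ir'")
        if self.prefactor_mode == "classical_ir":
            if self.temperature is None or self.temperature <= 0:
                raise ValueError("classical_ir mode needs a positive temperature")


@dataclass
class Spectrum:
    """A frequency grid (cm^-1, increasing from 0) with named intensity
    channels and normalization metadata."""

    wavenumbers: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def autocorrelation(series: np.ndarray, max_lag: int,
                    subtract_mean: bool = True) -> np.ndarray:
    """Time-origin-averaged ACF of a scalar series for lags 0..max_lag.

    C(tau) = mean over t of x(t) x(t + tau) with the unbiased 1/(N - tau)
    normalization; C(0) is the mean square (the variance when the mean is
    subtracted).  Computed via FFT.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < series length {n}")
    if subtract_mean:
        x = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acf / (n - np.arange(max_lag + 1))


def _resolve_lag(n_frames: int, config: SpectrumConfig) -> int:
    if config.max_lag is None:
        return max(1, n_frames // 2)
    if not 0 < config.max_lag < n_frames:
        raise ValueError(
            f"max_lag must be in (0, {n_frames}), got {config.max_lag}"
        )
    return int(config.max_lag)


def _lineshape(acf: np.ndarray, dt: float, config: SpectrumConfig):
    """Cosine transform of a windowed ACF -> (wavenumbers cm^-1, intensity).

    The ACF is even in the lag, so the spectrum is dt * (C_0 +
    2 sum_{tau>=1} w_tau C_tau cos(omega tau dt)), evaluated on the grid
    k / (n_fft * dt) and reported for omega >= 0 only.
    """
    L = len(acf) - 1
    if config.window == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * np.arange(L + 1) / L))
    else:
        w = np.ones(L + 1)
    a = acf * w
    nfft = config.zero_pad_factor * 2 * L
    padded = np.zeros(nfft)
    padded[: L + 1] = a
    spec = dt * (2.0 * np.real(np.fft.rfft(padded)) - a[0])
    freqs = np.fft.rfftfreq(nfft, d=dt)  # fs^-1
    return freqs * FS_INV_IN_CM, spec


def _component_acfs(frames: np.ndarray, max_lag: int, subtract_mean: bool):
    """ACF of each flattened tensor component; shape (n_components, max_lag+1)."""
    flat = frames.reshape(len(frames), -1)
    return np.stack([
        autocorrelation(flat[:, k], max_lag, subtract_mean)
        for k in range(flat.shape[1])
    ])


def dipole_lineshape(traj: TensorTrajectory, config: SpectrumConfig) -> Spectrum:
    """Raw IR line shape M(omega): transform of one third of the trace of
    the dipole ACF."""
    if traj.rank != 1:
        raise ValueError("dipole_lineshape needs a rank-1 trajectory")
    L = _resolve_lag(traj.n_frames, config)
    acfs = _component_acfs(traj.frames, L, config.subtract_mean)
    wn, intensity = _lineshape(acfs.sum(0) / 3.0, traj.dt, config)
    return Spectrum(wn, {"ir": intensity}, {"mode": "raw"})


def classical_ir_prefactor(wavenumbers: np.ndarray, temperature: float,
                           refractive_index: float = 1.0) -> np.ndarray:
    """beta * omega^2 / (6 c n) on the given wavenumber grid (omega in rad/fs)."""
    omega = 2.0 * np.pi * np.asarray(wavenumbers) / FS_INV_IN_CM
    beta = 1.0 / (KB_EV * temperature)
    return beta * omega ** 2 / (6.0 * SPEED_OF_LIGHT_ANG_FS * refractive_index)


def ir_spectrum(traj: TensorTrajectory, config: SpectrumConfig) -> Spectrum:
    """IR spectrum; ``raw`` mode returns M(omega), ``classical_ir`` applies
    the classical prefactor (zero intensity in the omega = 0 bin)."""
    spec = dipole_lineshape(traj, config)
    if config.prefactor_mode == "raw":
        return spec
    if config.temperature is None or config.temperature <= 0:
        raise ValueError("classical_ir mode needs a positive temperature")
    pref = classical_ir_prefactor(
        spec.wavenumbers, config.temperature, config.refractive_index
    )
    return Spectrum(
        spec.wavenumbers,
        {"ir": pref * spec.channels["ir"]},
        {"mode": "classical_ir", "temperature": config.temperature,
         "refractive_index": config.refractive_index},
    )


def gamma_beta_decompose(traj: TensorTrajectory):
    """Split alpha(t) = gamma(t) I + beta(t) with gamma = Tr(alpha)/3 and
    beta traceless (to machine precision) every frame."""
    if traj.rank != 2:
        raise ValueError("gamma/beta decomposition needs a rank-2 trajectory")
    gamma = np.trace(traj.frames, axis1=1, axis2=2) / 3.0
    beta = traj.frames - gamma[:, None, None] * np.eye(3)
    return gamma, beta


def raman_spectrum(traj: TensorTrajectory, config: SpectrumConfig,
                   mode: str = "full") -> Spectrum:
    """Stokes Raman line shape for one channel.

    Modes: ``iso`` (<gamma gamma>), ``aniso`` ((2/15) <Tr beta beta>),
    ``full`` (Tr <alpha alpha> = 3 iso + (15/2) aniso), or a polarization
    pair like ``xx``/``xy`` selecting <alpha_ab(0) alpha_ab(t)> — the
    Cartesian-axis form of Porto combinations such as Z(XX)Zbar ('xx') and
    Z(XY)Zbar ('xy').
    """
    if traj.rank != 2:
        raise ValueError("raman_spectrum needs a rank-2 trajectory")
    L = _resolve_lag(traj.n_frames, config)
    sub = config.subtract_mean
    if mode == "iso":
        gamma, _ = gamma_beta_decompose(traj)
        acf = autocorrelation(gamma, L, sub)
        name = "raman_iso"
    elif mode == "aniso":
        _, beta = gamma_beta_decompose(traj)
        acf = ANISO_COEFF * _component_acfs(beta, L, sub).sum(0)
        name = "raman_aniso"
    elif mode == "full":
        acf = _component_acfs(traj.frames, L, sub).sum(0)
        name = "raman_full"
    elif len(mode) == 2 and mode[0] in _PAIRS and mode[1] in _PAIRS:
        a, b = _PAIRS[mode[0]], _PAIRS[mode[1]]
        acf = autocorrelation(traj.frames[:, a, b], L, sub)
        name = f"raman_{mode}"
    else:
        raise ValueError(f"unknown Raman mode {mode!r}")
    wn, intensity = _lineshape(acf, traj.dt, config)
    return Spectrum(wn, {name: intensity}, {"mode": mode})


def raman_channels(traj: TensorTrajectory, config: SpectrumConfig,
                   modes=("full", "iso", "aniso")) -> Spectrum:
    """Several Raman channels on a shared frequency grid."""
    channels = {}
    wn = None
    for mode in modes:
        s = raman_spectrum(traj, config, mode)
        wn = s.wavenumbers
        channels.update(s.channels)
    return Spectrum(wn, channels, {"modes": list(modes)})


def normalize_by_band(spectrum: Spectrum, omega_lo: float,
                      omega_hi: float) -> Spectrum:
    """Divide every channel by its trapezoidal integral over
    [omega_lo, omega_hi] (grid points inside the band); the band integral
    of the result is 1.  Idempotent."""
    wn = spectrum.wavenumbers
    mask = (wn >= omega_lo) & (wn <= omega_hi)
    if mask.sum() < 2:
        raise ValueError(
            f"band [{omega_lo}, {omega_hi}] cm^-1 contains fewer than two "
            "grid points"
        )
    channels = {}
    for name, y in spectrum.channels.items():
        integral = np.trapezoid(y[mask], wn[mask])
        if integral == 0:
            raise ValueError(f"channel {name!r} integrates to zero on the band")
        channels[name] = y / integral
    meta = dict(spectrum.meta)
    meta["normalized_band_cm1"] = (omega_lo, omega_hi)
    return Spectrum(wn.copy(), channels, meta)
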