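"""Spectral-domain OCT: interferogram synthesis and the reconstruction chain.

The detector records, per A-scan, 2048 spectral samples of

    S(k) = source(k) * | E_r + sum_n a_n exp(i (2 k z_n + beta (k-k0)^2)) |^2,

with E_r the reference field and beta a quadratic dispersion
coefficient.  Reconstruction follows the standard chain: subtract the
recorded source background, apply a 2048-point Hann window, multiply by
the conjugate quadratic phase (dispersion compensation), Fourier
transform along k, and keep the positive-depth half.  The dispersion
coefficient can be estimated iteratively by minimising the absolute
difference between sub-band reconstructions.  Frame stacks are averaged
on a linear magnitude scale and displayed in dB; frames that decorrelate
from the stack mean (e.g. motion-corrupted ones) can be excluded by a
correlation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "RawSpectra",
    "Tomogram",
    "NoSignalError",
    "default_k_axis",
    "default_source_spectrum",
    "simulate_spectra",
    "reconstruct",
    "estimate_dispersion",
    "exclude_frames",
    "average_and_display",
]

N_SPECTRAL_SAMPLES = 2048


class NoSignalError(RuntimeError):
    """Raised when spectra contain no reflector above the noise floor."""


@dataclass
class RawSpectra:
    """Raw interferograms: Ns spectral samples x Na A-scans.

    ``k_axis`` is the uniform wavenumber grid in rad/um (strictly
    increasing), ``source_spectrum`` the recorded background
    |E_r|^2 * source(k) that background subtraction removes, ``beta``
    the quadratic dispersion coefficient in rad/(rad/um)^2 about the
    centre wavenumber ``k0``.
    """

    spectra: np.ndarray
    k_axis: np.ndarray
    source_spectrum: np.ndarray
    beta: float = 0.0
    reference_amplitude: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[0] == 1 and self.spectra.shape[1] == len(self.k_axis):
            self.spectra = self.spectra.T
        self.k_axis = np.asarray(self.k_axis, dtype=float).ravel()
        self.source_spectrum = np.asarray(self.source_spectrum, dtype=float).ravel()
        if np.any(np.diff(self.k_axis) <= 0):
            raise ValueError("k_axis must be strictly increasing")
        if np.any(self.source_spectrum < 0):
            raise ValueError("source_spectrum must be nonnegative")
        if self.spectra.shape[0] != len(self.k_axis):
            raise ValueError("spectra rows must match k_axis length")
        if len(self.source_spectrum) != len(self.k_axis):
            raise ValueError("source_spectrum must match k_axis length")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.spectra.shape[1]

    @property
    def k0(self) -> float:
        return float(self.k_axis.mean())

    @property
    def dk(self) -> float:
        return float(self.k_axis[1] - self.k_axis[0])

    @property
    def depth_pitch_um(self) -> float:
        """Axial pixel pitch of the reconstruction: pi / (Ns * dk)."""
        return np.pi / (self.n_samples * self.dk)

    @property
    def max_depth_um(self) -> float:
        """Unambiguous depth range pi / (2 dk)."""
        return np.pi / (2.0 * self.dk)


@dataclass
class Tomogram:
    """Complex reconstructed A-scan matrix, Nz x Na (one-sided depth)."""

    field: np.ndarray
    pixel_dz_um: float
    display: str = "linear"

    def __post_init__(self) -> None:
        self.field = np.atleast_2d(np.asarray(self.field))

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.field)

    @property
    def n_depth(self) -> int:
        return self.field.shape[0]


def default_k_axis(
    lambda_min_um: float = 0.8,
    lambda_max_um: float = 1.0,
    n_samples: int = N_SPECTRAL_SAMPLES,
) -> np.ndarray:
    """Uniform wavenumber axis spanning an 800-1000 nm source band."""
    return np.linspace(2 * np.pi / lambda_max_um, 2 * np.pi / lambda_min_um, n_samples)


def default_source_spectrum(k_axis: np.ndarray, rel_fwhm: float = 0.6) -> np.ndarray:
    """Gaussian source envelope on the k axis (peak 1)."""
    k_axis = np.asarray(k_axis, dtype=float)
    k0 = k_axis.mean()
    fwhm = rel_fwhm * (k_axis[-1] - k_axis[0])
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((k_axis - k0) / sigma) ** 2)


def simulate_spectra(
    columns,
    k_axis: np.ndarray | None = None,
    source_spectrum: np.ndarray | None = None,
    beta: float = 0.0,
    reference_amplitude: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawSpectra:
    """Synthesize raw interferograms for one or more scatterer columns.

    ``columns`` is a list of ``(amplitudes, depths_um)`` pairs, one per
    A-scan (a single pair is also accepted).  Depths must lie within
    the unambiguous range.  The recorded ``source_spectrum`` equals the
    DC term |E_r|^2 * source(k), so background subtraction is exact in
    the noiseless case (the weak sample-sample autocorrelation term
    remains, as it physically does).
    """
    if k_axis is None:
        k_axis = default_k_axis()
    k_axis = np.asarray(k_axis, dtype=float)
    if source_spectrum is None:
        source_spectrum = default_source_spectrum(k_axis)
    if isinstance(columns, tuple):  # single (amplitudes, depths) column
        columns = [columns]
    k0 = k_axis.mean()
    dk = k_axis[1] - k_axis[0]
    z_max = np.pi / (2.0 * dk)
    rng = np.random.default_rng(seed)
    spectra = np.empty((len(k_axis), len(columns)))
    disp = np.exp(1j * beta * (k_axis - k0) ** 2)
    for j, (a, z) in enumerate(columns):
        a = np.asarray(a, dtype=float).ravel()
        z = np.asarray(z, dtype=float).ravel()
        if a.size != z.size:
            raise ValueError("amplitudes and depths must have equal length")
        if z.size and np.any((z <= 0) | (z >= z_max)):
            raise ValueError(
                f"depths must lie in (0, {z_max:.1f}) um (unambiguous range)"
            )
        e_s = (a[None, :] * np.exp(2j * k_axis[:, None] * z[None, :])).sum(axis=1)
        field = reference_amplitude + disp * e_s
        s = source_spectrum * np.abs(field) ** 2
        if noise_sd > 0:
            s = s + rng.normal(0.0, noise_sd, size=s.shape)
        spectra[:, j] = s
    return RawSpectra(
        spectra=spectra,
        k_axis=k_axis,
        source_spectrum=source_spectrum * reference_amplitude**2,
        beta=beta,
        reference_amplitude=reference_amplitude,
        seed=seed,
    )


def _window_reconstruct(
    raw: RawSpectra, beta_comp: float, window: np.ndarray
) -> np.ndarray:
    k = raw.k_axis
    phase = np.exp(-1j * beta_comp * (k - raw.k0) ** 2)
    a = (raw.spectra - raw.source_spectrum[:, None]) * (window * phase)[:, None]
    f = np.fft.fft(a, axis=0)
    return np.abs(f[: raw.n_samples // 2])


def reconstruct(raw: RawSpectra, beta_comp: float = 0.0) -> Tomogram:
    """Background subtraction, Hann window, dispersion phase, Fourier transform.

    Per A-scan: ``(S - source_background) * Hann(Ns) *
    exp(-i beta_comp (k - k0)^2)`` followed by a DFT along k; the
    positive-depth half is kept.  A reflector at depth z peaks at index
    round(z / dz) with dz = pi / (Ns * dk).
    """
    if not np.isfinite(beta_comp):
        raise ValueError("beta_comp must be finite")
    window = np.hanning(raw.n_samples)
    k = raw.k_axis
    phase = np.exp(-1j * beta_comp * (k - raw.k0) ** 2)
    a = (raw.spectra - raw.source_spectrum[:, None]) * (window * phase)[:, None]
    f = np.fft.fft(a, axis=0)[: raw.n_samples // 2]
    return Tomogram(field=f, pixel_dz_um=raw.depth_pitch_um)


def _dispersion_objective(raw: RawSpectra, beta: float, floor_frac: float) -> float:
    """Sum |  |R_low| - |R_high|  | over pixels above the noise floor."""
    ns = raw.n_samples
    half = ns // 2
    w_lo = np.zeros(ns)
    w_lo[:half] = np.hanning(half)
    w_hi = np.zeros(ns)
    w_hi[half:] = np.hanning(ns - half)
    r_lo = _window_reconstruct(raw, beta, w_lo)
    r_hi = _window_reconstruct(raw, beta, w_hi)
    both = r_lo + r_hi
    mask = both > floor_frac * both.max()
    return float(np.abs(r_lo - r_hi)[mask].sum())


def estimate_dispersion(
    raw: RawSpectra,
    bracket: tuple[float, float] = (-150.0, 150.0),
    tol: float | None = None,
    floor_frac: float = 0.05,
    min_peak_snr: float = 10.0,
) -> float:
    """Estimate the quadratic dispersion coefficient beta.

    Minimises the summed absolute difference between the magnitude
    reconstructions of the lower and upper spectral half-windows
    (Hann-windowed halves of the 2048 samples) over beta, by bounded
    scalar minimisation to ``tol`` (default 1e-3 of the bracket width).
    Pixels below ``floor_frac`` of the sub-band maximum are ignored.
    The estimate is invariant to global amplitude scaling of the
    spectra.  Raises :class:`NoSignalError` for flat/noise-only input.
    """
    # ignore the lowest depth bins: residual DC always leaks there
    mag = reconstruct(raw, 0.0).magnitude[4:]
    med = np.median(mag)
    if med <= 0 or mag.max() < min_peak_snr * med:
        raise NoSignalError(
            "no reflector above the noise floor; cannot estimate dispersion"
        )
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    if tol is None:
        tol = 1e-3 * (hi - lo)
    res = optimize.minimize_scalar(
        lambda b: _dispersion_objective(raw, b, floor_frac),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def exclude_frames(
    frames: np.ndarray, threshold: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop frames whose correlation to the all-frame mean is below threshold.

    ``frames`` is (M, ...) linear magnitudes with M >= 2.  Returns the
    kept subset and a per-frame report (frame, correlation, kept).
    Raises if every frame would be excluded.
    """
    data = np.asarray(frames, dtype=float)
    if hasattr(frames, "data"):  # FrameStack
        data = np.asarray(frames.data, dtype=float)
    if data.ndim < 2 or data.shape[0] < 2:
        raise ValueError("need at least two frames")
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    mean = data.mean(axis=0).ravel()
    mean_c = mean - mean.mean()
    denom_m = np.sqrt(mean_c @ mean_c)
    corrs = []
    for fr in data:
        f = fr.ravel() - fr.mean()
        denom = np.sqrt(f @ f) * denom_m
        corrs.append(float(f @ mean_c / denom) if denom > 0 else 1.0)
    corrs = np.array(corrs)
    kept = corrs >= threshold
    report = pd.DataFrame(
        {"frame": np.arange(len(corrs)), "correlation": corrs, "kept": kept}
    )
    if not kept.any():
        raise ValueError(
            "all frames excluded; lower the correlation threshold "
            f"(min observed correlation {corrs.min():.3f})"
        )
    return data[kept], report


def average_and_display(
    frames: np.ndarray, eps_rel: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-scale magnitude average and its dB display image.

    The display transform is ``20 log10(mean + eps)`` with eps fixed at
    ``eps_rel`` times the image maximum, making the display
    deterministic and finite for zero pixels.
    """
    data = np.asarray(frames, dtype=float)
    if hasattr(frames, "data"):
        data = np.asarray(frames.data, dtype=float)
    if data.ndim < 2 or data.shape[0] < 1:
        raise ValueError("need at least one frame")
    mean = data.mean(axis=0)
    eps = eps_rel * mean.max() if mean.max() > 0 else eps_rel
    return mean, 20.0 * np.log10(mean + eps)
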