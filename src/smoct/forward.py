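"""Coherent OCT forward model: voxel phasor sums and frame stacks.

A voxel's single-frame value is the magnitude of the coherent sum of
the scatterer phasors it contains,

    R_m = | sum_n a_n exp(i (phi_n + theta_{n,m})) |,

with phi_n = 2 k z_n the round-trip axial phase and theta_{n,m} the
diffuser-induced local phase shift at scatterer n in frame m.  The
displayed pixel value after M averages is I = (1/M) sum_m R_m —
magnitudes averaged on a linear scale.  Conventional OCT corresponds to
theta frozen (identical speckle in every frame); speckle-modulated
acquisition draws a fresh, spatially decorrelated theta per frame, so
the averaged speckle contrast decays as 1/sqrt(M).

Image formation weights each scatterer by Gaussian lateral/axial PSFs.
For speed the complex scatterer amplitudes are deposited onto an
oversampled grid and blurred by FFT convolution — mathematically the
same Gaussian-weighted coherent sum, with sub-pixel positions quantised
to the fine grid for the PSF weight only (phases are computed from the
exact positions before binning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .diffuser import FWHM_TO_SIGMA, BeamSpec, ScreenSampler
from .phantoms import ScattererField, VolumeSpec

__all__ = [
    "NoiseModel",
    "FrameStack",
    "voxel_signal",
    "voxel_frames",
    "washout_factor",
    "simulate_frames",
    "simulate_enface_frames",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive complex circular Gaussian noise on the pre-magnitude field.

    ``additive_floor`` is the per-quadrature standard deviation in
    magnitude units; a single bright reflector then follows Rician
    single-frame statistics, the standard model for shot-noise-limited
    coherent detection.
    """

    additive_floor: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.additive_floor < 0:
            raise ValueError("additive_floor must be nonnegative")

    @property
    def active(self) -> bool:
        return self.enabled and self.additive_floor > 0

    def add(self, field_arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not self.active:
            return field_arr
        noise = rng.standard_normal(field_arr.shape) + 1j * rng.standard_normal(
            field_arr.shape
        )
        return field_arr + self.additive_floor * noise


@dataclass
class FrameStack:
    """M co-registered linear-magnitude frames of the same sample.

    ``data`` has shape (M, rows, cols); ``kind`` is ``"bscan"``
    (rows=depth z, cols=lateral x) or ``"enface"`` (rows=y, cols=x).
    ``pixel_dz_um`` is the row pitch (depth for B-scans, y for en face
    planes), ``pixel_dx_um`` the column pitch.
    """

    data: np.ndarray
    pixel_dz_um: float
    pixel_dx_um: float
    frame_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    kind: str = "bscan"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("data must be (M, rows, cols) with M >= 1")
        if np.any(self.data < 0):
            raise ValueError("frame magnitudes must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def average(self, m: int | None = None) -> np.ndarray:
        """Linear-scale magnitude average of the first m frames."""
        m = self.n_frames if m is None else m
        if not 1 <= m <= self.n_frames:
            raise ValueError(f"m must be in [1, {self.n_frames}]")
        return self.data[:m].mean(axis=0)


def voxel_signal(
    amplitudes: np.ndarray,
    axial_phases: np.ndarray,
    screen_phases: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-frame magnitudes and their average for one voxel.

    ``screen_phases`` has shape (M, N) — one local phase per scatterer
    per frame.  Returns ``(per_frame, I)`` with ``per_frame[m] =
    |sum_n a_n exp(i(phi_n + theta_{n,m}))|`` and I their mean.  An
    empty scatterer list gives zeros.
    """
    a = np.asarray(amplitudes, dtype=float).ravel()
    phi = np.asarray(axial_phases, dtype=float).ravel()
    theta = np.atleast_2d(np.asarray(screen_phases, dtype=float))
    if a.size != phi.size:
        raise ValueError("amplitudes and axial_phases must have equal length")
    if a.size == 0:
        return np.zeros(theta.shape[0]), 0.0
    if theta.shape[1] != a.size:
        raise ValueError("screen_phases must have shape (M, N)")
    per_frame = np.abs((a * np.exp(1j * (phi + theta))).sum(axis=1))
    return per_frame, float(per_frame.mean())


def voxel_frames(
    amplitudes: np.ndarray,
    axial_phases: np.ndarray,
    screen_phases,
    n_frames: int | None = None,
) -> np.ndarray:
    """Vectorised per-frame magnitudes for many voxels at once.

    ``amplitudes`` and ``axial_phases`` have shape (V, N).
    ``screen_phases`` is either an (M, V, N) array or a callable
    ``m -> (V, N)`` (used with ``n_frames``) so large studies never
    materialise the full M x V x N phase tensor.  Returns (M, V).
    """
    a = np.asarray(amplitudes, dtype=float)
    phi = np.asarray(axial_phases, dtype=float)
    if a.shape != phi.shape or a.ndim != 2:
        raise ValueError("amplitudes and axial_phases must both be (V, N)")
    base = a * np.exp(1j * phi)
    if callable(screen_phases):
        if n_frames is None:
            raise ValueError("n_frames is required when screen_phases is a callable")
        out = np.empty((n_frames, a.shape[0]))
        for m in range(n_frames):
            out[m] = np.abs((base * np.exp(1j * screen_phases(m))).sum(axis=1))
        return out
    theta = np.asarray(screen_phases, dtype=float)
    if theta.ndim != 3 or theta.shape[1:] != a.shape:
        raise ValueError("screen_phases array must be (M, V, N)")
    return np.abs((base[None] * np.exp(1j * theta)).sum(axis=2))


def washout_factor(
    n_phase_changes: int, n_samples: int = 200_000, seed: int = 0
) -> float:
    """Expected fringe-washout attenuation for K phase changes per A-scan.

    If the diffuser moves fast enough to impose K independent uniform
    phase jumps during one A-scan integration, the detected amplitude is
    attenuated by the mean resultant length of K+1 random unit phasors:
    exactly 1 for K=0, and ~ sqrt(pi/4)/sqrt(K+1) -> 0 as K grows.
    Evaluated by a deterministic (fixed-seed) Monte Carlo average.
    """
    if n_phase_changes < 0:
        raise ValueError("n_phase_changes must be >= 0")
    k = int(n_phase_changes)
    if k == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    # accumulate in blocks to bound memory for large K
    total = 0.0
    done = 0
    block = max(1, int(5e6 // (k + 1)))
    while done < n_samples:
        n = min(block, n_samples - done)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, k + 1))
        total += np.abs(np.exp(1j * phases).mean(axis=1)).sum()
        done += n
    return float(total / n_samples)


def _lateral_weight_sigma(beam: BeamSpec) -> float:
    return beam.main_psf_fwhm_um * FWHM_TO_SIGMA


def _deposit_and_blur(
    rows_um: np.ndarray,
    cols_um: np.ndarray,
    values: np.ndarray,
    extent_rows_um: float,
    extent_cols_um: float,
    pixel_rows_um: float,
    pixel_cols_um: float,
    sigma_rows_um: float,
    sigma_cols_um: float,
    oversample: int = 2,
) -> np.ndarray:
    """Coherent Gaussian-PSF image of point sources on a pixel grid.

    Complex amplitudes are binned onto a grid oversampled by
    ``oversample`` relative to the pixel pitch, convolved with a
    peak-normalised Gaussian kernel (so an isolated unit scatterer at a
    pixel centre maps to amplitude ~1), and sampled at pixel centres.
    """
    fr = pixel_rows_um / oversample
    fc = pixel_cols_um / oversample
    n_r = int(round(extent_rows_um / fr))
    n_c = int(round(extent_cols_um / fc))
    grid = np.zeros((n_r, n_c), dtype=complex)
    ir = np.clip((rows_um / fr).astype(int), 0, n_r - 1)
    ic = np.clip((cols_um / fc).astype(int), 0, n_c - 1)
    np.add.at(grid.real, (ir, ic), values.real)
    np.add.at(grid.imag, (ir, ic), values.imag)

    sr = sigma_rows_um / fr
    sc = sigma_cols_um / fc
    half_r = max(1, int(np.ceil(4 * sr)))
    half_c = max(1, int(np.ceil(4 * sc)))
    kr = np.exp(-0.5 * (np.arange(-half_r, half_r + 1) / sr) ** 2)
    kc = np.exp(-0.5 * (np.arange(-half_c, half_c + 1) / sc) ** 2)
    kernel = np.outer(kr, kc)  # peak 1: amplitude PSF
    out = signal.fftconvolve(grid.real, kernel, mode="same") + 1j * signal.fftconvolve(
        grid.imag, kernel, mode="same"
    )
    # sample at pixel centres
    idx_r = (np.arange(int(round(extent_rows_um / pixel_rows_um))) * oversample
             + oversample // 2)
    idx_c = (np.arange(int(round(extent_cols_um / pixel_cols_um))) * oversample
             + oversample // 2)
    return out[np.ix_(np.clip(idx_r, 0, n_r - 1), np.clip(idx_c, 0, n_c - 1))]


def _frame_offsets(screens, n_frames: int | None) -> list[tuple[float, float]]:
    offs = np.atleast_2d(np.asarray(screens, dtype=float))
    if offs.shape[1] != 2:
        raise ValueError("offsets must be an (M, 2) array of (x, y) um")
    return [tuple(o) for o in offs]


def simulate_frames(
    field: ScattererField,
    beam: BeamSpec,
    sampler: ScreenSampler | None,
    offsets_um: np.ndarray,
    volume: VolumeSpec | None = None,
    noise: NoiseModel | None = None,
    mode: str = "sm",
    seed: int = 0,
    oversample: int = 2,
) -> FrameStack:
    """B-scan frame stack (depth x lateral) of a scatterer field.

    One frame per diffuser offset.  Per pixel the coherent sum runs over
    scatterers weighted by Gaussian lateral (``main_psf_fwhm``) and
    axial (``axial_fwhm``) amplitude PSFs, with round-trip axial phase
    phi_n = 2 k z_n.  The B-scan plane is y = extent_y/2; out-of-plane
    scatterers are down-weighted by the lateral PSF in y.  In ``sm``
    mode theta is sampled from the diffuser phase field at the
    scatterer's lateral position under the per-frame offset; in
    ``conventional`` mode theta = 0 for every frame, so without noise
    all frames are identical (static speckle).  Additive complex noise
    is applied per frame at the pixel level before taking magnitudes.
    """
    volume = volume or field.volume
    noise = noise or NoiseModel(0.0, enabled=False)
    if mode not in ("sm", "conventional"):
        raise ValueError("mode must be 'sm' or 'conventional'")
    offsets = _frame_offsets(offsets_um, None)
    if len(offsets) == 0:
        raise ValueError("need at least one diffuser offset (frame)")
    if mode == "sm" and sampler is None:
        raise ValueError("sm mode requires a ScreenSampler")

    x, y, z = field.positions.T
    sig_lat = _lateral_weight_sigma(beam)
    sig_ax = beam.axial_fwhm_um * FWHM_TO_SIGMA
    y_plane = volume.extent_y / 2.0
    w_y = np.exp(-0.5 * ((y - y_plane) / sig_lat) ** 2)
    base = field.amplitudes * w_y * np.exp(1j * (2.0 * beam.k * z))

    rng = np.random.default_rng(seed)
    frames = []
    meta = []
    for m, off in enumerate(offsets):
        if mode == "sm":
            theta = sampler.sample(x, y, off)
        else:
            theta = 0.0
        vals = base * np.exp(1j * theta) if np.ndim(theta) else base
        img = _deposit_and_blur(
            z, x, vals,
            volume.extent_z, volume.extent_x,
            volume.voxel_dz, volume.voxel_dx,
            sig_ax, sig_lat, oversample,
        )
        img = noise.add(img, rng)
        frames.append(np.abs(img))
        meta.append({"frame": m, "offset_x_um": off[0], "offset_y_um": off[1]})
    return FrameStack(
        data=np.stack(frames),
        pixel_dz_um=volume.voxel_dz,
        pixel_dx_um=volume.voxel_dx,
        frame_meta=pd.DataFrame(meta),
        kind="bscan",
    )


def simulate_enface_frames(
    field: ScattererField,
    beam: BeamSpec,
    sampler: ScreenSampler | None,
    offsets_um: np.ndarray,
    volume: VolumeSpec | None = None,
    noise: NoiseModel | None = None,
    mode: str = "sm",
    seed: int = 0,
    depth_um: float | None = None,
    oversample: int = 2,
) -> FrameStack:
    """En face frame stack (rows=y, cols=x) at a fixed depth plane.

    Scatterers are weighted by the axial PSF around ``depth_um``
    (default: mid-volume) and by the lateral PSF in both x and y; the
    axial phase 2 k z_n of each scatterer is retained, so sub-resolution
    depth structure produces fully developed speckle exactly as in a
    B-scan pixel.
    """
    volume = volume or field.volume
    noise = noise or NoiseModel(0.0, enabled=False)
    if mode not in ("sm", "conventional"):
        raise ValueError("mode must be 'sm' or 'conventional'")
    offsets = _frame_offsets(offsets_um, None)
    if mode == "sm" and sampler is None:
        raise ValueError("sm mode requires a ScreenSampler")
    z0 = volume.extent_z / 2.0 if depth_um is None else depth_um

    x, y, z = field.positions.T
    sig_lat = _lateral_weight_sigma(beam)
    sig_ax = beam.axial_fwhm_um * FWHM_TO_SIGMA
    w_z = np.exp(-0.5 * ((z - z0) / sig_ax) ** 2)
    base = field.amplitudes * w_z * np.exp(1j * (2.0 * beam.k * z))

    rng = np.random.default_rng(seed)
    frames = []
    meta = []
    for m, off in enumerate(offsets):
        theta = sampler.sample(x, y, off) if mode == "sm" else 0.0
        vals = base * np.exp(1j * theta) if np.ndim(theta) else base
        img = _deposit_and_blur(
            y, x, vals,
            volume.extent_y, volume.extent_x,
            volume.voxel_dx, volume.voxel_dx,
            sig_lat, sig_lat, oversample,
        )
        img = noise.add(img, rng)
        frames.append(np.abs(img))
        meta.append({"frame": m, "offset_x_um": off[0], "offset_y_um": off[1]})
    return FrameStack(
        data=np.stack(frames),
        pixel_dz_um=volume.voxel_dx,
        pixel_dx_um=volume.voxel_dx,
        frame_meta=pd.DataFrame(meta),
        kind="enface",
    )
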