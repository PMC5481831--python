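"""Synthetic scatterer phantoms with retained ground truth.

OCT phantoms are emulated as clouds of point scatterers: a homogeneous
turbid medium is a Poisson point process with a stated mean number of
particles per voxel (e.g. a gold-nanosphere agarose gel at 12 particles
per voxel), a resolution phantom is two scatterer-filled blocks adjoined
at a small wedge angle leaving a linearly narrowing scatterer-free gap,
and a bead phantom adds sparse bright point targets on a turbid
background.  Every generator records its ground truth (gap-width ramp,
bead centres) so downstream metrics can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VolumeSpec",
    "ScattererField",
    "generate_uniform_field",
    "generate_gap_phantom",
    "generate_bead_phantom",
]


@dataclass(frozen=True)
class VolumeSpec:
    """Rectangular phantom volume on a regular voxel grid.

    Extents and pitches are in micrometres.  ``voxel_dx`` is the lateral
    pitch (both x and y), ``voxel_dz`` the axial (depth) pitch.  The
    implied voxel grid must be integral: extents are required to be
    whole multiples of the pitch.  Coordinates are right-handed with z
    increasing into the sample; voxel intervals are half-open,
    0-based.
    """

    extent_x: float
    extent_y: float
    extent_z: float
    voxel_dx: float = 2.0
    voxel_dz: float = 2.0

    def __post_init__(self) -> None:
        for name in ("extent_x", "extent_y", "extent_z", "voxel_dx", "voxel_dz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for ext, pitch, name in (
            (self.extent_x, self.voxel_dx, "extent_x"),
            (self.extent_y, self.voxel_dx, "extent_y"),
            (self.extent_z, self.voxel_dz, "extent_z"),
        ):
            n = ext / pitch
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name}={ext} is not an integer multiple of its voxel pitch {pitch}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel grid shape ``(nx, ny, nz)``."""
        return (
            int(round(self.extent_x / self.voxel_dx)),
            int(round(self.extent_y / self.voxel_dx)),
            int(round(self.extent_z / self.voxel_dz)),
        )

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in um^3 (dx * dx * dz)."""
        return self.voxel_dx * self.voxel_dx * self.voxel_dz

    def to_dict(self) -> dict:
        return {
            "extent_x": self.extent_x,
            "extent_y": self.extent_y,
            "extent_z": self.extent_z,
            "voxel_dx": self.voxel_dx,
            "voxel_dz": self.voxel_dz,
        }


@dataclass
class ScattererField:
    """Point scatterers filling a phantom volume.

    ``positions`` is an ``(N, 3)`` array of (x, y, z) in um,
    ``amplitudes`` the nonnegative scattering amplitudes (arbitrary
    units), ``labels`` a per-scatterer class tag (``"background"`` or
    ``"bead"``).  ``ground_truth`` holds generator-specific truth such
    as the per-column gap width or bead centres.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    labels: np.ndarray
    volume: VolumeSpec
    seed: int | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        self.labels = np.asarray(self.labels).ravel()
        n = len(self.positions)
        if len(self.amplitudes) != n or len(self.labels) != n:
            raise ValueError("positions, amplitudes and labels must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")
        ext = np.array([self.volume.extent_x, self.volume.extent_y, self.volume.extent_z])
        if n and (np.any(self.positions < 0) or np.any(self.positions > ext)):
            raise ValueError("scatterer positions fall outside the volume")

    def __len__(self) -> int:
        return len(self.positions)

    def voxel_counts(self) -> np.ndarray:
        """Per-voxel scatterer counts on the volume's grid, shape (nx, ny, nz)."""
        nx, ny, nz = self.volume.shape
        if len(self) == 0:
            return np.zeros((nx, ny, nz), dtype=int)
        ix = np.minimum((self.positions[:, 0] / self.volume.voxel_dx).astype(int), nx - 1)
        iy = np.minimum((self.positions[:, 1] / self.volume.voxel_dx).astype(int), ny - 1)
        iz = np.minimum((self.positions[:, 2] / self.volume.voxel_dz).astype(int), nz - 1)
        counts = np.zeros((nx, ny, nz), dtype=int)
        np.add.at(counts, (ix, iy, iz), 1)
        return counts

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write the columnar scatterer table plus a YAML sidecar.

        The sidecar (``<path>.meta.yaml``) carries the VolumeSpec, seed
        and any ground truth.
        """
        path = Path(path)
        df = pd.DataFrame(
            {
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "z_um": self.positions[:, 2],
                "amplitude": self.amplitudes,
                "label": self.labels,
            }
        )
        df.to_csv(path, index=False, float_format="%.8g")
        meta = {
            "volume": self.volume.to_dict(),
            "seed": self.seed,
            "ground_truth": {
                k: np.asarray(v).tolist() for k, v in self.ground_truth.items()
            },
        }
        Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScattererField":
        path = Path(path)
        df = pd.read_csv(path)
        meta = yaml.safe_load(Path(str(path) + ".meta.yaml").read_text())
        gt = {k: np.asarray(v) for k, v in (meta.get("ground_truth") or {}).items()}
        return cls(
            positions=df[["x_um", "y_um", "z_um"]].to_numpy(),
            amplitudes=df["amplitude"].to_numpy(),
            labels=df["label"].to_numpy(),
            volume=VolumeSpec(**meta["volume"]),
            seed=meta.get("seed"),
            ground_truth=gt,
        )


def _draw_amplitudes(rng: np.random.Generator, n: int, amp_model: str, cv: float) -> np.ndarray:
    if amp_model == "constant":
        return np.ones(n)
    if amp_model == "lognormal":
        if cv < 0:
            raise ValueError("amplitude CV must be nonnegative")
        if cv == 0:
            return np.ones(n)
        sigma2 = np.log1p(cv * cv)
        mu = -0.5 * sigma2  # unit mean
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    raise ValueError(f"unknown amp_model {amp_model!r}")


def _uniform_positions(
    rng: np.random.Generator, volume: VolumeSpec, mean_per_voxel: float
) -> np.ndarray:
    """Poisson counts per voxel, positions uniform within each voxel."""
    nx, ny, nz = volume.shape
    counts = rng.poisson(mean_per_voxel, size=nx * ny * nz)
    total = int(counts.sum())
    vox = np.repeat(np.arange(nx * ny * nz), counts)
    ix, iy, iz = np.unravel_index(vox, (nx, ny, nz))
    u = rng.random((total, 3))
    pos = np.empty((total, 3))
    pos[:, 0] = (ix + u[:, 0]) * volume.voxel_dx
    pos[:, 1] = (iy + u[:, 1]) * volume.voxel_dx
    pos[:, 2] = (iz + u[:, 2]) * volume.voxel_dz
    return pos


def generate_uniform_field(
    volume: VolumeSpec,
    mean_per_voxel: float,
    amp_model: str = "constant",
    amp_cv: float = 0.0,
    seed: int = 0,
) -> ScattererField:
    """Homogeneous turbid phantom: Poisson(mean_per_voxel) scatterers per voxel.

    Per-voxel counts are independent Poisson draws and positions are
    uniform within each voxel, so for a homogeneous field the index of
    dispersion of the counts is ~1.  ``amp_model`` is ``"constant"``
    (all amplitudes 1) or ``"lognormal"`` with coefficient of variation
    ``amp_cv`` (unit mean), modelling particle-size variability.
    """
    if mean_per_voxel <= 0:
        raise ValueError("mean_per_voxel must be strictly positive")
    rng = np.random.default_rng(seed)
    pos = _uniform_positions(rng, volume, mean_per_voxel)
    amps = _draw_amplitudes(rng, len(pos), amp_model, amp_cv)
    labels = np.full(len(pos), "background")
    return ScattererField(pos, amps, labels, volume, seed=seed)


def gap_width_at(x_um: np.ndarray | float, wedge_angle_deg: float) -> np.ndarray:
    """Ground-truth gap width w(x) = x * tan(angle) of the wedge phantom."""
    return np.asarray(x_um, dtype=float) * np.tan(np.deg2rad(wedge_angle_deg))


def generate_gap_phantom(
    volume: VolumeSpec,
    wedge_angle_deg: float,
    mean_per_voxel: float,
    seed: int = 0,
    amp_model: str = "constant",
    amp_cv: float = 0.0,
) -> ScattererField:
    """Two scatterer blocks adjoined at a wedge angle with a narrowing gap.

    The gap separates the blocks along y, centred at ``extent_y / 2``;
    its full width grows linearly from 0 at x=0 as ``w(x) = x tan(angle)``.
    Scatterers inside the gap are removed, and the ground-truth width at
    each lateral voxel-column centre is recorded under
    ``ground_truth["gap_width_um"]`` (plus ``gap_center_um``,
    ``column_x_um`` and ``wedge_angle_deg``).
    """
    if not (0 <= wedge_angle_deg < 10):
        raise ValueError("wedge_angle_deg must lie in [0, 10)")
    base = generate_uniform_field(volume, mean_per_voxel, amp_model, amp_cv, seed)
    x = base.positions[:, 0]
    y = base.positions[:, 1]
    half_w = 0.5 * gap_width_at(x, wedge_angle_deg)
    y_c = volume.extent_y / 2.0
    keep = np.abs(y - y_c) >= half_w
    nx = volume.shape[0]
    col_x = (np.arange(nx) + 0.5) * volume.voxel_dx
    gt = {
        "column_x_um": col_x,
        "gap_width_um": gap_width_at(col_x, wedge_angle_deg),
        "gap_center_um": np.array([y_c]),
        "wedge_angle_deg": np.array([wedge_angle_deg]),
    }
    return ScattererField(
        base.positions[keep],
        base.amplitudes[keep],
        base.labels[keep],
        volume,
        seed=seed,
        ground_truth=gt,
    )


def generate_bead_phantom(
    volume: VolumeSpec,
    background_per_voxel: float,
    bead_density_per_voxel: float,
    bead_diameter_um: float = 3.05,
    bead_amp_ratio: float = 10.0,
    seed: int = 0,
    amp_model: str = "constant",
    amp_cv: float = 0.0,
) -> ScattererField:
    """Sparse bright beads in a turbid background.

    Each bead is a single dominant point scatterer at the bead centre
    with amplitude ``bead_amp_ratio`` times the mean background
    amplitude (the bead diameter, ~3 um, is at or below the lateral
    PSF, so beads act as bright point targets).  Bead centres are
    recorded in ``ground_truth["bead_centers_um"]``.  With
    ``bead_density_per_voxel=0`` the output is identical to
    :func:`generate_uniform_field` under the same seed.
    """
    if bead_density_per_voxel < 0:
        raise ValueError("bead_density_per_voxel must be nonnegative")
    if bead_amp_ratio <= 0:
        raise ValueError("bead_amp_ratio must be strictly positive")
    bg = generate_uniform_field(volume, background_per_voxel, amp_model, amp_cv, seed)
    if bead_density_per_voxel == 0:
        bg.ground_truth = {"bead_centers_um": np.zeros((0, 3)), "bead_diameter_um": np.array([bead_diameter_um])}
        return bg
    # independent stream so the background is unchanged by the bead draw
    rng_b = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    n_beads = rng_b.poisson(bead_density_per_voxel * volume.n_voxels)
    ext = np.array([volume.extent_x, volume.extent_y, volume.extent_z])
    centers = rng_b.random((n_beads, 3)) * ext
    mean_bg_amp = float(bg.amplitudes.mean()) if len(bg) else 1.0
    pos = np.vstack([bg.positions, centers])
    amps = np.concatenate([bg.amplitudes, np.full(n_beads, bead_amp_ratio * mean_bg_amp)])
    labels = np.concatenate([bg.labels, np.full(n_beads, "bead")])
    gt = {
        "bead_centers_um": centers,
        "bead_diameter_um": np.array([bead_diameter_um]),
    }
    return ScattererField(pos, amps, labels, volume, seed=seed, ground_truth=gt)
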