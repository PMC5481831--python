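"""Speckle statistics: normalized s.d., the 1/sqrt(M) law, distributions.

For fully developed speckle the single-frame amplitude in a homogeneous
region is Rayleigh distributed, with contrast (s.d./mean)
sqrt(4/pi - 1) ~= 0.5227.  Averaging M frames with mutually
uncorrelated speckle reduces the speckle-attributable contrast as
1/sqrt(M); the part of the normalized s.d. C that survives unlimited
averaging (C_base) reflects the sample itself — for randomly dispersed
particles, the Poisson spread of the per-voxel scatterer number, with
limiting pixel values I ~= a sqrt(N pi) / 2, N ~ Poisson(lambda).

The normalized speckle s(M) isolates the decaying component by a
variance decomposition:

    s(M) = sqrt(max(C(M)^2 - C_base^2, 0)) / sqrt(C(1)^2 - C_base^2).

All statistics use linear-scale magnitudes and the population (1/n)
standard-deviation convention, so small closed-form examples are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RAYLEIGH_CONTRAST",
    "SpeckleReport",
    "normalized_std",
    "speckle_curve",
    "distribution_analysis",
    "iqr_by_m",
    "sm_limit_values",
]

RAYLEIGH_CONTRAST = float(np.sqrt(4.0 / np.pi - 1.0))


@dataclass
class SpeckleReport:
    """Tables and fits summarising a speckle-reduction measurement."""

    c_by_m: pd.DataFrame
    normalized_speckle_by_m: pd.DataFrame
    fit: dict
    c_base: float
    distribution: dict = field(default_factory=dict)
    region: str = "full frame"

    def to_csv(self, directory: str | Path, prefix: str = "speckle") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.c_by_m.to_csv(directory / f"{prefix}_c_by_m.csv", index=False,
                           float_format="%.10g")
        self.normalized_speckle_by_m.to_csv(
            directory / f"{prefix}_normalized_speckle.csv", index=False,
            float_format="%.10g",
        )
        summary = pd.DataFrame([{**self.fit, "c_base": self.c_base,
                                 "region": self.region}])
        summary.to_csv(directory / f"{prefix}_fit.csv", index=False,
                       float_format="%.10g")

    def plot(self, path: str | Path) -> None:
        """Optional log-log plot of s(M) against the 1/sqrt(M) law."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.normalized_speckle_by_m["M"].to_numpy(float)
        s = self.normalized_speckle_by_m["normalized_speckle"].to_numpy(float)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.loglog(m, s, "o", ms=3, label="measured")
        ax.loglog(m, 1 / np.sqrt(m), "-", label=r"$1/\sqrt{M}$")
        ax.set_xlabel("M (averages)")
        ax.set_ylabel("normalized speckle")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def normalized_std(
    image: np.ndarray, mask: np.ndarray | None = None, min_pixels: int = 100
) -> float:
    """Normalized s.d. C = population s.d. / mean over a region.

    Computed on LINEAR-scale magnitudes.  The region must contain at
    least ``min_pixels`` pixels and have a strictly positive mean.
    """
    image = np.asarray(image, dtype=float)
    vals = image[np.asarray(mask, bool)] if mask is not None else image.ravel()
    if vals.size < min_pixels:
        raise ValueError(f"region has {vals.size} pixels; need >= {min_pixels}")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("region mean must be strictly positive")
    return float(vals.std() / mean)


def _running_c(
    data: np.ndarray, mask: np.ndarray | None, m_list, min_pixels: int
) -> pd.DataFrame:
    rows = []
    csum = np.zeros_like(data[0], dtype=float)
    m_set = sorted(set(int(m) for m in m_list))
    next_i = 0
    for m in range(1, m_set[-1] + 1):
        csum += data[m - 1]
        if next_i < len(m_set) and m == m_set[next_i]:
            rows.append({"M": m, "C": normalized_std(csum / m, mask, min_pixels)})
            next_i += 1
    return pd.DataFrame(rows)


def speckle_curve(
    stack,
    mask: np.ndarray | None = None,
    m_list=None,
    c_base: float | None = None,
    min_pixels: int = 100,
    region: str = "full frame",
) -> SpeckleReport:
    """C(M) and the normalized speckle s(M) with a log-log power-law fit.

    ``stack`` is a FrameStack or an (M, ...) array of linear magnitudes.
    For each requested M, the first M frames are averaged linearly and C
    computed over the masked region.  ``c_base`` is the intrinsic
    (speckle-free) component of C; pass 0 for a pure-speckle simulation
    with constant per-voxel scatterer number.  If None it is estimated
    as C at the largest available M (the best speckle-suppressed
    average at hand).  ``fit`` reports the least-squares slope of
    log s vs log M (expected -0.5 for independent frames), its 95%
    confidence half-width, amplitude and r^2.
    """
    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    if data.ndim < 2:
        raise ValueError("stack must be (M, ...) frames")
    n_frames = data.shape[0]
    if m_list is None:
        m_list = np.arange(1, n_frames + 1)
    m_list = np.asarray(sorted(set(int(m) for m in m_list)))
    if m_list[-1] > n_frames:
        raise ValueError(f"max(M)={m_list[-1]} exceeds available frames {n_frames}")
    if m_list[0] < 1:
        raise ValueError("M values must be >= 1")

    c_df = _running_c(data, mask, m_list, min_pixels)
    if c_base is None:
        c_base = float(c_df["C"].iloc[-1])
    c1 = float(c_df.loc[c_df["M"] == c_df["M"].min(), "C"].iloc[0])
    denom = c1 * c1 - c_base * c_base
    if denom <= 0:
        raise ValueError(
            "degenerate normalization: C(1)^2 <= C_base^2 (no speckle component)"
        )
    s = np.sqrt(np.maximum(c_df["C"].to_numpy() ** 2 - c_base * c_base, 0.0) / denom)
    s_df = pd.DataFrame({"M": c_df["M"], "normalized_speckle": s})

    pos = s > 0
    logm = np.log(c_df["M"].to_numpy(float)[pos])
    logs = np.log(s[pos])
    if len(logm) >= 3 and np.ptp(logm) > 0:
        res = stats.linregress(logm, logs)
        fit = {
            "exponent": float(res.slope),
            "exponent_ci95": float(1.96 * res.stderr),
            "amplitude": float(np.exp(res.intercept)),
            "r2": float(res.rvalue**2),
        }
    else:
        fit = {"exponent": np.nan, "exponent_ci95": np.nan,
               "amplitude": np.nan, "r2": np.nan}
    return SpeckleReport(
        c_by_m=c_df,
        normalized_speckle_by_m=s_df,
        fit=fit,
        c_base=float(c_base),
        region=region,
    )


def sm_limit_values(lambda_n: float, amplitude: float = 1.0, n_max: int | None = None):
    """Support and probabilities of the speckle-free limit distribution.

    In the fully averaged limit a voxel with N scatterers of amplitude a
    converges to a * sqrt(N pi) / 2 (the Rayleigh mean with
    sigma^2 = N a^2 / 2), so pixel values follow the mapped Poisson law
    I_N = a sqrt(N pi)/2 with N ~ Poisson(lambda_n).
    """
    if n_max is None:
        n_max = int(lambda_n + 12 * np.sqrt(lambda_n) + 20)
    n = np.arange(0, n_max + 1)
    p = stats.poisson.pmf(n, lambda_n)
    v = amplitude * np.sqrt(n * np.pi) / 2.0
    return v, p


def _poisson_sqrt_moments(lam: float) -> tuple[float, float]:
    """(E sqrt(N), E N) for N ~ Poisson(lam)."""
    n_max = int(lam + 12 * np.sqrt(lam) + 20)
    n = np.arange(0, n_max + 1)
    p = stats.poisson.pmf(n, lam)
    return float((np.sqrt(n) * p).sum()), lam


def _fit_sm_limit(values: np.ndarray) -> tuple[float, float]:
    """Moment-matched (lambda_n, amplitude) of the mapped-Poisson model."""
    m1 = values.mean()
    cv2 = values.var() / (m1 * m1)

    def gap(lam: float) -> float:
        es, en = _poisson_sqrt_moments(lam)
        return en / (es * es) - 1.0 - cv2

    lo, hi = 1e-2, 1e4
    if gap(lo) < 0:  # extremely broad: lambda below lower bound
        lam = lo
    elif gap(hi) > 0:  # extremely narrow
        lam = hi
    else:
        lam = optimize.brentq(gap, lo, hi, xtol=1e-6, rtol=1e-10)
    es, _ = _poisson_sqrt_moments(lam)
    amp = m1 / (np.sqrt(np.pi) / 2.0 * es)
    return float(lam), float(amp)


def _ks_distance_discrete(values: np.ndarray, support: np.ndarray,
                          pmf: np.ndarray) -> float:
    """sup |F_emp - F_model| for a discrete model distribution."""
    values = np.sort(values)
    cdf_model = np.cumsum(pmf)
    # evaluate both CDFs at the model support points (sup over jumps)
    emp_at = np.searchsorted(values, support, side="right") / len(values)
    emp_before = np.searchsorted(values, support, side="left") / len(values)
    d = np.max(np.abs(emp_at - cdf_model))
    d_pre = np.max(np.abs(emp_before - np.concatenate([[0.0], cdf_model[:-1]])))
    return float(max(d, d_pre))


def distribution_analysis(
    pixels: np.ndarray, model: str = "rayleigh", min_pixels: int = 1000
) -> dict:
    """Fit a pixel-value distribution model and report goodness of fit.

    ``model="rayleigh"`` fits a maximum-likelihood Rayleigh scale (loc
    fixed at 0) and reports the Kolmogorov-Smirnov distance — the
    single-frame speckle hypothesis.  ``model="sm_limit"`` compares the
    empirical distribution to the mapped-Poisson prediction
    I = a sqrt(N pi)/2, N ~ Poisson(lambda_n), with (lambda_n, a)
    moment-matched, and reports the analogous sup-distance — the
    hypothesis that averaging has exposed the scatterer-number
    statistics of the phantom.
    """
    vals = np.asarray(pixels, dtype=float).ravel()
    if vals.size < min_pixels:
        raise ValueError(f"need >= {min_pixels} pixels, got {vals.size}")
    if model == "rayleigh":
        _, scale = stats.rayleigh.fit(vals, floc=0)
        ks = stats.kstest(vals, "rayleigh", args=(0, scale))
        return {
            "model": "rayleigh",
            "scale": float(scale),
            "ks_distance": float(ks.statistic),
        }
    if model == "sm_limit":
        lam, amp = _fit_sm_limit(vals)
        support, pmf = sm_limit_values(lam, amp)
        d = _ks_distance_discrete(vals, support, pmf)
        return {
            "model": "sm_limit",
            "lambda_n": lam,
            "amplitude": amp,
            "ks_distance": d,
        }
    raise ValueError("model must be 'rayleigh' or 'sm_limit'")


def iqr_by_m(stack, m_list, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Interquartile range of the M-frame average versus M.

    A narrowing IQR with M is the signature of speckle suppression; a
    static speckle pattern (conventional acquisition) leaves it
    essentially unchanged.
    """
    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    rows = []
    for m in sorted(set(int(m) for m in m_list)):
        avg = data[:m].mean(axis=0)
        vals = avg[np.asarray(mask, bool)] if mask is not None else avg.ravel()
        q1, q3 = np.percentile(vals, [25, 75])
        rows.append({"M": m, "iqr": float(q3 - q1)})
    return pd.DataFrame(rows)
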