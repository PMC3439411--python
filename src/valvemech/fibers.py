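"""Fiber orientation analysis by 2-D Fourier transform.

A fibrous texture concentrates spectral power perpendicular to its stripes,
so the angular distribution of 2-D FFT power — rotated by 90 degrees — is an
estimate of the fiber orientation distribution.  The fiber alignment index
(FAI) is the fraction of angular power lying within a half-width (default
10 degrees) of the loading axis; it is 1 when all power sits on the axis and
20/180 for a perfectly isotropic texture at the default window.

Angles are axial (period 180 degrees), measured from the +x (loading,
column) axis toward +y (row), in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ZeroPowerError
from .stats import linear_trend

DEFAULT_AXIS_DEG = 0.0
DEFAULT_HALF_WIDTH_DEG = 10.0


@dataclass(frozen=True)
class OrientationSpectrum:
    """Angular power distribution of a fiber image over [0, 180) degrees."""

    power: np.ndarray
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        n_expected = int(round(180.0 / self.bin_width))
        if len(self.power) != n_expected:
            raise ValueError(f"expected {n_expected} bins of {self.bin_width} deg, got {len(self.power)}")
        if np.any(self.power < 0):
            raise ValueError("bin powers must be nonnegative")

    @property
    def angle_bins(self) -> np.ndarray:
        """Bin centers in degrees: (i + 1/2) * bin_width over [0, 180)."""
        return (np.arange(len(self.power)) + 0.5) * self.bin_width

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class AlignmentTrajectory:
    """Per-stretch alignment index values with their linear trend."""

    stretch: np.ndarray
    fai: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def orientation_spectrum(
    image: np.ndarray,
    bin_width: float = 1.0,
    annulus: tuple[float, float] = (0.1, 0.8),
    window: bool = True,
) -> OrientationSpectrum:
    """Angular power spectrum of a grayscale raster.

    The image is mean-subtracted, apodized by a raised-cosine (Hann) window,
    and Fourier transformed; power is accumulated into angular bins over a
    radial annulus (``annulus`` in fractions of the Nyquist frequency, DC
    excluded) by nearest-bin assignment.  Spectral angles are rotated by
    +90 degrees so that bins index *fiber* orientation, not stripe normals.

    Raises
    ------
    ZeroPowerError
        If the image is constant.
    ValueError
        If the raster is smaller than 64 x 64 or not 2-D.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    if min(img.shape) < 64:
        raise ValueError("raster must be at least 64 x 64")
    if np.ptp(img) == 0:
        raise ZeroPowerError("constant image has no orientation signal")

    img = img - img.mean()
    if window:
        wr = np.hanning(img.shape[0])
        wc = np.hanning(img.shape[1])
        img = img * np.outer(wr, wc)

    power = np.abs(np.fft.fft2(img)) ** 2
    fr = np.fft.fftfreq(img.shape[0])[:, None]  # row (y) frequency, cycles/px
    fc = np.fft.fftfreq(img.shape[1])[None, :]  # col (x) frequency
    radius = np.hypot(fr / 0.5, fc / 0.5)  # in fractions of Nyquist
    keep = (radius >= annulus[0]) & (radius <= annulus[1])
    keep[0, 0] = False

    ang = (np.degrees(np.arctan2(fr, fc)) + 90.0) % 180.0  # fiber angle
    n_bins = int(round(180.0 / bin_width))
    bins = np.minimum((ang[np.broadcast_to(keep, power.shape)] / bin_width).astype(int), n_bins - 1)
    hist = np.zeros(n_bins)
    np.add.at(hist, bins, power[keep])
    # The Cartesian grid is anisotropic in angle (exact-axis and diagonal
    # samples pile into single bins); dividing by the per-bin sample count
    # estimates the angular power *density*, which is what the bins report.
    counts = np.zeros(n_bins)
    np.add.at(counts, bins, 1.0)
    hist = np.divide(hist, counts, out=np.zeros_like(hist), where=counts > 0)
    if hist.sum() == 0:
        raise ZeroPowerError("no spectral power inside the annulus")
    return OrientationSpectrum(power=hist, bin_width=bin_width)


def fai(
    spectrum: OrientationSpectrum,
    axis: float = DEFAULT_AXIS_DEG,
    half_width: float = DEFAULT_HALF_WIDTH_DEG,
) -> float:
    """Fiber alignment index: angular power fraction within ``half_width``
    degrees (axial distance, period 180) of ``axis``."""
    if not 0.0 < half_width <= 90.0:
        raise ValueError(f"half_width must lie in (0, 90], got {half_width!r}")
    centers = spectrum.angle_bins
    dist = np.abs((centers - axis + 90.0) % 180.0 - 90.0)
    inside = dist <= half_width + 1e-9
    return float(spectrum.power[inside].sum() / spectrum.total_power)


def dominant_angle(spectrum: OrientationSpectrum) -> float:
    """Bin-center angle of maximum power, degrees in [0, 180)."""
    return float(spectrum.angle_bins[int(np.argmax(spectrum.power))])


def fai_trajectory(
    images: Sequence[tuple[float, np.ndarray]],
    axis: float = DEFAULT_AXIS_DEG,
    half_width: float = DEFAULT_HALF_WIDTH_DEG,
    bin_width: float = 1.0,
) -> AlignmentTrajectory:
    """Alignment index per stretch level and its least-squares linear trend.

    ``images`` is a sequence of ``(stretch, raster)`` pairs; a failure in any
    level's spectrum is re-raised carrying the level identity.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 stretch levels")
    lam, values = [], []
    for stretch, img in images:
        try:
            spec = orientation_spectrum(img, bin_width=bin_width)
        except (ZeroPowerError, ValueError) as exc:
            raise type(exc)(f"at stretch {stretch:g}: {exc}") from exc
        lam.append(float(stretch))
        values.append(fai(spec, axis=axis, half_width=half_width))
    lam = np.asarray(lam)
    values = np.asarray(values)
    slope, intercept, r2 = linear_trend(lam, values)
    return AlignmentTrajectory(stretch=lam, fai=values, slope=slope, intercept=intercept, r_squared=r2)


def trajectory_from_directory(
    scene_dir: str | Path,
    manifest: str | Path | None = None,
    axis: float = DEFAULT_AXIS_DEG,
    half_width: float = DEFAULT_HALF_WIDTH_DEG,
) -> tuple[AlignmentTrajectory, pd.DataFrame]:
    """Run the alignment trajectory over a directory of per-stretch TIFFs.

    The manifest CSV (``filename, stretch``; defaults to ``manifest.csv`` in
    the directory) names one raster per stretch level.  Returns the
    trajectory and a tidy ``stretch, fai`` table.
    """
    import tifffile

    scene_dir = Path(scene_dir)
    manifest = Path(manifest) if manifest is not None else scene_dir / "manifest.csv"
    table = pd.read_csv(manifest).sort_values("stretch")
    images = [
        (float(row.stretch), tifffile.imread(scene_dir / row.filename))
        for row in table.itertuples()
    ]
    traj = fai_trajectory(images, axis=axis, half_width=half_width)
    tidy = pd.DataFrame({"stretch": traj.stretch, "fai": traj.fai})
    return traj, tidy
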