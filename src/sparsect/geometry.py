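"""Parallel-beam acquisition geometry, projector, adjoint, and FBP.

The scanner model is 2-D parallel beam: at view angle ``theta`` every ray is
perpendicular to a linear detector of ``n_bins`` bins, and the detector offset
of bin ``b`` is ``(b - (n_bins - 1)/2) * pixel_spacing``.  A ray with offset
``t`` is the line ``x*cos(theta) + y*sin(theta) = t`` in image coordinates
centred on the pixel grid.  The projector is ray-driven (Joseph's method):
each ray marches along its dominant axis and linearly interpolates the image
across the other axis, accumulating intersection length.  The backprojector
applies the exact transpose of those interpolation weights, so
``<A x, y> == <x, A^T y>`` holds to rounding error -- this adjoint identity is
what the data-fidelity gradient ``2 A^T (A x - y)`` relies on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as _fft


class GeometryError(ValueError):
    """Invalid geometry definition or shape mismatch between operands."""


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition description.

    Parameters
    ----------
    n_views : int
        Number of equally spaced projection angles.
    n_bins : int
        Number of detector bins; bin width equals ``pixel_spacing``.
    angular_span_deg : float
        Total angular coverage in degrees, in (0, 360].  Angles are
        ``k * angular_span_deg / n_views`` for ``k = 0 .. n_views - 1``
        (endpoint excluded, so a 180-degree scan has no duplicated
        opposing view).
    image_size : int
        Side length in pixels of the square reconstruction grid.
    pixel_spacing : float
        Physical width of one pixel (and of one detector bin).
    """

    n_views: int
    n_bins: int = 128
    angular_span_deg: float = 180.0
    image_size: int = 128
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise GeometryError(f"n_views must be >= 1, got {self.n_views}")
        if self.n_bins < 1:
            raise GeometryError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.image_size < 2:
            raise GeometryError(f"image_size must be >= 2, got {self.image_size}")
        if not (0.0 < self.angular_span_deg <= 360.0):
            raise GeometryError(
                f"angular_span_deg must be in (0, 360], got {self.angular_span_deg}"
            )
        if not (self.pixel_spacing > 0):
            raise GeometryError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")

    @property
    def angles_rad(self) -> np.ndarray:
        """View angles in radians, measured from the +x axis."""
        span = np.deg2rad(self.angular_span_deg)
        return np.arange(self.n_views) * span / self.n_views

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_views, self.n_bins)

    def with_views(self, n_views: int) -> "Geometry":
        """Same scanner with a different number of views."""
        return Geometry(
            n_views=n_views,
            n_bins=self.n_bins,
            angular_span_deg=self.angular_span_deg,
            image_size=self.image_size,
            pixel_spacing=self.pixel_spacing,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Geometry":
        with open(path) as fh:
            return cls(**json.load(fh))


def inscribed_circle_mask(geometry: Geometry) -> np.ndarray:
    """Boolean mask of pixels inside the grid's inscribed circle.

    FBP is only trustworthy there; reconstruction metrics are evaluated
    inside this mask.
    """
    n = geometry.image_size
    c = (n - 1) / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    return (ii - c) ** 2 + (jj - c) ** 2 <= (n / 2.0) ** 2


def _check_image(image: np.ndarray, geometry: Geometry) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    n = geometry.image_size
    if image.shape != (n, n):
        raise GeometryError(
            f"image shape {image.shape} does not match geometry ({n}, {n})"
        )
    if not np.all(np.isfinite(image)):
        raise GeometryError("image contains non-finite pixels")
    return image


def _check_sinogram(sinogram: np.ndarray, geometry: Geometry) -> np.ndarray:
    sinogram = np.asarray(sinogram, dtype=np.float64)
    if sinogram.shape != geometry.sinogram_shape:
        raise GeometryError(
            f"sinogram shape {sinogram.shape} does not match geometry "
            f"{geometry.sinogram_shape}"
        )
    return sinogram


@lru_cache(maxsize=8)
def _ray_coefficients(geometry: Geometry):
    """Per-view interpolation weights shared by projector and adjoint.

    For each view returns ``(rows, cols, weights)`` flattened over
    (driving-axis sample, bin): the sinogram entry for bin b accumulates
    ``weights * image[rows, cols]`` for all samples of that bin, and the
    adjoint scatters with identical weights.  Computing both operators from
    one table makes adjointness exact by construction.
    """
    n = geometry.image_size
    nb = geometry.n_bins
    s = geometry.pixel_spacing
    c = (n - 1) / 2.0
    bc = (nb - 1) / 2.0
    t_over_s = np.arange(nb) - bc  # bin offsets in pixel units

    views = []
    for theta in geometry.angles_rad:
        ct, st = np.cos(theta), np.sin(theta)
        idx = np.arange(n)
        if abs(ct) >= abs(st):
            # drive along rows: y fixed per row, interpolate along columns
            # x*ct + y*st = t  ->  col = (t/s - (row - c)*st)/ct + c
            f = (t_over_s[None, :] - (idx[:, None] - c) * st) / ct + c
            length = s / abs(ct)
            drive_is_row = True
        else:
            # drive along columns: x fixed per column, interpolate along rows
            f = (t_over_s[None, :] - (idx[:, None] - c) * ct) / st + c
            length = s / abs(st)
            drive_is_row = False

        valid = (f >= 0.0) & (f <= n - 1)
        j0 = np.clip(np.floor(f).astype(np.intp), 0, n - 2)
        w = f - j0

        drive = np.broadcast_to(idx[:, None], f.shape)
        bins = np.broadcast_to(np.arange(nb)[None, :], f.shape)

        v = valid.ravel()
        j0v = j0.ravel()[v]
        wv = w.ravel()[v]
        dv = drive.ravel()[v]
        bv = bins.ravel()[v]

        # two interpolation taps per sample
        taps_idx = np.concatenate([j0v, j0v + 1])
        taps_w = np.concatenate([(1.0 - wv), wv]) * length
        taps_drive = np.concatenate([dv, dv])
        taps_bins = np.concatenate([bv, bv])

        if drive_is_row:
            rows, cols = taps_drive, taps_idx
        else:
            rows, cols = taps_idx, taps_drive
        views.append((rows, cols, taps_bins, taps_w))
    return views


def forward_project(image: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Apply the projection operator A: image -> sinogram of line integrals."""
    image = _check_image(image, geometry)
    sino = np.zeros(geometry.sinogram_shape)
    for v, (rows, cols, bins, w) in enumerate(_ray_coefficients(geometry)):
        np.add.at(sino[v], bins, w * image[rows, cols])
    return sino


def back_project(sinogram: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Apply the exact adjoint A^T: sinogram -> image."""
    sinogram = _check_sinogram(sinogram, geometry)
    image = np.zeros((geometry.image_size, geometry.image_size))
    for v, (rows, cols, bins, w) in enumerate(_ray_coefficients(geometry)):
        np.add.at(image, (rows, cols), w * sinogram[v, bins])
    return image


def _ramp_filter(n_pad: int, pixel_spacing: float) -> np.ndarray:
    """Frequency response of the discrete Ram-Lak (ramp) filter.

    Built from the band-limited spatial-domain kernel rather than |omega|
    directly, which avoids the DC bias of the naive frequency ramp.
    """
    # spatial kernel h[0] = 1/4, h[odd n] = -1/(pi n)^2, h[even n] = 0
    orders = np.concatenate(
        (np.arange(1, n_pad / 2 + 1, 2, dtype=int),
         np.arange(n_pad / 2 - 1, 0, -2, dtype=int))
    )
    h = np.zeros(n_pad)
    h[0] = 0.25
    h[1::2] = -1.0 / (np.pi * orders) ** 2
    return 2.0 * np.real(_fft.fft(h)) / pixel_spacing


def fbp(sinogram: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Filtered backprojection: ramp filter each view, backproject, scale.

    Uses the Ram-Lak filter with zero-padding to at least twice the next
    power of two, pixel-driven backprojection with linear interpolation
    along the detector, and the standard parallel-beam scale
    ``pi / (2 * n_views)``.
    """
    sinogram = _check_sinogram(sinogram, geometry)
    if geometry.n_bins < 2:
        raise GeometryError("FBP requires n_bins >= 2")

    nb = geometry.n_bins
    n_pad = max(64, int(2 ** np.ceil(np.log2(2 * nb))))
    filt = _ramp_filter(n_pad, geometry.pixel_spacing)
    padded = np.zeros((geometry.n_views, n_pad))
    padded[:, :nb] = sinogram
    filtered = np.real(_fft.ifft(_fft.fft(padded, axis=1) * filt[None, :], axis=1))
    filtered = filtered[:, :nb]

    n = geometry.image_size
    c = (n - 1) / 2.0
    bc = (nb - 1) / 2.0
    xs = np.arange(n) - c
    jj, ii = np.meshgrid(xs, xs)  # ii: row offsets (y), jj: col offsets (x)

    recon = np.zeros((n, n))
    for v, theta in enumerate(geometry.angles_rad):
        # detector coordinate of each pixel centre, in bin units
        t = jj * np.cos(theta) + ii * np.sin(theta) + bc
        b0 = np.clip(np.floor(t).astype(np.intp), 0, nb - 2)
        w = t - b0
        inside = (t >= 0.0) & (t <= nb - 1)
        prof = filtered[v]
        recon += np.where(inside, (1.0 - w) * prof[b0] + w * prof[b0 + 1], 0.0)
    recon *= np.pi / (2.0 * geometry.n_views)
    return recon
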