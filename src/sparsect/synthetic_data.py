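"""Random anatomical-looking phantoms and the labelled good/bad FBP corpus.

Real patient slices are not shipped with this package.  What the classifier
actually needs from its training data is the property its own analysis
exploits: a bounded body containing piecewise-smooth structures with sharp
boundaries, so that few-view reconstructions show streak (angular-aliasing)
artifacts and full-view reconstructions do not.  The generator therefore
draws an elliptical soft-tissue body containing a random number of
contrast ellipses, renders every phantom entirely inside the grid's
inscribed circle, and reconstructs each one twice with FBP: from a
few-view sinogram (label 1, "bad") and from a full-view sinogram
(label 0, "good").
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

from .geometry import Geometry, fbp, forward_project


class ConfigError(ValueError):
    """Invalid phantom or corpus configuration."""


@dataclass(frozen=True)
class PhantomConfig:
    """Distribution of the random ellipse phantoms.

    ``intensity_range`` is the additive contrast of interior structures
    relative to ``body_intensity``; negatives carve darker regions (air,
    low-density tissue), positives brighter ones (bone-like).  Noise, when
    enabled, is i.i.d. Gaussian added to the sinogram.
    """

    image_size: int = 128
    n_ellipses_range: tuple[int, int] = (3, 8)
    intensity_range: tuple[float, float] = (-0.5, 0.8)
    body_intensity: float = 1.0
    noise_model: str = "none"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_ellipses_range
        if lo > hi or lo < 0:
            raise ConfigError(f"empty n_ellipses_range {self.n_ellipses_range}")
        if self.intensity_range[0] > self.intensity_range[1]:
            raise ConfigError(f"empty intensity_range {self.intensity_range}")
        if self.noise_model not in ("none", "gaussian"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.image_size < 8:
            raise ConfigError("image_size must be >= 8")


@dataclass
class LabeledSample:
    """One FBP reconstruction with its completeness label.

    label 1 = reconstructed from the few-view (incomplete) sinogram,
    label 0 = reconstructed from the full-view (complete) sinogram.
    """

    image: np.ndarray
    label: int
    seed: int
    phantom_index: int
    n_views: int


def _ellipse_mask(n: int, cx: float, cy: float, a: float, b: float,
                  phi: float) -> np.ndarray:
    """Boolean mask of the ellipse centred at (cx, cy) in pixel coordinates."""
    ii, jj = np.mgrid[0:n, 0:n]
    x = jj - cx
    y = ii - cy
    xr = x * np.cos(phi) + y * np.sin(phi)
    yr = -x * np.sin(phi) + y * np.cos(phi)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, index: int) -> np.ndarray:
    """Render phantom number ``index``; deterministic in (config.seed, index).

    The body ellipse and every interior structure are kept inside the
    inscribed circle of the grid, and the result is clipped to be
    nonnegative (attenuation coefficients cannot be negative).
    """
    if index < 0:
        raise ConfigError(f"index must be >= 0, got {index}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    n = config.image_size
    c = (n - 1) / 2.0
    r_circle = n / 2.0

    # body: near-centred ellipse with semi-axes well inside the circle
    a_body = rng.uniform(0.70, 0.92) * r_circle
    b_body = rng.uniform(0.70, 0.92) * r_circle
    phi_body = rng.uniform(0.0, np.pi)
    img = np.zeros((n, n))
    body = _ellipse_mask(n, c, c, a_body, b_body, phi_body)
    img[body] = config.body_intensity

    k = int(rng.integers(config.n_ellipses_range[0],
                         config.n_ellipses_range[1] + 1))
    for _ in range(k):
        for _attempt in range(50):
            a = rng.uniform(0.05, 0.35) * r_circle
            b = rng.uniform(0.05, 0.35) * r_circle
            phi = rng.uniform(0.0, np.pi)
            # place the structure's bounding circle inside the body ellipse
            r_max = max(a, b)
            margin = 1.0 - r_max / min(a_body, b_body)
            if margin <= 0:
                continue
            rho = np.sqrt(rng.uniform()) * margin
            ang = rng.uniform(0.0, 2 * np.pi)
            # unit-disk sample mapped through the body ellipse's frame
            ux, uy = rho * np.cos(ang), rho * np.sin(ang)
            ex = a_body * ux * np.cos(phi_body) - b_body * uy * np.sin(phi_body)
            ey = a_body * ux * np.sin(phi_body) + b_body * uy * np.cos(phi_body)
            cx, cy = c + ex, c + ey
            contrast = rng.uniform(*config.intensity_range)
            img += contrast * _ellipse_mask(n, cx, cy, a, b, phi)
            break
    return np.clip(img, 0.0, None)


def _noisy(sino: np.ndarray, config: PhantomConfig, rng: np.random.Generator
           ) -> np.ndarray:
    if config.noise_model == "gaussian" and config.noise_sigma > 0:
        return sino + rng.normal(0.0, config.noise_sigma, size=sino.shape)
    return sino


def build_corpus(config: PhantomConfig, n_pairs: int, few_view_geom: Geometry,
                 full_view_geom: Geometry) -> list[LabeledSample]:
    """Build ``2 * n_pairs`` labelled FBP reconstructions.

    Each phantom is projected with both geometries and reconstructed with
    FBP; the few-view reconstruction gets label 1, the full-view one
    label 0.  The same phantom underlies both labels of a pair -- the
    classification task only needs the two classes to come from the same
    image population, not from disjoint subjects.
    """
    if n_pairs < 1:
        raise ConfigError(f"n_pairs must be >= 1, got {n_pairs}")
    if few_view_geom.with_views(full_view_geom.n_views) != full_view_geom:
        raise ConfigError("the two geometries must differ only in n_views")
    if few_view_geom.image_size != config.image_size:
        raise ConfigError("geometry image_size does not match PhantomConfig")

    samples: list[LabeledSample] = []
    for i in range(n_pairs):
        phantom = generate_phantom(config, i)
        for label, geom in ((1, few_view_geom), (0, full_view_geom)):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, i, label]))
            sino = _noisy(forward_project(phantom, geom), config, rng)
            samples.append(LabeledSample(
                image=fbp(sino, geom).astype(np.float32),
                label=label,
                seed=config.seed,
                phantom_index=i,
                n_views=geom.n_views,
            ))
    return samples


def save_corpus(samples: list[LabeledSample], path, config: PhantomConfig,
                ) -> None:
    """Write a corpus to HDF5: /images (n,H,W) float32, /labels (n,1) int8."""
    images = np.stack([s.image for s in samples]).astype(np.float32)
    labels = np.array([[s.label] for s in samples], dtype=np.int8)
    provenance = {
        "config": asdict(config),
        "phantom_index": [s.phantom_index for s in samples],
        "n_views": [s.n_views for s in samples],
    }
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=images)
        fh.create_dataset("labels", data=labels)
        fh.attrs["provenance"] = json.dumps(provenance)


def load_corpus(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a corpus written by :func:`save_corpus`.

    Returns (images, labels, provenance) with labels flattened to 1-D.
    """
    with h5py.File(path, "r") as fh:
        images = fh["images"][()]
        labels = fh["labels"][()].reshape(-1)
        provenance = json.loads(fh.attrs["provenance"])
    return images, labels, provenance
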