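"""Total-variation penalty and its smoothed gradient.

Discrete TV with forward differences and replicate boundary (the difference
at the last row/column is zero).  The isotropic variant sums
``sqrt(Dx^2 + Dy^2 + eps^2)`` over pixels; the anisotropic variant sums the
eps-smoothed absolute values of the two differences separately.  A strictly
positive ``eps`` makes the penalty differentiable everywhere, which the
steepest-descent reconstructor requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class TvConfigError(ValueError):
    """Invalid TV configuration or input."""


@dataclass(frozen=True)
class TvConfig:
    """TV discretisation choice.

    ``epsilon`` is the smoothing constant under the square root, in image
    intensity units; it must be > 0 whenever a gradient is taken.
    """

    variant: str = "isotropic"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.variant not in ("isotropic", "anisotropic"):
            raise TvConfigError(f"unknown TV variant {self.variant!r}")
        if self.epsilon < 0:
            raise TvConfigError("epsilon must be >= 0")


def _diffs(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dx = np.zeros_like(image)
    dy = np.zeros_like(image)
    dx[:, :-1] = image[:, 1:] - image[:, :-1]
    dy[:-1, :] = image[1:, :] - image[:-1, :]
    return dx, dy


def _check(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise TvConfigError(f"image must be at least 2x2, got {image.shape}")
    return image


def tv_norm(image: np.ndarray, cfg: TvConfig = TvConfig()) -> float:
    """Smoothed total variation of the image."""
    image = _check(image)
    dx, dy = _diffs(image)
    if cfg.variant == "isotropic":
        return float(np.sum(np.sqrt(dx * dx + dy * dy + cfg.epsilon ** 2)))
    return float(np.sum(np.sqrt(dx * dx + cfg.epsilon ** 2)
                        + np.sqrt(dy * dy + cfg.epsilon ** 2)))


def tv_gradient(image: np.ndarray, cfg: TvConfig = TvConfig()) -> np.ndarray:
    """Exact gradient of the eps-smoothed TV; requires epsilon > 0."""
    if cfg.epsilon <= 0:
        raise TvConfigError(
            "tv_gradient requires epsilon > 0 (subgradients not provided)")
    image = _check(image)
    dx, dy = _diffs(image)
    if cfg.variant == "isotropic":
        r = np.sqrt(dx * dx + dy * dy + cfg.epsilon ** 2)
        px = dx / r
        py = dy / r
    else:
        px = dx / np.sqrt(dx * dx + cfg.epsilon ** 2)
        py = dy / np.sqrt(dy * dy + cfg.epsilon ** 2)
    # each pixel receives -px - py from its own differences and +px / +py
    # from the left / upper neighbours' differences (negative divergence)
    g = -px - py
    g[:, 1:] += px[:, :-1]
    g[1:, :] += py[:-1, :]
    return g
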