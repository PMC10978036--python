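"""Variational reconstruction with the learned score as a Bayesian penalty.

The objective is

    F(X) = alpha1 * ||A X - Y||^2  +  alpha2 * CNN(X)  +  alpha3 * TV(X)

where A is the parallel-beam projector, Y the measured sinogram, CNN(X)
the trained classifier's logit (large when X looks like a few-view
reconstruction), and TV(X) the smoothed total variation.  F can be
negative, because the logit can be.  Minimisation is plain steepest
descent, x <- x - tau * grad F, with either a fixed step or a
simple-decrease backtracking line search; with backtracking the objective
is non-increasing by construction, which is the property the per-iteration
trace is meant to exhibit.  The CNN term is nonconvex, so descent finds a
stationary point, not a certified global minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn_prior import CnnPrior, cnn_score, cnn_score_gradient
from .geometry import (Geometry, _check_image, _check_sinogram,
                       back_project, fbp, forward_project)
from .regularizers import TvConfig, tv_gradient, tv_norm


class DivergenceError(RuntimeError):
    """The objective became non-finite during iteration."""


class ModeError(ValueError):
    """The CNN was passed in classifier mode where score mode is required."""


@dataclass(frozen=True)
class ReconConfig:
    """Hyper-parameters of the iterative solve.

    The default penalty weights are the reference operating point for
    patient-scale intensities; they are coupled to the intensity and
    geometry normalisation of the data, so synthetic corpora at other
    scales need rescaled weights (every experiment here passes its own).
    """

    alpha1: float = 1e-8
    alpha2: float = 0.002
    alpha3: float = 1e-11
    n_iter: int = 600
    step_rule: str = "backtracking"
    step_size: float = 1.0
    init: str = "fbp"
    nonnegativity: bool = False

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.step_rule not in ("fixed", "backtracking"):
            raise ValueError(f"unknown step_rule {self.step_rule!r}")
        if self.init not in ("fbp", "zeros"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ScoreTrace:
    """Per-iteration record; row 0 is the initial point."""

    iteration: list[int] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    data_term: list[float] = field(default_factory=list)
    cnn_score: list[float] = field(default_factory=list)
    tv_term: list[float] = field(default_factory=list)
    step: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iteration)

    def append(self, it: int, f: float, comps: dict, step: float) -> None:
        self.iteration.append(it)
        self.objective.append(f)
        self.data_term.append(comps["data_term"])
        self.cnn_score.append(comps["cnn_score"])
        self.tv_term.append(comps["tv_term"])
        self.step.append(step)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,F,data_term,cnn_score,tv_term,step\n")
            for row in zip(self.iteration, self.objective, self.data_term,
                           self.cnn_score, self.tv_term, self.step):
                fh.write("%d,%.10g,%.10g,%.10g,%.10g,%.10g\n" % row)


def _require_score_mode(model: CnnPrior) -> None:
    if model.mode != "score":
        raise ModeError("the CNN must be in score mode (call to_score_mode())")


def objective(x: np.ndarray, y: np.ndarray, geometry: Geometry,
              model: CnnPrior, tv_cfg: TvConfig, rc: ReconConfig
              ) -> tuple[float, dict]:
    """Evaluate F and return its three addends separately.

    The CNN score is always evaluated, even at alpha2 = 0, so the trace
    stays a diagnostic of artifact severity regardless of the weights.
    """
    _require_score_mode(model)
    x = _check_image(x, geometry)
    y = _check_sinogram(y, geometry)
    residual = forward_project(x, geometry) - y
    with np.errstate(over="ignore"):  # divergent iterates yield inf, caught upstream
        comps = {
            "data_term": float(np.sum(residual * residual)),
            "cnn_score": cnn_score(model, x),
            "tv_term": tv_norm(x, tv_cfg),
        }
    f = (rc.alpha1 * comps["data_term"] + rc.alpha2 * comps["cnn_score"]
         + rc.alpha3 * comps["tv_term"])
    return f, comps


def objective_gradient(x: np.ndarray, y: np.ndarray, geometry: Geometry,
                       model: CnnPrior, tv_cfg: TvConfig, rc: ReconConfig
                       ) -> np.ndarray:
    """Gradient of F: 2*a1*A^T(Ax - y) + a2*grad CNN(x) + a3*grad TV(x)."""
    _require_score_mode(model)
    x = _check_image(x, geometry)
    y = _check_sinogram(y, geometry)
    g = np.zeros_like(x)
    if rc.alpha1 != 0:
        residual = forward_project(x, geometry) - y
        g += 2.0 * rc.alpha1 * back_project(residual, geometry)
    if rc.alpha2 != 0:
        g += rc.alpha2 * cnn_score_gradient(model, x)
    if rc.alpha3 != 0:
        g += rc.alpha3 * tv_gradient(x, tv_cfg)
    return g


def reconstruct(y: np.ndarray, geometry: Geometry, model: CnnPrior,
                rc: ReconConfig = ReconConfig(), tv_cfg: TvConfig = TvConfig()
                ) -> tuple[np.ndarray, ScoreTrace]:
    """Steepest-descent minimisation of F starting from FBP (or zeros).

    With ``step_rule="backtracking"`` each iteration starts from twice the
    previously accepted step and halves (at most 20 times) until F does not
    increase; if no decreasing step is found the iterate is kept and a
    warning is recorded.  Returns the final image and the full trace
    (``rc.n_iter + 1`` rows including the initial point).
    """
    _require_score_mode(model)
    y = _check_sinogram(y, geometry)
    if rc.init == "fbp":
        x = fbp(y, geometry)
    else:
        x = np.zeros((geometry.image_size, geometry.image_size))
    if rc.nonnegativity:
        x = np.maximum(x, 0.0)

    f, comps = objective(x, y, geometry, model, tv_cfg, rc)
    if not np.isfinite(f):
        raise DivergenceError("objective non-finite at the initial point")
    trace = ScoreTrace()
    trace.append(0, f, comps, 0.0)

    tau = rc.step_size
    for k in range(1, rc.n_iter + 1):
        g = objective_gradient(x, y, geometry, model, tv_cfg, rc)

        if rc.step_rule == "fixed":
            x = x - tau * g
            if rc.nonnegativity:
                x = np.maximum(x, 0.0)
            f, comps = objective(x, y, geometry, model, tv_cfg, rc)
            step = tau
        else:
            t = tau
            accepted = False
            for _ in range(21):  # first try plus 20 halvings
                x_try = x - t * g
                if rc.nonnegativity:
                    x_try = np.maximum(x_try, 0.0)
                f_try, comps_try = objective(x_try, y, geometry, model,
                                             tv_cfg, rc)
                if np.isfinite(f_try) and f_try <= f:
                    accepted = True
                    break
                t *= 0.5
            if accepted:
                x, f, comps = x_try, f_try, comps_try
                step = t
                tau = 2.0 * t  # warm start for the next line search
            else:
                step = 0.0
                trace.warnings.append(
                    f"iteration {k}: step underflow, iterate unchanged")

        if not np.isfinite(f):
            raise DivergenceError(f"objective non-finite at iteration {k}")
        trace.append(k, f, comps, step)
    return x, trace
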