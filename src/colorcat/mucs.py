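"""Reconstruction of a behaviorally uniform color space (MUCS).

The stimulus-nonuniformity model estimates the perceptual distance between
each pair of neighboring stimuli.  Accumulating those distances around the
circle yields new hue angles for the stimuli -- their positions in a color
space in which the subject's matches are, on average, unbiased.  This module
derives that map from a fitted model and converts hues between the nominal
(CIELUV) parameterization and the derived uniform one by circular piecewise-
linear interpolation, exactly invertible on and off the stimulus grid.

The absolute rotation of the derived space is unidentifiable; stimulus 0 is
anchored to MUCS hue 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import wrap_angle
from .tccv import ModelFitResult

__all__ = [
    "UniformSpaceMap",
    "derive_map",
    "cieluv_to_mucs",
    "mucs_to_cieluv",
    "sample_uniform_mucs",
]


@dataclass(frozen=True)
class UniformSpaceMap:
    """Monotone circular map between nominal and uniform hue angles.

    ``cieluv_hues[k]`` and ``mucs_hues[k]`` are the positions of stimulus k
    in the two spaces; both are strictly increasing with entry 0 equal to
    the anchor, and both wrap after a 360-degree total span.
    """

    cieluv_hues: np.ndarray
    mucs_hues: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cieluv_hues, dtype=float)
        m = np.asarray(self.mucs_hues, dtype=float)
        object.__setattr__(self, "cieluv_hues", c)
        object.__setattr__(self, "mucs_hues", m)
        if c.shape != m.shape or c.ndim != 1:
            raise ValueError("hue grids must be 1-d and the same length")
        if np.any(np.diff(c) <= 0) or np.any(np.diff(m) <= 0):
            raise ValueError("hue grids must be strictly increasing")
        if m[0] != 0.0:
            raise ValueError("mucs_hues must be anchored at 0")


def derive_map(fitted: ModelFitResult, cieluv_hues: np.ndarray | None = None) -> UniformSpaceMap:
    """Build the uniform-space map from a stimulus-nonuniformity fit.

    The fitted inter-neighbor distances (already normalized to a 360-degree
    total) are accumulated into MUCS hue angles: ``mucs_hues[k] = sum_{j<k}
    D_j``, with stimulus 0 at 0.
    """
    model = fitted.model
    if model.variant != "stimulus_nonuniformity":
        raise ValueError(
            f"need a stimulus_nonuniformity fit, got variant {model.variant!r}"
        )
    if not fitted.converged:
        raise ValueError("refusing to derive a map from a non-converged fit")
    d = np.asarray(model.distances, dtype=float)
    mucs = np.concatenate([[0.0], np.cumsum(d)[:-1]])
    if cieluv_hues is None:
        n = len(d)
        cieluv_hues = np.arange(n) * (360.0 / n)
    return UniformSpaceMap(cieluv_hues=np.asarray(cieluv_hues, dtype=float), mucs_hues=mucs)


def _circular_interp(x, xgrid: np.ndarray, ygrid: np.ndarray):
    """Piecewise-linear interpolation on a circular grid (both axes mod 360)."""
    x = wrap_angle(x)
    # extend one period each way so every query has a bracketing segment
    xg = np.concatenate([xgrid - 360.0, xgrid, xgrid + 360.0])
    yg = np.concatenate([ygrid - 360.0, ygrid, ygrid + 360.0])
    return wrap_angle(np.interp(x, xg, yg))


def cieluv_to_mucs(space_map: UniformSpaceMap, hue):
    """Nominal (CIELUV) hue angle(s) -> uniform-space hue angle(s)."""
    out = _circular_interp(hue, space_map.cieluv_hues, space_map.mucs_hues)
    return float(out) if np.isscalar(hue) else out


def mucs_to_cieluv(space_map: UniformSpaceMap, hue):
    """Uniform-space hue angle(s) -> nominal (CIELUV) hue angle(s)."""
    out = _circular_interp(hue, space_map.mucs_hues, space_map.cieluv_hues)
    return float(out) if np.isscalar(hue) else out


def sample_uniform_mucs(space_map: UniformSpaceMap, n: int) -> np.ndarray:
    """n hues evenly spaced in the uniform space, expressed in CIELUV.

    Where the fitted distances are small (stimuli perceptually bunched in
    the nominal space), the returned CIELUV hues bunch correspondingly.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    even = np.arange(n) * (360.0 / n)
    return mucs_to_cieluv(space_map, even)
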