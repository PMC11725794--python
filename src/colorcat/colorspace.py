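"""Equiluminant CIELUV hue circles and circular hue-angle arithmetic.

The stimulus set used throughout this package is a ring of colors at fixed
lightness L* and fixed chroma (u*v* radius) around an adapting white point,
sampled at even hue-angle intervals.  The canonical set has 64 colors spaced
5.625 degrees apart at L* = 76.0693, chroma 37, around an adapting field of
chromaticity xy = (0.2684, 0.2409) at 38.5 cd/m^2.

Hue angles are in degrees, measured counterclockwise from the positive u*
axis, and are always reduced to the canonical interval [0, 360).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSet",
    "build_stimulus_set",
    "canonical_stimulus_set",
    "stimulus_to_tristimulus",
    "xyz_to_luv",
    "wrap_angle",
    "circular_diff",
    "CANONICAL_LIGHTNESS",
    "CANONICAL_CHROMA",
    "CANONICAL_WHITE",
    "CANONICAL_N_COLORS",
]

CANONICAL_N_COLORS = 64
CANONICAL_LIGHTNESS = 76.0693
CANONICAL_CHROMA = 37.0
#: adapting-field chromaticity (CIE 1931 xy) and luminance in cd/m^2
CANONICAL_WHITE = (0.2684, 0.2409, 38.5)


def wrap_angle(angle):
    """Reduce an angle (degrees) to the canonical interval [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def circular_diff(a, b):
    """Signed circular difference ``a - b`` in degrees, in (-180, +180].

    Positive values are counterclockwise (increasing hue angle).  The
    antipodal tie is broken toward +180, never -180, so the result is a
    deterministic function of (a mod 360, b mod 360).  Accepts scalars or
    arrays (broadcasting).
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if d.ndim == 0:
        return float(d)
    return d


class InvalidParadigmError(ValueError):
    """Raised for stimulus sets too small to support a 4AFC trial."""


@dataclass(frozen=True)
class StimulusSet:
    """An equiluminant ring of colors in CIELUV.

    Attributes
    ----------
    n_colors : int
        Number of colors on the ring (>= 4).
    hue_angles : np.ndarray
        Hue angle of each color in degrees, strictly increasing in [0, 360).
    chroma : float
        Common u*v* radius of all colors.
    lightness : float
        Common L* of all colors.
    white_point : tuple of float
        Adapting chromaticity and luminance ``(x, y, Y)`` with Y in cd/m^2.
    """

    n_colors: int
    hue_angles: np.ndarray
    chroma: float
    lightness: float
    white_point: tuple = CANONICAL_WHITE

    def __post_init__(self):
        hues = np.asarray(self.hue_angles, dtype=float)
        object.__setattr__(self, "hue_angles", hues)
        if self.n_colors < 4:
            raise InvalidParadigmError(
                f"a 4AFC paradigm needs at least 4 distinct colors, got {self.n_colors}"
            )
        if hues.shape != (self.n_colors,):
            raise ValueError("hue_angles must have one entry per color")
        if np.any(np.diff(hues) <= 0) or hues[0] < 0 or hues[-1] >= 360:
            raise ValueError("hue_angles must be strictly increasing in [0, 360)")
        if self.chroma <= 0:
            raise ValueError("chroma must be positive")

    @property
    def spacing(self) -> float:
        """Nominal spacing 360/n (degrees); exact for the even sampling."""
        return 360.0 / self.n_colors

    def uv(self) -> np.ndarray:
        """(n, 2) array of (u*, v*) displacements from the white point."""
        h = np.deg2rad(self.hue_angles)
        return self.chroma * np.stack([np.cos(h), np.sin(h)], axis=1)

    def index_hue(self, index) -> np.ndarray | float:
        """Hue angle(s) of the given color index/indices."""
        return self.hue_angles[index]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_colors": self.n_colors,
                "hue_angles": self.hue_angles.tolist(),
                "chroma": self.chroma,
                "lightness": self.lightness,
                "white_point": {
                    "x": self.white_point[0],
                    "y": self.white_point[1],
                    "Y": self.white_point[2],
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusSet":
        d = json.loads(text)
        wp = d["white_point"]
        return cls(
            n_colors=int(d["n_colors"]),
            hue_angles=np.asarray(d["hue_angles"], dtype=float),
            chroma=float(d["chroma"]),
            lightness=float(d["lightness"]),
            white_point=(wp["x"], wp["y"], wp["Y"]),
        )


def build_stimulus_set(
    n_colors: int = CANONICAL_N_COLORS,
    lightness: float = CANONICAL_LIGHTNESS,
    chroma: float = CANONICAL_CHROMA,
    white_point: tuple = CANONICAL_WHITE,
    phase: float = 0.0,
) -> StimulusSet:
    """Build an evenly sampled equiluminant hue circle.

    ``phase`` rotates the whole ring; the default places color 0 on the
    positive u* axis (hue 0).  The absolute origin is a labeling convention:
    every analysis in this package is rotation-equivariant.
    """
    if n_colors < 4:
        raise InvalidParadigmError(
            f"a 4AFC paradigm needs at least 4 distinct colors, got {n_colors}"
        )
    hues = wrap_angle(phase + np.arange(n_colors) * (360.0 / n_colors))
    order = np.argsort(hues)
    if not np.array_equal(order, np.arange(n_colors)):
        # non-zero phase can wrap the last entries past 360; re-sort so the
        # canonical increasing-order invariant holds (indices are relabeled)
        hues = hues[order]
    return StimulusSet(
        n_colors=n_colors,
        hue_angles=hues,
        chroma=float(chroma),
        lightness=float(lightness),
        white_point=tuple(white_point),
    )


def canonical_stimulus_set() -> StimulusSet:
    """The canonical 64-color ring (5.625 degree spacing, chroma 37)."""
    return build_stimulus_set()


def _white_xyz(white_point) -> np.ndarray:
    x, y, Y = white_point
    return np.array([x * Y / y, Y, (1.0 - x - y) * Y / y])


def _uv_prime(xyz: np.ndarray):
    X, Y, Z = xyz
    denom = X + 15.0 * Y + 3.0 * Z
    return 4.0 * X / denom, 9.0 * Y / denom


def luv_to_xyz(lstar: float, ustar: float, vstar: float, white_point) -> np.ndarray:
    """CIE 1976 L*u*v* -> XYZ with an explicit white point (x, y, Y)."""
    wxyz = _white_xyz(white_point)
    un, vn = _uv_prime(wxyz)
    Yn = wxyz[1]
    if lstar > 8.0:
        Y = Yn * ((lstar + 16.0) / 116.0) ** 3
    else:
        Y = Yn * lstar * (3.0 / 29.0) ** 3
    if lstar == 0.0:
        return np.array([0.0, 0.0, 0.0])
    up = ustar / (13.0 * lstar) + un
    vp = vstar / (13.0 * lstar) + vn
    X = Y * 9.0 * up / (4.0 * vp)
    Z = Y * (12.0 - 3.0 * up - 20.0 * vp) / (4.0 * vp)
    return np.array([X, Y, Z])


def xyz_to_luv(xyz, white_point) -> np.ndarray:
    """XYZ -> CIE 1976 (L*, u*, v*) with an explicit white point (x, y, Y)."""
    xyz = np.asarray(xyz, dtype=float)
    wxyz = _white_xyz(white_point)
    un, vn = _uv_prime(wxyz)
    Yn = wxyz[1]
    yr = xyz[1] / Yn
    if yr > (6.0 / 29.0) ** 3:
        lstar = 116.0 * yr ** (1.0 / 3.0) - 16.0
    else:
        lstar = (29.0 / 3.0) ** 3 * yr
    up, vp = _uv_prime(xyz)
    return np.array([lstar, 13.0 * lstar * (up - un), 13.0 * lstar * (vp - vn)])


def stimulus_to_tristimulus(stimulus_set: StimulusSet, index: int) -> np.ndarray:
    """CIE XYZ coordinates of one stimulus (for rendering/inspection).

    Applies the CIELUV inverse transform with the set's stored white point;
    no standard-illuminant assumption is made (the adapting chromaticity of
    the canonical set is not a CIE D illuminant).
    """
    if not 0 <= index < stimulus_set.n_colors:
        raise IndexError(
            f"stimulus index {index} out of range [0, {stimulus_set.n_colors})"
        )
    u, v = stimulus_set.uv()[index]
    return luv_to_xyz(stimulus_set.lightness, u, v, stimulus_set.white_point)
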