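"""Discrimination contours and their ellipse fits.

One JND per orientation of the distance-duration plane, mirrored through
the reference point, gives a 16-point discrimination contour (8
orientations x 2).  An ellipse fitted to the contour summarizes which cue
the observer relies on: its major-axis orientation, measured in degrees
from the vertical distance axis, is

* ~0 degrees  - duration-dominant (vertical ellipse: large distance JNDs),
* ~45 degrees - speed-dominant,
* ~90 degrees - distance-dominant (horizontal ellipse).

Two fitting routes are provided.  The primary one is the direct
ellipse-specific least-squares fit of Fitzgibbon/Halir-Flusser, which always
returns an ellipse.  The ``conic`` alternative fits an unconstrained
algebraic conic and classifies it, failing with :class:`NotAnEllipseError`
on hyperbolic or degenerate JND sets - emulating general-conic toolbox
routines, whose occasional failures on human JND sets are part of the
analysis (those subjects drop out of the orientation statistics only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import orientation_direction

__all__ = [
    "EllipseFit",
    "NotAnEllipseError",
    "ContourError",
    "contour_points",
    "fit_ellipse",
    "axial_difference",
    "ellipse_points",
]


class ContourError(ValueError):
    """Incomplete or malformed contour set."""


class NotAnEllipseError(ValueError):
    """The best-fitting conic is not an ellipse."""


@dataclass(frozen=True)
class EllipseFit:
    """Geometric ellipse parameters plus the algebraic conic coefficients.

    ``theta_deg`` is the major-axis orientation in [0, 180), measured from
    the positive distance (vertical) axis toward the positive duration
    (horizontal) axis - the same convention as the stimulus orientations.
    ``conic`` holds (A, B, C, D, E, F) with A x^2 + B xy + C y^2 + D x +
    E y + F = 0 in (w_duration, w_distance) coordinates.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    theta_deg: float
    conic: tuple[float, float, float, float, float, float]


def contour_points(fits: pd.DataFrame) -> np.ndarray:
    """Build the mirrored contour point set from per-orientation JNDs.

    ``fits`` needs one row per orientation with columns ``orientation_deg``
    and ``jnd_signed`` (post-substitution).  Each orientation phi with JND
    magnitude j contributes the two points +-j * (sin phi, cos phi); the
    result is an (2 * n_orientations, 2) array of (w_duration, w_distance)
    coordinates, symmetric about the origin by construction.
    """
    angles = np.asarray(fits["orientation_deg"], dtype=float)
    if len(np.unique(angles.round(9))) != len(angles):
        raise ContourError("duplicate orientations in contour fit table")
    if fits["jnd_signed"].isna().any():
        missing = angles[fits["jnd_signed"].isna().to_numpy()]
        raise ContourError(f"missing JND at orientations {missing.tolist()}")
    pts = []
    for angle, jnd in zip(angles, fits["jnd_signed"].to_numpy(dtype=float)):
        d = orientation_direction(angle)
        j = abs(jnd)
        if j == 0:
            raise ContourError(f"zero JND at orientation {angle}")
        pts.append(j * d)
        pts.append(-j * d)
    return np.asarray(pts)


def _solve_direct(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Halir-Flusser numerically stable direct least-squares ellipse fit.

    Minimizes algebraic error subject to 4AC - B^2 = 1, which forces the
    conic to be an ellipse.
    """
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    t = -np.linalg.solve(s3, s2.T)
    m = s1 + s2 @ t
    # premultiply by inv(C1) for C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.where(cond > 0)[0]
    if len(good) == 0:
        raise NotAnEllipseError("direct fit produced no ellipse solution")
    a1 = np.real(eigvec[:, good[0]])
    return np.concatenate([a1, t @ a1])


def _solve_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unconstrained algebraic conic fit (smallest singular vector)."""
    d = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return vt[-1]


def _conic_geometry(coef: np.ndarray) -> EllipseFit:
    a, b, c, d, e, f = (float(v) for v in coef)
    disc = b * b - 4 * a * c
    if disc >= 0:
        raise NotAnEllipseError(f"conic discriminant B^2-4AC = {disc:.3g} >= 0")
    m2 = np.array([[a, b / 2.0], [b / 2.0, c]])
    center = np.linalg.solve(2 * m2, [-d, -e])
    f0 = f + 0.5 * (d * center[0] + e * center[1])
    eigval, eigvec = np.linalg.eigh(m2)
    radii_sq = -f0 / eigval
    if np.any(radii_sq <= 0):
        raise NotAnEllipseError("degenerate or imaginary ellipse")
    radii = np.sqrt(radii_sq)
    major_idx = int(np.argmax(radii))
    v = eigvec[:, major_idx]
    angle_from_x = np.degrees(np.arctan2(v[1], v[0])) % 180.0
    theta = (90.0 - angle_from_x) % 180.0
    return EllipseFit(
        center=(float(center[0]), float(center[1])),
        semi_major=float(radii[major_idx]),
        semi_minor=float(radii[1 - major_idx]),
        theta_deg=float(theta),
        conic=tuple(float(v) for v in coef),
    )


def fit_ellipse(points: np.ndarray, method: str = "direct") -> EllipseFit:
    """Fit an ellipse to contour points (n >= 6, columns w_duration, w_distance).

    ``method="direct"`` uses the ellipse-constrained least-squares fit;
    ``method="conic"`` fits a free algebraic conic and raises
    :class:`NotAnEllipseError` when the best conic is not a (real) ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise ContourError("need at least 6 points of shape (n, 2)")
    x, y = pts[:, 0], pts[:, 1]
    if np.linalg.matrix_rank(np.column_stack([x, y, np.ones_like(x)])) < 3:
        raise ContourError("points are collinear")
    if method == "direct":
        coef = _solve_direct(x, y)
    elif method == "conic":
        coef = _solve_conic(x, y)
    else:
        raise ValueError("method must be 'direct' or 'conic'")
    return _conic_geometry(coef)


def axial_difference(theta_a: float, theta_b: float) -> float:
    """Smallest angle between two axial orientations, degrees in [0, 90].

    Axial means defined modulo 180 degrees, as for an ellipse's major axis.
    """
    if not (np.isfinite(theta_a) and np.isfinite(theta_b)):
        raise ValueError("orientations must be finite")
    d = abs(theta_a - theta_b) % 180.0
    return float(min(d, 180.0 - d))


def ellipse_points(
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    theta_deg: float,
    n: int = 16,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Sample points of an ellipse given in the vertical-axis convention
    (inverse of :func:`fit_ellipse`; used for round-trip validation)."""
    if t is None:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    phi = np.radians(90.0 - theta_deg)  # major-axis angle from the x-axis
    ca, sa = np.cos(phi), np.sin(phi)
    x = semi_major * np.cos(t)
    y = semi_minor * np.sin(t)
    return np.column_stack(
        [center[0] + x * ca - y * sa, center[1] + x * sa + y * ca]
    )
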