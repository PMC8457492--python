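"""Stimulus design for a 2AFC auditory speed-discrimination experiment.

The stimulus space is the distance-duration Weber plane: every target sound
is described by the pair of Weber fractions

    w_distance = (T_distance - R_distance) / R_distance
    w_duration = (T_duration - R_duration) / R_duration

relative to a reference sound travelling 21.17 degrees of arc in 800 ms
(26.4625 deg/s).  The plane is sampled along equally spaced orientations
through the reference point; by convention ``w_duration`` is the horizontal
axis and ``w_distance`` the vertical axis, and an orientation angle is
measured in degrees from the positive distance (vertical) axis toward the
positive duration (horizontal) axis.  Four orientations have names:

* 0 degrees, *spatial* - only travelled distance varies;
* 90 degrees, *temporal* - only duration varies;
* 45 degrees, *coherent* - distance and duration vary proportionally, so
  physical speed never changes;
* 135 degrees, *opposite* - distance and duration vary inversely, so speed
  changes steeply.

Along each orientation a constant-stimuli grid of (by default) nine levels
is laid out; the middle level is the reference itself and the extreme levels
reach a speed ratio of ``ratio_extreme`` (default 4) against the reference
wherever the orientation geometry allows it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "DesignError",
    "CueDomainError",
    "SPATIAL",
    "TEMPORAL",
    "COHERENT",
    "OPPOSITE",
    "UNNAMED",
    "orientation_angles",
    "orientation_direction",
    "label_condition",
    "cue_offsets",
    "target_speed",
    "level_factors",
    "magnitude_grid",
    "build_design",
    "DESIGN_COLUMNS",
]

SPATIAL = "spatial"
TEMPORAL = "temporal"
COHERENT = "coherent"
OPPOSITE = "opposite"
UNNAMED = "unnamed"

_NAMED_ANGLES = {0.0: SPATIAL, 45.0: COHERENT, 90.0: TEMPORAL, 135.0: OPPOSITE}

#: Column order of the trial-schedule table (and its CSV serialization).
DESIGN_COLUMNS = [
    "subject_id",
    "block",
    "orientation_deg",
    "condition",
    "level_index",
    "magnitude",
    "w_duration",
    "w_distance",
    "target_speed_deg_s",
    "motion_direction",
    "start_offset",
    "rep",
]


class DesignError(ValueError):
    """Invalid design configuration or infeasible stimulus grid."""


class CueDomainError(DesignError):
    """A cue offset would drive target duration or distance to zero or below."""


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the stimulus design.

    Parameters
    ----------
    reference_distance : float
        Travelled arc of the reference sound, degrees.
    reference_duration : float
        Duration of the reference sound, milliseconds.
    n_orientations : int
        Number of equally spaced orientations through the reference point,
        covering [0, 180) degrees.
    n_levels : int
        Levels per orientation; must be odd so that the middle level is the
        reference stimulus itself.
    n_reps : int
        Repetitions of each level.
    ratio_extreme : float
        Target/reference speed ratio reached by the extreme levels (where
        the orientation allows it); levels are geometric in this factor.
    n_blocks : int
        Number of experimental blocks trials are dealt into.
    speaker_span : float
        Angular span of the loudspeaker array, degrees (trial metadata only).
    n_speakers : int
        Number of loudspeakers in the array (trial metadata only).
    seed : int
        Seed of the schedule randomization.
    """

    reference_distance: float = 21.17
    reference_duration: float = 800.0
    n_orientations: int = 8
    n_levels: int = 9
    n_reps: int = 6
    ratio_extreme: float = 4.0
    n_blocks: int = 6
    speaker_span: float = 50.0
    n_speakers: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_distance <= 0:
            raise DesignError("reference_distance must be positive")
        if self.reference_duration <= 0:
            raise DesignError("reference_duration must be positive")
        if self.n_levels < 3 or self.n_levels % 2 == 0:
            raise DesignError("n_levels must be odd (middle level = reference)")
        if self.ratio_extreme <= 1:
            raise DesignError("ratio_extreme must exceed 1")
        if self.n_orientations < 4:
            raise DesignError("need at least 4 orientations")
        if self.n_reps < 1:
            raise DesignError("n_reps must be at least 1")
        if self.n_blocks < 1:
            raise DesignError("n_blocks must be at least 1")

    @property
    def reference_speed(self) -> float:
        """Reference speed in degrees/second (full precision, no rounding)."""
        return self.reference_distance / (self.reference_duration / 1000.0)


def orientation_angles(n_orientations: int = 8) -> np.ndarray:
    """Equally spaced orientation angles in [0, 180), degrees."""
    return np.arange(n_orientations) * (180.0 / n_orientations)


def orientation_direction(angle_deg: float) -> np.ndarray:
    """Unit vector (w_duration, w_distance) of an orientation.

    Exact zeros are restored on the pure axes, where ``sin``/``cos`` of a
    float multiple of pi carry ~1e-16 residues.
    """
    phi = np.radians(angle_deg)
    d = np.array([np.sin(phi), np.cos(phi)])
    d[np.abs(d) < 1e-12] = 0.0
    return d


def label_condition(angle_deg: float) -> str:
    """Name the experimental condition of an orientation angle.

    0 -> spatial, 45 -> coherent, 90 -> temporal, 135 -> opposite; any other
    angle in [0, 180) is ``unnamed``.
    """
    if not np.isfinite(angle_deg) or angle_deg < 0 or angle_deg >= 180:
        raise DesignError(f"orientation angle {angle_deg!r} outside [0, 180)")
    for named, label in _NAMED_ANGLES.items():
        if np.isclose(angle_deg, named, atol=1e-9):
            return label
    return UNNAMED


def cue_offsets(angle_deg: float, magnitude: float) -> tuple[float, float]:
    """Cue offset (w_duration, w_distance) at a signed magnitude along an orientation.

    Raises
    ------
    CueDomainError
        If either Weber fraction would be <= -1 (non-positive target
        duration or distance), naming the offending cue.
    """
    direction = orientation_direction(angle_deg)
    w_duration, w_distance = magnitude * direction
    if w_duration <= -1:
        raise CueDomainError(
            f"w_duration = {w_duration:.4f} <= -1: target duration would vanish"
        )
    if w_distance <= -1:
        raise CueDomainError(
            f"w_distance = {w_distance:.4f} <= -1: target distance would vanish"
        )
    return float(w_duration), float(w_distance)


def target_speed(w_duration, w_distance, config: DesignConfig | None = None):
    """Target speed, degrees/second, of a cue offset (vectorized).

    ``speed = reference_speed * (1 + w_distance) / (1 + w_duration)``.
    """
    config = config or DesignConfig()
    w_duration = np.asarray(w_duration, dtype=float)
    w_distance = np.asarray(w_distance, dtype=float)
    if np.any(w_duration <= -1) or np.any(w_distance <= -1):
        raise CueDomainError("cue offsets must keep both Weber fractions > -1")
    out = config.reference_speed * (1.0 + w_distance) / (1.0 + w_duration)
    return float(out) if out.ndim == 0 else out


def level_factors(config: DesignConfig) -> np.ndarray:
    """Geometric grid of speed-ratio factors, ``ratio_extreme**(k/h)`` for
    k = -h..h with h = (n_levels - 1) / 2."""
    h = (config.n_levels - 1) // 2
    k = np.arange(-h, h + 1)
    return config.ratio_extreme ** (k / h)


def _magnitude_for_speed_factor(angle_deg: float, factor: float) -> float | None:
    """Signed magnitude m along an orientation whose speed ratio equals ``factor``.

    Solves (1 + m cos) / (1 + m sin) = f.  Returns None when the orientation
    geometry cannot reach the factor with both Weber fractions > -1.
    """
    s, c = orientation_direction(angle_deg)
    denom = c - factor * s
    if abs(denom) < 1e-12:
        return None if abs(factor - 1.0) > 1e-12 else 0.0
    m = (factor - 1.0) / denom
    w_t, w_d = m * s, m * c
    margin = 1e-9
    if 1.0 + w_t <= margin or 1.0 + w_d <= margin:
        return None
    return float(m)


def magnitude_grid(angle_deg: float, config: DesignConfig | None = None) -> np.ndarray:
    """Signed level magnitudes along one orientation, sorted ascending.

    Levels are geometric in the target/reference speed-ratio factor over
    ``[1/ratio_extreme, ratio_extreme]`` wherever the orientation can reach
    the whole factor range.  Two orientation families cannot:

    * the coherent line (45 degrees), where speed never changes - there the
      grid is geometric in the shared cue factor, ``1 + w = f``;
    * near-coherent obliques whose attainable speed ratio is capped by the
      line's slope - there the grid is geometric in the dominant cue factor
      (distance factor below 45 degrees, duration factor above).

    The middle level is always the reference (magnitude 0).
    """
    config = config or DesignConfig()
    factors = level_factors(config)
    mags = [_magnitude_for_speed_factor(angle_deg, f) for f in factors]
    if any(m is None for m in mags):
        s, c = orientation_direction(angle_deg)
        if np.isclose(abs(s), abs(c)):  # coherent-type diagonal
            mags = [(f - 1.0) / s for f in factors]
        elif abs(c) >= abs(s):  # distance-dominant: distance factor = f
            mags = [(f - 1.0) / c for f in factors]
        else:  # duration-dominant: duration factor = 1/f
            mags = [(1.0 / f - 1.0) / s for f in factors]
        for m in mags:
            cue_offsets(angle_deg, m)  # validates the fallback grid
    return np.sort(np.asarray(mags, dtype=float))


def build_design(config: DesignConfig | None = None, subject_id: str = "S1") -> pd.DataFrame:
    """Build the full randomized trial schedule for one subject.

    Returns a table with one row per trial and columns :data:`DESIGN_COLUMNS`
    (``n_orientations * n_levels * n_reps`` rows; 432 with the defaults).
    Motion direction and start speaker offset are sampled uniformly, the row
    order is shuffled with ``config.seed``, and trials are then dealt
    round-robin into ``n_blocks``.  The same seed reproduces the same
    schedule exactly.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for angle in orientation_angles(config.n_orientations):
        condition = label_condition(angle)
        mags = magnitude_grid(angle, config)
        for level_index, m in enumerate(mags):
            w_t, w_d = cue_offsets(angle, m)
            speed = target_speed(w_t, w_d, config)
            for rep in range(config.n_reps):
                rows.append(
                    (
                        subject_id,
                        angle,
                        condition,
                        level_index,
                        m,
                        w_t,
                        w_d,
                        speed,
                        rep,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "orientation_deg",
            "condition",
            "level_index",
            "magnitude",
            "w_duration",
            "w_distance",
            "target_speed_deg_s",
            "rep",
        ],
    )
    n = len(df)
    df["motion_direction"] = rng.choice(["leftward", "rightward"], size=n)
    df["start_offset"] = rng.integers(0, 3, size=n)
    df = df.iloc[rng.permutation(n)].reset_index(drop=True)
    df["block"] = np.arange(n) % config.n_blocks
    return df[DESIGN_COLUMNS]
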