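"""Synthetic cue-weighted observers for 2AFC speed discrimination.

Each simulated observer receives noisy internal estimates of the trial's
duration and distance Weber fractions,

    w_t_hat = w_duration + eps_t,   w_d_hat = w_distance + eps_d,

with independent Gaussian noise of standard deviation ``noise_sd`` in Weber
units, derives a noisy speed Weber fraction

    w_v_hat = (1 + w_d_hat) / (1 + w_t_hat) - 1,

and answers "faster" whenever the decision variable

    D = weight_speed * w_v_hat
        - weight_duration * w_t_hat
        + weight_distance * spatial_sign * w_d_hat

is positive.  The negative duration term encodes the temporal assumption
"shorter sound = faster sound"; ``spatial_sign = -1`` encodes its spatial
analogue, the (erroneous) heuristic "shorter travelled distance = faster
sound".  With probability ``lapse`` the answer is replaced by a fair coin
flip; exact ties (D == 0) are also resolved by a fair coin.

These observers are pipeline validators, not cognitive models: their
weights are chosen so that each preset produces the discrimination-contour
signature (ellipse orientation) its name announces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["ObserverParams", "observer_preset", "simulate_responses", "PRESETS"]


@dataclass(frozen=True)
class ObserverParams:
    """Cue weights and noise of one simulated observer.

    ``weight_speed``, ``weight_duration`` and ``weight_distance`` are
    non-negative; the duration weight always acts with the "shorter =
    faster" sign, and ``spatial_sign`` selects the veridical (+1, longer
    distance = faster) or inverted (-1) use of the distance cue.
    """

    weight_speed: float
    weight_duration: float
    weight_distance: float
    spatial_sign: int = 1
    noise_sd: float = 0.3
    lapse: float = 0.02

    def __post_init__(self) -> None:
        w = (self.weight_speed, self.weight_duration, self.weight_distance)
        if any(x < 0 for x in w):
            raise ValueError("cue weights must be non-negative")
        if not any(x > 0 for x in w):
            raise ValueError("at least one cue weight must be positive")
        if self.spatial_sign not in (-1, 1):
            raise ValueError("spatial_sign must be +1 or -1")
        if not 0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


#: Named observer presets (weights speed, duration, distance; spatial sign).
PRESETS: dict[str, ObserverParams] = {
    "duration_only": ObserverParams(0.0, 1.0, 0.0, +1),
    "distance_only": ObserverParams(0.0, 0.0, 1.0, +1),
    "speed_only": ObserverParams(1.0, 0.0, 0.0, +1),
    # duration-dominant with an inverted use of the distance cue
    "eb_like": ObserverParams(0.0, 1.0, 0.4, -1),
    # duration-dominant but veridical, with some genuine speed sensitivity
    "sc_like": ObserverParams(0.3, 1.0, 0.3, +1),
}


def observer_preset(name: str, **overrides) -> ObserverParams:
    """Return a named observer preset, optionally overriding fields
    (e.g. ``observer_preset("duration_only", noise_sd=0.2)``)."""
    try:
        params = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown observer preset {name!r}; known: {sorted(PRESETS)}"
        ) from None
    return replace(params, **overrides) if overrides else params


def simulate_responses(
    design: pd.DataFrame,
    observer: ObserverParams,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one "faster"/"slower" answer per trial of a schedule.

    ``design`` needs at least ``w_duration`` and ``w_distance`` columns; the
    returned copy carries an additional ``response`` column.  Noise draws
    that would push a noisy Weber fraction to -1 or below are resampled, so
    the internal cues are always valid.  Identical seeds give identical
    response tables.
    """
    if len(design) == 0:
        raise ValueError("design has no trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_t = design["w_duration"].to_numpy(dtype=float)
    w_d = design["w_distance"].to_numpy(dtype=float)
    n = len(design)

    wt_hat = w_t + rng.normal(0.0, observer.noise_sd, size=n)
    wd_hat = w_d + rng.normal(0.0, observer.noise_sd, size=n)
    bad = (wt_hat <= -1) | (wd_hat <= -1)
    while np.any(bad):
        k = int(bad.sum())
        wt_hat[bad] = w_t[bad] + rng.normal(0.0, observer.noise_sd, size=k)
        wd_hat[bad] = w_d[bad] + rng.normal(0.0, observer.noise_sd, size=k)
        bad = (wt_hat <= -1) | (wd_hat <= -1)

    wv_hat = (1.0 + wd_hat) / (1.0 + wt_hat) - 1.0
    decision = (
        observer.weight_speed * wv_hat
        - observer.weight_duration * wt_hat
        + observer.weight_distance * observer.spatial_sign * wd_hat
    )
    faster = decision > 0
    ties = decision == 0
    if np.any(ties):
        faster[ties] = rng.random(int(ties.sum())) < 0.5
    if observer.lapse > 0:
        lapsed = rng.random(n) < observer.lapse
        faster[lapsed] = rng.random(int(lapsed.sum())) < 0.5

    out = design.copy()
    out["response"] = np.where(faster, "faster", "slower")
    return out
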