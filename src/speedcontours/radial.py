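"""Signed radial speed coordinate and JND conversion.

To compare precision across conditions, every trial is collapsed onto a
single signed coordinate: the radial distance of its cue offset from the
reference,

    |r| = sqrt(w_duration^2 + w_distance^2),

signed so that r > 0 means the target is veridically faster.  The default
sign rule is sign(w_distance - w_duration) - positive exactly when the
speed ratio exceeds 1 - with the constant-speed (coherent) line signed by
its w_distance coordinate, where the speed difference is identically zero.
A literal variant signing purely by the plane's vertical coordinate
(``rule="y"``) is kept as an option; applied globally it would invert the
temporal condition for a veridical observer, which is why it is not the
default.

Observers who judge by a "shorter = faster" heuristic produce *decreasing*
"faster"-vs-r curves (negative JNDs) in conditions where the heuristic
misleads.  To place such inverted curves on a common precision scale,
negative JNDs are converted within each cohort:

    JND_conv = JND_neg - min(JND) + max(JND),

with min/max over all the group's signed JNDs; non-negative JNDs pass
through.  After conversion, small JND_conv always means good speed
discrimination, and every inverted curve scores at or above the group's
worst upright curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psychometrics import PsychFit, aggregate_proportions, fit_psychometric

__all__ = [
    "radial_coordinate",
    "attach_radial",
    "fit_condition",
    "convert_negative_jnds",
    "NAMED_CONDITIONS",
]

NAMED_CONDITIONS = ("spatial", "temporal", "coherent", "opposite")


def radial_coordinate(w_duration, w_distance, rule: str = "speed"):
    """Signed radial distance of cue offsets from the reference (vectorized).

    ``rule="speed"`` (default): sign of the veridical speed difference,
    sign(w_distance - w_duration), falling back to sign(w_distance) on the
    constant-speed line.  ``rule="y"``: sign of w_distance alone.
    """
    w_t = np.asarray(w_duration, dtype=float)
    w_d = np.asarray(w_distance, dtype=float)
    mag = np.hypot(w_t, w_d)
    if rule == "speed":
        sign = np.sign(w_d - w_t)
        sign = np.where(sign == 0, np.sign(w_d), sign)
    elif rule == "y":
        sign = np.sign(w_d)
    else:
        raise ValueError("rule must be 'speed' or 'y'")
    sign = np.where(sign == 0, 1.0, sign)  # the reference point itself: r = 0 anyway
    out = sign * mag
    return float(out) if out.ndim == 0 else out


def attach_radial(responses: pd.DataFrame, rule: str = "speed") -> pd.DataFrame:
    """Return a copy of the trial table with the signed radial column ``r``."""
    out = responses.copy()
    out["r"] = radial_coordinate(
        out["w_duration"].to_numpy(), out["w_distance"].to_numpy(), rule=rule
    )
    return out


def fit_condition(
    responses: pd.DataFrame,
    condition: str,
    rule: str = "speed",
    sigma_ceiling_factor: float = 10.0,
    p_floor: float = 0.0,
) -> PsychFit:
    """Fit the "faster"-vs-r psychometric curve of one named condition.

    Inverted curves (negative ``jnd_signed``) are expected for heuristic
    observers in the spatial and coherent conditions.
    """
    if condition not in NAMED_CONDITIONS:
        raise ValueError(
            f"condition must be one of {NAMED_CONDITIONS}, got {condition!r}"
        )
    df = responses if "r" in responses.columns else attach_radial(responses, rule=rule)
    series = aggregate_proportions(df, axis="r", condition=condition)
    return fit_psychometric(
        series, sigma_ceiling_factor=sigma_ceiling_factor, p_floor=p_floor
    )


def convert_negative_jnds(
    records: pd.DataFrame,
    group_col: str = "group",
    jnd_col: str = "jnd_signed",
    out_col: str = "jnd_conv",
) -> pd.DataFrame:
    """Apply the negative-JND conversion within each cohort.

    For every group, negative signed JNDs become ``jnd - min + max`` where
    min and max run over all the group's signed JNDs (across conditions);
    non-negative JNDs are unchanged.  Adds ``out_col`` and returns a copy.
    """
    if len(records) == 0:
        raise ValueError("empty JND table")
    out = records.copy()
    conv = np.empty(len(out), dtype=float)
    for _, idx in out.groupby(group_col, sort=False).groups.items():
        vals = out.loc[idx, jnd_col].to_numpy(dtype=float)
        if len(vals) == 0 or not np.all(np.isfinite(vals)):
            raise ValueError(f"group {_!r} has missing or non-finite JNDs")
        lo, hi = vals.min(), vals.max()
        conv[out.index.get_indexer(idx)] = np.where(vals < 0, vals - lo + hi, vals)
    out[out_col] = conv
    return out
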