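"""Psychometric-function estimation for 2AFC "faster/slower" data.

"Faster" proportions are aggregated per stimulus level and fitted with a
two-parameter cumulative Gaussian

    p(x) = Phi((x - pse) / sigma)

by count-weighted Bernoulli maximum likelihood.  ``sigma`` is allowed
either sign: a negative sigma describes an inverted (decreasing) curve, and
its absolute value is still the just-noticeable difference (JND).  No lapse
parameter is fitted; an observer's lapses inflate the estimated sigma.

Each fit carries a goodness-of-fit gate: the squared Pearson correlation
between observed and fitted proportions (R^2) is tested with an F statistic
on (1, k - 2) degrees of freedom.  Fits that fail the gate, or whose |sigma|
exceeds a ceiling (flat curves), are replaced by the worst JND of their
cohort cell (:func:`substitute_worst`), mirroring how non-significant human
fits are interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "ProportionSeries",
    "PsychFit",
    "SelectionError",
    "SubstitutionError",
    "aggregate_proportions",
    "fit_psychometric",
    "gof_significant",
    "substitute_worst",
    "fits_to_frame",
]

_PEPS = 1e-9  # probability clip inside the likelihood


class SelectionError(ValueError):
    """A trial filter selected no trials."""


class SubstitutionError(ValueError):
    """A cohort cell has no valid, significant fit to substitute from."""


@dataclass(frozen=True)
class ProportionSeries:
    """Per-level "faster" proportions along one stimulus axis."""

    x: np.ndarray
    p_faster: np.ndarray
    n: np.ndarray
    axis_label: str = "magnitude"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        p = np.asarray(self.p_faster, dtype=float)
        n = np.asarray(self.n, dtype=int)
        if not (len(x) == len(p) == len(n)):
            raise ValueError("x, p_faster and n must have equal length")
        if np.any(n < 1):
            raise ValueError("each level needs at least one trial")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "p_faster", p)
        object.__setattr__(self, "n", n)


@dataclass
class PsychFit:
    """A fitted cumulative Gaussian.

    ``jnd_signed`` is the fitted sigma, negative for inverted (decreasing)
    curves.  ``valid`` is False when the optimizer failed, the data were
    degenerate, or the curve is effectively flat (|sigma| above the
    ceiling).  ``substituted`` marks fits whose JND was replaced by the
    worst of their cohort cell.
    """

    pse: float = np.nan
    jnd_signed: float = np.nan
    r_squared: float = np.nan
    gof_p: float = np.nan
    valid: bool = False
    substituted: bool = False
    n_levels: int = 0
    n_trials: int = 0
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "pse": self.pse,
            "jnd_signed": self.jnd_signed,
            "r_squared": self.r_squared,
            "gof_p": self.gof_p,
            "valid": self.valid,
            "substituted": self.substituted,
            "n_levels": self.n_levels,
            "n_trials": self.n_trials,
            "note": self.note,
        }


def aggregate_proportions(
    responses: pd.DataFrame,
    axis: str = "magnitude",
    orientation_deg: float | None = None,
    condition: str | None = None,
) -> ProportionSeries:
    """Aggregate "faster" proportions per distinct value of one stimulus axis.

    Parameters
    ----------
    responses : DataFrame
        Trial table with a ``response`` column ("faster"/"slower") and the
        requested axis column (``magnitude``, ``w_duration``, ``w_distance``
        or ``r``; the signed radial coordinate must have been attached by
        :func:`speedcontours.radial.attach_radial` before asking for ``r``).
    orientation_deg, condition :
        Optional filters on the trial table.
    """
    df = responses
    if orientation_deg is not None:
        df = df[np.isclose(df["orientation_deg"], orientation_deg)]
    if condition is not None:
        df = df[df["condition"] == condition]
    if len(df) == 0:
        raise SelectionError(
            f"no trials selected (orientation={orientation_deg}, condition={condition})"
        )
    if axis not in df.columns:
        raise KeyError(
            f"axis column {axis!r} not in the trial table"
            + (" (attach the radial coordinate first)" if axis == "r" else "")
        )
    x = df[axis].to_numpy(dtype=float).round(12)  # merge float twins
    faster = (df["response"] == "faster").to_numpy()
    levels = np.unique(x)
    n = np.array([(x == lv).sum() for lv in levels])
    k = np.array([faster[x == lv].sum() for lv in levels])
    return ProportionSeries(levels, k / n, n, axis_label=axis)


def _nll(
    params: np.ndarray, x: np.ndarray, k: np.ndarray, n: np.ndarray, floor: float
) -> float:
    pse, sigma = params
    if sigma == 0:
        return np.inf
    p = floor + (1.0 - 2.0 * floor) * ndtr((x - pse) / sigma)
    p = np.clip(p, _PEPS, 1 - _PEPS)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_psychometric(
    series: ProportionSeries,
    sigma_ceiling_factor: float = 10.0,
    p_floor: float = 0.0,
) -> PsychFit:
    """Fit a cumulative Gaussian to a proportion series by weighted ML.

    Requires at least 3 distinct x values.  Degenerate input (all x equal)
    yields an invalid fit rather than an exception, so batch pipelines can
    proceed and substitute.  ``|sigma| > sigma_ceiling_factor * max|x|``
    marks the curve as flat (invalid).

    ``p_floor`` compresses the fitted curve into ``[p_floor, 1 - p_floor]``
    (a fixed, symmetric guess/lapse floor, not a free parameter).  With the
    default 0 the curve is the bare two-parameter cumulative Gaussian; a
    small positive floor makes the slope estimate robust to
    stimulus-independent errors at saturated levels, which otherwise exert
    enormous leverage on sigma.
    """
    x, p, n = series.x, series.p_faster, series.n
    fit = PsychFit(n_levels=len(np.unique(x)), n_trials=int(n.sum()))
    if fit.n_levels < 3:
        fit.note = "degenerate: fewer than 3 distinct stimulus levels"
        return fit
    k = np.round(p * n)

    # moment-style start: straight-line fit of p on x gives slope/intercept
    w = n / n.sum()
    xm, pm = np.sum(w * x), np.sum(w * p)
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (p - pm)) / sxx if sxx > 0 else 0.0
    span = np.max(np.abs(x))
    if abs(slope) > 1e-8:
        sigma0 = stats.norm.pdf(0.0) / slope  # Phi'(0) = 0.3989
        pse0 = float(np.clip(xm + (0.5 - pm) / slope, -2 * span, 2 * span))
    else:
        sigma0, pse0 = 4.0 * span, float(xm)

    best = None
    for s0 in (sigma0, -sigma0):
        res = optimize.minimize(
            _nll,
            np.array([pse0, s0]),
            args=(x, k, n, p_floor),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 1500},
        )
        if best is None or res.fun < best.fun:
            best = res
    pse, sigma = best.x
    fit.pse, fit.jnd_signed = float(pse), float(sigma)

    fitted = p_floor + (1.0 - 2.0 * p_floor) * ndtr((x - pse) / sigma)
    fit.r_squared, fit.gof_p = _r_squared_gate(p, fitted)
    if not best.success and not np.isfinite(best.fun):
        fit.note = "optimizer failed"
        return fit
    if sigma == 0 or abs(sigma) > sigma_ceiling_factor * span:
        fit.note = "flat curve: |sigma| above ceiling"
        return fit
    fit.valid = True
    return fit


def _r_squared_gate(observed: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    """R^2 between observed and fitted proportions plus its F-test p-value
    on (1, k - 2) degrees of freedom."""
    kpts = len(observed)
    if kpts < 3 or np.std(observed) == 0 or np.std(fitted) == 0:
        return 0.0, 1.0
    r = np.corrcoef(observed, fitted)[0, 1]
    r2 = float(r * r)
    if r2 >= 1.0:
        return 1.0, 0.0
    f = r2 / (1.0 - r2) * (kpts - 2)
    return r2, float(stats.f.sf(f, 1, kpts - 2))


def gof_significant(fit: PsychFit, alpha: float = 0.05) -> bool:
    """True when the fit's R^2 passes its significance gate at ``alpha``."""
    if not np.isfinite(fit.gof_p):
        return False
    return bool(fit.gof_p < alpha)


def fits_to_frame(fits: dict | list[dict]) -> pd.DataFrame:
    """Stack per-cell :class:`PsychFit` results (dicts of key -> PsychFit, or a
    list of row dicts containing a ``fit`` entry) into a flat DataFrame."""
    rows = []
    items = fits.items() if isinstance(fits, dict) else enumerate(fits)
    for key, val in items:
        if isinstance(val, dict) and "fit" in val:
            row = {c: v for c, v in val.items() if c != "fit"}
            row.update(val["fit"].to_dict())
        else:
            row = {"key": key}
            row.update(val.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _conv_within(values: np.ndarray) -> np.ndarray:
    """JND_conv of signed JNDs within one cell: negatives map to
    value - min + max, non-negatives pass through."""
    lo, hi = values.min(), values.max()
    return np.where(values < 0, values - lo + hi, values)


def _worst_of(donors: np.ndarray, criterion: str) -> float:
    score = _conv_within(donors) if criterion == "conv" else np.abs(donors)
    # ties on the worst score resolve toward the larger magnitude
    return float(donors[np.lexsort((np.abs(donors), score))[-1]])


def substitute_worst(
    fits: pd.DataFrame,
    group_cols: list[str],
    alpha: float = 0.05,
    criterion: str = "conv",
    fallback_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Replace invalid or non-significant JNDs by the worst JND of their cell.

    A cell is one combination of ``group_cols`` (e.g. cohort x condition).
    Within each cell the donor is the valid, significant fit with the worst
    discrimination precision; "worst" is ordered either by the converted
    JND (``criterion="conv"``, appropriate for signed radial-axis JNDs
    where an inverted curve is always worst) or by absolute magnitude
    (``criterion="abs"``, appropriate for contour radii).  Valid significant
    fits are never altered.

    A cell may contain no usable donor at all (a whole cohort can be blind
    to one orientation).  By default that raises; when ``fallback_cols`` is
    given (a coarser grouping, e.g. the cohort alone, or ``[]`` for the
    whole table) the donor pool widens to that level instead.

    Raises
    ------
    SubstitutionError
        If some cell (after any fallback) has no valid, significant fit.
    """
    if criterion not in ("conv", "abs"):
        raise ValueError("criterion must be 'conv' or 'abs'")
    out = fits.copy()
    out["substituted"] = out.get("substituted", False)
    ok = out["valid"] & (out["gof_p"] < alpha)
    bad_cells = []
    for key, idx in out.groupby(group_cols, sort=False).groups.items():
        idx = np.asarray(idx)
        cell_ok = ok.loc[idx].to_numpy()
        if cell_ok.all():
            continue
        if cell_ok.any():
            donors = out.loc[idx[cell_ok], "jnd_signed"].to_numpy(dtype=float)
        elif fallback_cols is not None:
            if fallback_cols:
                row = out.loc[idx[0], fallback_cols]
                wider = (out[fallback_cols] == row.to_numpy()).all(axis=1)
            else:
                wider = pd.Series(True, index=out.index)
            donors = out.loc[wider & ok, "jnd_signed"].to_numpy(dtype=float)
            if donors.size == 0:
                bad_cells.append(key)
                continue
        else:
            bad_cells.append(key)
            continue
        out.loc[idx[~cell_ok], "jnd_signed"] = _worst_of(donors, criterion)
        out.loc[idx[~cell_ok], "substituted"] = True
    if bad_cells:
        raise SubstitutionError(
            f"no valid significant fit to substitute from in cells: {bad_cells}"
        )
    return out
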