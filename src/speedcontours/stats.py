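"""Permutation inference and effect sizes for cohort JND tables.

All tests are two-sided permutation tests with ``(count + 1)/(n_iter + 1)``
p-values under random resampling; whenever the full permutation set is
small enough (at most ``max_exact`` elements, default 20000, covering e.g.
2^10 sign patterns and the 12870 splits of an 8+8 comparison) the test
switches automatically to exhaustive enumeration and the p-value is exact.
Effect sizes follow the conventional pairings: Hedges' g (with the exact
small-sample correction) for t-type tests, Cramer's V for contingency
tables, partial eta^2 for ANOVA effects.  Confidence intervals are t-based
and labelled as such.

The mixed ANOVA uses the classical two-factor mixed-design decomposition
(between-subjects Group against the subject-within-group mean square;
within-subjects Condition and the interaction against the condition-by-
subject residual).  Its permutation scheme respects the exchangeability
units of the design: Group p-values come from permuting group labels
across subjects, Condition and interaction p-values from permuting
condition labels independently within each subject after removing subject
means (Freedman-Lane-style residual permutation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "AnovaResult",
    "DegenerateDataError",
    "LayoutError",
    "hedges_g_correction",
    "perm_t_one_sample",
    "perm_t_two_sample",
    "perm_t_paired",
    "perm_mixed_anova",
    "chi_square_corner",
    "chi_square_2x2",
    "adjust_bonferroni",
    "shapiro_wilk",
    "wrap_axial",
]

MAX_EXACT = 20000  # largest permutation set enumerated exhaustively
_TIE_EPS = 1e-12  # tolerance when counting |t*| >= |t|


class DegenerateDataError(ValueError):
    """Zero-variance input where a variance is required."""


class LayoutError(ValueError):
    """Incomplete subject x condition layout for the mixed ANOVA."""


@dataclass
class TestResult:
    """Outcome of one permutation (or classical) test."""

    statistic: float
    p_value: float
    n_iterations: int
    ci_95: tuple[float, float] = (np.nan, np.nan)
    effect_size: float = np.nan
    effect_size_label: str = ""
    exact: bool = False
    seed: int | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_iterations": self.n_iterations,
            "ci_95": list(self.ci_95),
            "effect_size": self.effect_size,
            "effect_size_label": self.effect_size_label,
            "exact": self.exact,
            "note": self.note,
        }


@dataclass
class AnovaResult:
    """Permutation mixed-ANOVA outcome: one entry per effect."""

    effects: dict[str, dict] = field(default_factory=dict)
    n_iterations: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"effects": self.effects, "n_iterations": self.n_iterations}


def wrap_axial(diff) -> np.ndarray | float:
    """Wrap orientation differences into (-90, 90] degrees (axial data)."""
    d = (np.asarray(diff, dtype=float) + 90.0) % 180.0 - 90.0
    d = np.where(d == -90.0, 90.0, d)
    return float(d) if d.ndim == 0 else d


def hedges_g_correction(df: int) -> float:
    """Exact small-sample correction J(df) = Gamma(df/2) / (sqrt(df/2) Gamma((df-1)/2))."""
    if df < 2:
        return np.nan
    return float(
        np.exp(gammaln(df / 2.0) - 0.5 * np.log(df / 2.0) - gammaln((df - 1) / 2.0))
    )


def _t_stats_signed(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t statistics of d under an array of sign patterns."""
    flipped = signs * d
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    n = d.size
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    t = np.where((sd == 0) & (mean != 0), np.copysign(np.inf, mean), t)
    return t


def perm_t_one_sample(
    values,
    target: float = 0.0,
    n_iter: int = 5000,
    seed: int | None = None,
    wrap: bool = False,
    max_exact: int = MAX_EXACT,
) -> TestResult:
    """Two-sided sign-flip permutation one-sample t-test of mean(d) = 0.

    ``d = values - target``, axially wrapped into (-90, 90] when ``wrap``
    (appropriate when comparing ellipse orientations to a dominant
    orientation, since axial angles are defined modulo 180 degrees).  Null
    distribution by random (or, when 2^n <= ``max_exact``, exhaustive) sign
    flips of d.  Effect size is Hedges' g of the differences; the CI is the
    t-based 95% interval on the mean difference.
    """
    d = np.asarray(values, dtype=float) - target
    if wrap:
        d = np.atleast_1d(wrap_axial(d))
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean, sd = d.mean(), d.std(ddof=1)
    if np.all(d == 0):
        return TestResult(0.0, 1.0, 0, ci_95=(0.0, 0.0), effect_size=0.0,
                          effect_size_label="hedges_g", exact=True, seed=seed,
                          note="all differences zero")
    t_obs = float(_t_stats_signed(d, np.ones((1, n)))[0])

    if 2**n <= max_exact:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        signs = 2 * bits - 1
        t_null = _t_stats_signed(d, signs)
        p = float(np.mean(np.abs(t_null) >= abs(t_obs) - _TIE_EPS))
        n_done, exact = 2**n, True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_iter, n))
        t_null = _t_stats_signed(d, signs)
        hits = int(np.sum(np.abs(t_null) >= abs(t_obs) - _TIE_EPS))
        p = (hits + 1) / (n_iter + 1)
        n_done, exact = n_iter, False

    g = (mean / sd) * hedges_g_correction(n - 1) if sd > 0 else np.nan
    if sd > 0:
        half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci = (mean - half, mean + half)
    else:
        ci = (mean, mean)
    return TestResult(t_obs, p, n_done, ci_95=ci, effect_size=float(g),
                      effect_size_label="hedges_g", exact=exact, seed=seed)


def perm_t_paired(
    a, b, n_iter: int = 5000, seed: int | None = None, wrap: bool = False
) -> TestResult:
    """Paired-samples permutation t-test: sign flips of the pair differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return perm_t_one_sample(a - b, 0.0, n_iter=n_iter, seed=seed, wrap=wrap)


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        return 0.0 if ma == mb else math.inf * math.copysign(1.0, ma - mb)
    return float((ma - mb) / math.sqrt(se2))


def perm_t_two_sample(
    a,
    b,
    n_iter: int = 5000,
    seed: int | None = None,
    max_exact: int = MAX_EXACT,
) -> TestResult:
    """Two-sided label-shuffle permutation test on a Welch t statistic.

    Exhaustive over all C(na+nb, na) group assignments when that count is
    at most ``max_exact``.  Hedges' g uses the pooled standard deviation
    with the exact small-sample correction; zero pooled variance with
    unequal means is flagged as degenerate (g undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    t_obs = _welch_t(a, b)

    n_comb = math.comb(na + nb, na)
    if n_comb <= max_exact:
        idx_all = np.fromiter(
            itertools.chain.from_iterable(
                itertools.combinations(range(na + nb), na)
            ),
            dtype=int,
        ).reshape(n_comb, na)
        hits = 0
        mask = np.zeros(na + nb, dtype=bool)
        for idx in idx_all:
            mask[:] = False
            mask[idx] = True
            t_star = _welch_t(pooled[mask], pooled[~mask])
            if abs(t_star) >= abs(t_obs) - _TIE_EPS:
                hits += 1
        p = hits / n_comb
        n_done, exact = n_comb, True
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_iter):
            perm = rng.permutation(na + nb)
            t_star = _welch_t(pooled[perm[:na]], pooled[perm[na:]])
            if abs(t_star) >= abs(t_obs) - _TIE_EPS:
                hits += 1
        p = (hits + 1) / (n_iter + 1)
        n_done, exact = n_iter, False

    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    note = ""
    if sp2 == 0:
        g = 0.0 if a.mean() == b.mean() else np.nan
        note = "degenerate: zero pooled variance"
    else:
        g = (a.mean() - b.mean()) / math.sqrt(sp2) * hedges_g_correction(na + nb - 2)
    # Welch CI on the mean difference
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 > 0:
        dfw = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        half = sps.t.ppf(0.975, dfw) * math.sqrt(se2)
        ci = (a.mean() - b.mean() - half, a.mean() - b.mean() + half)
    else:
        ci = (a.mean() - b.mean(),) * 2
    return TestResult(t_obs, p, n_done, ci_95=ci, effect_size=float(g),
                      effect_size_label="hedges_g", exact=exact, seed=seed, note=note)


def _mixed_f(y: np.ndarray, grp: np.ndarray) -> tuple[np.ndarray, ...]:
    """F statistics (group, condition, interaction) and the matching SS pairs.

    ``y`` has shape (..., n_subjects, n_conditions); ``grp`` is a boolean
    (n_subjects,) mask of the first group.  Classical balanced mixed-design
    decomposition with subjects nested in groups.
    """
    n, c = y.shape[-2], y.shape[-1]
    n0, n1 = int(grp.sum()), int((~grp).sum())
    subj = y.mean(axis=-1)                       # (..., n)
    gm = y.mean(axis=(-2, -1))                   # (...,)
    g0 = subj[..., grp].mean(axis=-1)
    g1 = subj[..., ~grp].mean(axis=-1)
    ss_between = c * ((subj - gm[..., None]) ** 2).sum(axis=-1)
    ss_group = c * (n0 * (g0 - gm) ** 2 + n1 * (g1 - gm) ** 2)
    ss_subjw = ss_between - ss_group
    cond = y.mean(axis=-2)                       # (..., c)
    ss_cond = n * ((cond - gm[..., None]) ** 2).sum(axis=-1)
    cell0 = y[..., grp, :].mean(axis=-2)         # (..., c)
    cell1 = y[..., ~grp, :].mean(axis=-2)
    dev0 = cell0 - g0[..., None] - cond + gm[..., None]
    dev1 = cell1 - g1[..., None] - cond + gm[..., None]
    ss_inter = n0 * (dev0**2).sum(axis=-1) + n1 * (dev1**2).sum(axis=-1)
    ss_ws = ((y - subj[..., None]) ** 2).sum(axis=(-2, -1))
    ss_err = ss_ws - ss_cond - ss_inter
    df_err = (n - 2) * (c - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_group = (ss_group / 1.0) / (ss_subjw / (n - 2))
        f_cond = (ss_cond / (c - 1)) / (ss_err / df_err)
        f_inter = (ss_inter / (c - 1)) / (ss_err / df_err)
    f_group = np.where(np.isfinite(f_group), f_group,
                       np.where(ss_group == 0, 0.0, np.inf))
    f_cond = np.where(np.isfinite(f_cond), f_cond,
                      np.where(ss_cond == 0, 0.0, np.inf))
    f_inter = np.where(np.isfinite(f_inter), f_inter,
                       np.where(ss_inter == 0, 0.0, np.inf))
    return f_group, f_cond, f_inter, ss_group, ss_subjw, ss_cond, ss_inter, ss_err


def perm_mixed_anova(
    table: pd.DataFrame,
    dv: str = "jnd_conv",
    within: str = "condition",
    between: str = "group",
    subject: str = "subject_id",
    n_iter: int = 5000,
    seed: int | None = None,
) -> AnovaResult:
    """Permutation mixed-design ANOVA on a long-format JND table.

    Requires a complete two-group x c-condition layout: every subject must
    have exactly one value per condition.  Returns per-effect F, permutation
    p and partial eta^2 (= SS_effect / (SS_effect + SS_error-for-effect)).
    """
    wide = table.pivot_table(index=[subject, between], columns=within, values=dv,
                             aggfunc="first")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].get_level_values(0).tolist()
        raise LayoutError(f"incomplete condition layout for subjects: {bad}")
    counts = table.groupby([subject, within]).size()
    if (counts > 1).any():
        dup = counts[counts > 1].index.get_level_values(0).unique().tolist()
        raise LayoutError(f"duplicate condition rows for subjects: {dup}")
    groups = wide.index.get_level_values(1)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise LayoutError(f"need exactly 2 groups, got {list(labels)}")
    y = wide.to_numpy(dtype=float)
    grp = np.asarray(groups == labels[0])
    n, c = y.shape
    if grp.sum() < 2 or (~grp).sum() < 2:
        raise LayoutError("each group needs at least 2 subjects")

    (f_g, f_c, f_i, ss_g, ss_sw, ss_c, ss_i, ss_e) = _mixed_f(y, grp)
    rng = np.random.default_rng(seed)

    # Group effect: permute group membership across subjects.  Only subject
    # means enter F_group, and the between-subjects SS is label-invariant,
    # so the null distribution vectorizes over permutations.
    subj_means = y.mean(axis=1)
    n0 = int(grp.sum())
    n1 = n - n0
    gm_all = float(y.mean())
    ss_between = c * float(np.sum((subj_means - gm_all) ** 2))
    picks = np.argsort(rng.random((n_iter, n)), axis=1)[:, :n0]
    s0 = np.take(subj_means, picks).sum(axis=1)
    g0n = s0 / n0
    g1n = (subj_means.sum() - s0) / n1
    ss_g_null = c * (n0 * (g0n - gm_all) ** 2 + n1 * (g1n - gm_all) ** 2)
    ss_sw_null = ss_between - ss_g_null
    with np.errstate(divide="ignore", invalid="ignore"):
        f_g_null = ss_g_null / (ss_sw_null / (n - 2))
    f_g_null = np.where(np.isfinite(f_g_null), f_g_null,
                        np.where(ss_g_null == 0, 0.0, np.inf))
    p_g = (np.sum(f_g_null >= f_g - _TIE_EPS) + 1) / (n_iter + 1)

    # Condition and interaction: permute condition labels within subjects
    # on subject-centered data (Freedman-Lane residual permutation).
    yc = y - subj_means[:, None]
    order = np.argsort(rng.random((n_iter, n, c)), axis=-1)
    y_null = np.take_along_axis(np.broadcast_to(yc, (n_iter, n, c)), order, axis=-1)
    _, f_c_null, f_i_null, *_ = _mixed_f(y_null, grp)
    p_c = (np.sum(f_c_null >= f_c - _TIE_EPS) + 1) / (n_iter + 1)
    p_i = (np.sum(f_i_null >= f_i - _TIE_EPS) + 1) / (n_iter + 1)

    def eta(ss_eff, ss_err):
        tot = ss_eff + ss_err
        return float(ss_eff / tot) if tot > 0 else 0.0

    effects = {
        "group": {"F": float(f_g), "p_perm": float(p_g),
                  "partial_eta_sq": eta(ss_g, ss_sw), "df": (1, n - 2)},
        "condition": {"F": float(f_c), "p_perm": float(p_c),
                      "partial_eta_sq": eta(ss_c, ss_e),
                      "df": (c - 1, (n - 2) * (c - 1))},
        "interaction": {"F": float(f_i), "p_perm": float(p_i),
                        "partial_eta_sq": eta(ss_i, ss_e),
                        "df": (c - 1, (n - 2) * (c - 1))},
    }
    return AnovaResult(effects=effects, n_iterations=n_iter, seed=seed)


def chi_square_2x2(counts: np.ndarray) -> tuple[float, float, float, str]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns (chi2, p, Cramer's V, note).  A zero margin makes the statistic
    undefined; it is reported as 0 with a flag instead of raising.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    total = obs.sum()
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0) or total == 0:
        return 0.0, 1.0, 0.0, "degenerate: zero margin, statistic undefined"
    expected = np.outer(rows, cols) / total
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    p = float(sps.chi2.sf(chi2, 1))
    v = float(np.sqrt(chi2 / total))
    return chi2, p, v, ""


def chi_square_corner(
    responses: pd.DataFrame,
    point_a: tuple[float, float],
    point_b: tuple[float, float],
    atol: float = 1e-9,
) -> TestResult:
    """Compare "faster" proportions between two points of the stimulus plane.

    ``point_a`` and ``point_b`` are (w_duration, w_distance) coordinates;
    trials are matched by proximity (``atol``).  A 2x2 point x response
    contingency table is tested with a 1-df Pearson chi-square, Cramer's V,
    and a Wald 95% CI on the difference of "faster" proportions (a - b).
    """
    def _select(pt):
        m = np.isclose(responses["w_duration"], pt[0], atol=atol) & np.isclose(
            responses["w_distance"], pt[1], atol=atol
        )
        return responses[m]

    sel_a, sel_b = _select(point_a), _select(point_b)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("both plane points need trials")
    ka = int((sel_a["response"] == "faster").sum())
    kb = int((sel_b["response"] == "faster").sum())
    na, nb = len(sel_a), len(sel_b)
    counts = np.array([[ka, na - ka], [kb, nb - kb]], dtype=float)
    chi2, p, v, note = chi_square_2x2(counts)
    pa, pb = ka / na, kb / nb
    se = math.sqrt(pa * (1 - pa) / na + pb * (1 - pb) / nb)
    z = sps.norm.ppf(0.975)
    ci = (pa - pb - z * se, pa - pb + z * se)
    return TestResult(chi2, p, 0, ci_95=ci, effect_size=v,
                      effect_size_label="cramers_v", exact=False, note=note)


def adjust_bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) for a family of m comparisons."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("family size m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (thin wrapper for report completeness)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise DegenerateDataError("constant input: normality test undefined")
    w, p = sps.shapiro(v)
    return TestResult(float(w), float(p), 0, effect_size_label="", note="shapiro_wilk")
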