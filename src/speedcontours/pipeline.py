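"""End-to-end pipeline: design -> simulate -> fit -> contours + radial -> stats.

The pipeline reproduces the full analysis chain on a simulated cohort:

1. build each subject's randomized trial schedule;
2. simulate 2AFC responses from jittered cue-weighted observers;
3. fit per-orientation psychometric curves on the magnitude axis, gate them
   on goodness of fit, and substitute failed fits with the worst JND of
   their cohort cell;
4. build each subject's 16-point discrimination contour and fit its
   ellipse (subjects whose point set rejects the ellipse fit - possible in
   ``conic`` mode - are excluded from the orientation statistics only);
5. fit per-condition psychometric curves on the signed radial coordinate,
   substitute, and convert negative JNDs to the common precision scale;
6. run the statistical battery: normality checks, orientation-vs-dominant
   permutation t-tests, between-group orientation test, permutation mixed
   ANOVA on JND_conv with post-hocs, and the corner chi-square comparison.

Every output file records the config hash and global seed that produced
it; two runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import contours, psychometrics, radial, stats
from .config import AnalysisConfig, PipelineConfig, config_hash
from .design import DesignConfig, build_design, magnitude_grid, orientation_angles
from .observers import ObserverParams, observer_preset, simulate_responses

__all__ = [
    "PipelineResult",
    "PipelineError",
    "simulate_cohort",
    "fit_orientation_curves",
    "fit_subject_ellipses",
    "fit_radial_jnds",
    "single_observer_ellipse",
    "corner_points",
    "run_group_stats",
    "run_pipeline",
    "write_outputs",
]

DOMINANT_ORIENTATIONS = {"duration": 0.0, "speed": 45.0, "distance": 90.0}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    config: PipelineConfig
    responses: pd.DataFrame
    orientation_fits: pd.DataFrame
    ellipses: pd.DataFrame
    excluded_subjects: list
    jnd_records: pd.DataFrame
    stats_report: dict
    observers: pd.DataFrame = field(default_factory=pd.DataFrame)


def _jittered_observer(
    base: ObserverParams, rng: np.random.Generator, cohort
) -> ObserverParams:
    w = np.array([base.weight_speed, base.weight_duration, base.weight_distance])
    w = np.clip(w + rng.normal(0.0, cohort.weight_jitter_sd, 3), 0.0, None)
    if not np.any(w > 0):
        w = np.array([base.weight_speed, base.weight_duration, base.weight_distance])
    noise = max(0.05, base.noise_sd + rng.normal(0.0, cohort.noise_jitter_sd))
    return replace(
        base,
        weight_speed=float(w[0]),
        weight_duration=float(w[1]),
        weight_distance=float(w[2]),
        noise_sd=float(noise),
    )


def simulate_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every subject of the configured cohort.

    Returns the pooled response table (with ``group`` column) and a table
    of each subject's realized observer parameters.
    """
    root = np.random.SeedSequence(config.seed)
    frames, obs_rows = [], []
    subj_counter = 0
    group_items = list(config.cohort.groups.items())
    all_ss = root.spawn(sum(spec.n for _, spec in group_items))
    for label, spec in group_items:
        base = observer_preset(spec.preset)
        for i in range(spec.n):
            ss = all_ss[subj_counter]
            subj_counter += 1
            rng = np.random.default_rng(ss)
            subject_id = f"{label}{i + 1:02d}"
            obs = _jittered_observer(base, rng, config.cohort)
            design = build_design(
                replace(config.design, seed=int(ss.generate_state(1)[0] % 2**31)),
                subject_id=subject_id,
            )
            resp = simulate_responses(design, obs, seed=rng)
            resp.insert(1, "group", label)
            frames.append(resp)
            obs_rows.append(
                {
                    "subject_id": subject_id,
                    "group": label,
                    "preset": spec.preset,
                    "weight_speed": obs.weight_speed,
                    "weight_duration": obs.weight_duration,
                    "weight_distance": obs.weight_distance,
                    "spatial_sign": obs.spatial_sign,
                    "noise_sd": obs.noise_sd,
                    "lapse": obs.lapse,
                }
            )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(obs_rows)


def fit_orientation_curves(
    responses: pd.DataFrame,
    analysis: AnalysisConfig | None = None,
    substitution_cells: list[str] | None = None,
) -> pd.DataFrame:
    """Fit one magnitude-axis psychometric curve per subject x orientation.

    Failed or non-significant fits receive the worst |JND| of their
    substitution cell (default: cohort group x orientation; for a lone
    subject pass ``["subject_id"]`` to pool across that subject's
    orientations, the only sample available).
    """
    analysis = analysis or AnalysisConfig()
    rows = []
    for (subject, angle), df in responses.groupby(
        ["subject_id", "orientation_deg"], sort=True
    ):
        series = psychometrics.aggregate_proportions(df, axis="magnitude")
        fit = psychometrics.fit_psychometric(
            series,
            sigma_ceiling_factor=analysis.sigma_ceiling_factor,
            p_floor=analysis.fit_p_floor,
        )
        row = {
            "subject_id": subject,
            "orientation_deg": float(angle),
            "condition": df["condition"].iloc[0],
        }
        if "group" in df.columns:
            row["group"] = df["group"].iloc[0]
        row.update(fit.to_dict())
        rows.append(row)
    fits = pd.DataFrame(rows)
    fallback = None
    if substitution_cells is None:
        if "group" in fits.columns:
            substitution_cells, fallback = ["group", "orientation_deg"], ["group"]
        else:
            substitution_cells = ["subject_id"]
    return psychometrics.substitute_worst(
        fits, substitution_cells, alpha=analysis.alpha, criterion="abs",
        fallback_cols=fallback,
    )


def fit_subject_ellipses(
    orientation_fits: pd.DataFrame, analysis: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, list]:
    """Fit one contour ellipse per subject; collect non-elliptical subjects.

    Returns the ellipse table and a list of (subject_id, reason) pairs for
    subjects whose JND set rejected the ellipse fit; they are excluded from
    the orientation statistics only.
    """
    analysis = analysis or AnalysisConfig()
    rows, excluded = [], []
    for subject, df in orientation_fits.groupby("subject_id", sort=True):
        try:
            pts = contours.contour_points(df)
            ell = contours.fit_ellipse(pts, method=analysis.ellipse_method)
        except (contours.NotAnEllipseError, contours.ContourError) as err:
            excluded.append((subject, str(err)))
            continue
        row = {
            "subject_id": subject,
            "center_w_duration": ell.center[0],
            "center_w_distance": ell.center[1],
            "semi_major": ell.semi_major,
            "semi_minor": ell.semi_minor,
            "theta_deg": ell.theta_deg,
        }
        if "group" in df.columns:
            row["group"] = df["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows), excluded


def fit_radial_jnds(
    responses: pd.DataFrame, analysis: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per subject x named condition: signed radial JND and JND_conv.

    Fits the "faster"-vs-r curve for each of the four named conditions,
    substitutes failed fits with the worst converted JND of the group x
    condition cell, then applies the negative-JND conversion per group.
    """
    analysis = analysis or AnalysisConfig()
    df = radial.attach_radial(responses, rule=analysis.sign_rule)
    rows = []
    for subject, sub in df.groupby("subject_id", sort=True):
        for condition in radial.NAMED_CONDITIONS:
            fit = radial.fit_condition(
                sub,
                condition,
                sigma_ceiling_factor=analysis.sigma_ceiling_factor,
                p_floor=analysis.fit_p_floor,
            )
            row = {"subject_id": subject, "condition": condition}
            if "group" in sub.columns:
                row["group"] = sub["group"].iloc[0]
            row.update(fit.to_dict())
            rows.append(row)
    fits = pd.DataFrame(rows)
    if "group" in fits.columns:
        cells, fallback = ["group", "condition"], ["group"]
    else:
        cells, fallback = ["condition"], []
    fits = psychometrics.substitute_worst(
        fits, cells, alpha=analysis.alpha, criterion="conv", fallback_cols=fallback
    )
    group_col = "group" if "group" in fits.columns else "condition"
    fits = radial.convert_negative_jnds(fits, group_col=group_col)
    keep = [
        c
        for c in [
            "subject_id",
            "group",
            "condition",
            "pse",
            "jnd_signed",
            "jnd_conv",
            "r_squared",
            "gof_p",
            "valid",
            "substituted",
        ]
        if c in fits.columns
    ]
    return fits[keep]


def single_observer_ellipse(
    preset: str,
    n_reps: int = 60,
    noise_sd: float = 0.3,
    lapse: float = 0.02,
    seed: int = 0,
    design: DesignConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> contours.EllipseFit:
    """Contour ellipse of one simulated observer preset, end to end.

    Builds the default design at ``n_reps`` repetitions per level,
    simulates the named observer, fits and substitutes the per-orientation
    psychometric curves (pooling the substitution over the lone subject's
    own orientations), and fits the contour ellipse.
    """
    analysis = analysis or AnalysisConfig()
    ss = np.random.SeedSequence(seed)
    s_design, s_obs = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    cfg = design or DesignConfig()
    cfg = replace(cfg, n_reps=n_reps, seed=s_design)
    schedule = build_design(cfg, subject_id=preset)
    obs = observer_preset(preset, noise_sd=noise_sd, lapse=lapse)
    resp = simulate_responses(schedule, obs, seed=s_obs)
    fits = fit_orientation_curves(resp, analysis, substitution_cells=["subject_id"])
    pts = contours.contour_points(fits)
    return contours.fit_ellipse(pts, method=analysis.ellipse_method)


def corner_points(design_cfg: DesignConfig | None = None) -> tuple[tuple, tuple]:
    """The two opposite-condition corner points of the default plane:
    (shorter duration / longer distance, longer duration / shorter distance)."""
    cfg = design_cfg or DesignConfig()
    mags = magnitude_grid(135.0, cfg)
    s, c = np.sin(np.radians(135.0)), np.cos(np.radians(135.0))
    lo, hi = mags[0], mags[-1]
    upper_left = (lo * s, lo * c)  # negative magnitude: w_t < 0 < w_d
    lower_right = (hi * s, hi * c)
    return upper_left, lower_right


def run_group_stats(
    ellipses: pd.DataFrame,
    jnd_records: pd.DataFrame,
    responses: pd.DataFrame,
    analysis: AnalysisConfig | None = None,
    design_cfg: DesignConfig | None = None,
    seed: int = 0,
) -> dict:
    """The full statistical battery on cohort tables (see module docstring)."""
    analysis = analysis or AnalysisConfig()
    rng_seeds = iter(
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(64)
    )
    report: dict = {"alpha": analysis.alpha, "n_iter": analysis.n_iter}
    groups = list(pd.unique(jnd_records["group"]))

    # --- ellipse orientation: normality, dominant-orientation tests -------
    orient: dict = {}
    for g in groups:
        th = ellipses.loc[ellipses["group"] == g, "theta_deg"].to_numpy()
        entry: dict = {"n": int(th.size), "theta_deg": th.tolist()}
        if th.size >= 3:
            sw = stats.shapiro_wilk(stats.wrap_axial(th))
            entry["shapiro"] = {"W": sw.statistic, "p": sw.p_value}
        tests = {}
        for name, angle in DOMINANT_ORIENTATIONS.items():
            res = stats.perm_t_one_sample(
                th, angle, n_iter=analysis.n_iter, seed=next(rng_seeds), wrap=True
            )
            tests[name] = res.to_dict()
        padj = stats.adjust_bonferroni([tests[k]["p_value"] for k in tests])
        for k, pa in zip(tests, padj):
            tests[k]["p_bonferroni"] = float(pa)
        entry["vs_dominant"] = tests
        orient[g] = entry
    if len(groups) == 2:
        th_a = ellipses.loc[ellipses["group"] == groups[0], "theta_deg"].to_numpy()
        th_b = ellipses.loc[ellipses["group"] == groups[1], "theta_deg"].to_numpy()
        if th_a.size >= 2 and th_b.size >= 2:
            res = stats.perm_t_two_sample(
                stats.wrap_axial(th_a),
                stats.wrap_axial(th_b),
                n_iter=analysis.n_iter,
                seed=next(rng_seeds),
            )
            orient["between_groups"] = res.to_dict()
    report["orientation"] = orient

    # --- JND_conv: normality, mixed ANOVA, post-hocs ----------------------
    prec: dict = {}
    for g in groups:
        vals = jnd_records.loc[jnd_records["group"] == g, "jnd_conv"].to_numpy()
        sw = stats.shapiro_wilk(vals)
        prec[g] = {"shapiro": {"W": sw.statistic, "p": sw.p_value}}
    anova = stats.perm_mixed_anova(
        jnd_records, dv="jnd_conv", n_iter=analysis.n_iter, seed=next(rng_seeds)
    )
    prec["anova"] = anova.to_dict()

    wide = jnd_records.pivot_table(
        index="subject_id", columns="condition", values="jnd_conv", aggfunc="first"
    )
    conds = list(radial.NAMED_CONDITIONS)
    pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1 :]]
    posthoc_cond = {}
    for a, b in pairs:
        res = stats.perm_t_paired(
            wide[a].to_numpy(), wide[b].to_numpy(),
            n_iter=analysis.n_iter, seed=next(rng_seeds),
        )
        posthoc_cond[f"{a}_vs_{b}"] = res.to_dict()
    padj = stats.adjust_bonferroni([v["p_value"] for v in posthoc_cond.values()])
    for k, pa in zip(posthoc_cond, padj):
        posthoc_cond[k]["p_bonferroni"] = float(pa)
    prec["posthoc_condition"] = posthoc_cond

    if len(groups) == 2:
        posthoc_grp = {}
        for cond in conds:
            sel = jnd_records[jnd_records["condition"] == cond]
            va = sel.loc[sel["group"] == groups[0], "jnd_conv"].to_numpy()
            vb = sel.loc[sel["group"] == groups[1], "jnd_conv"].to_numpy()
            res = stats.perm_t_two_sample(
                va, vb, n_iter=analysis.n_iter, seed=next(rng_seeds)
            )
            posthoc_grp[cond] = res.to_dict()
        padj = stats.adjust_bonferroni([v["p_value"] for v in posthoc_grp.values()])
        for k, pa in zip(posthoc_grp, padj):
            posthoc_grp[k]["p_bonferroni"] = float(pa)
        prec["posthoc_group_by_condition"] = posthoc_grp
    report["precision"] = prec

    # --- corner comparison: temporal-assumption signature ------------------
    ul, lr = corner_points(design_cfg)
    corner: dict = {"short_dur_long_dist": list(ul), "long_dur_short_dist": list(lr)}
    for g in groups:
        sel = responses[responses["group"] == g] if "group" in responses else responses
        res = stats.chi_square_corner(sel, ul, lr)
        corner[g] = res.to_dict()
    report["corner_chi_square"] = corner
    return report


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Execute the whole pipeline; optionally write the report bundle."""
    config = config or PipelineConfig()
    try:
        responses, observers = simulate_cohort(config)
    except Exception as err:
        raise PipelineError(f"simulate stage failed: {err}") from err
    try:
        orientation_fits = fit_orientation_curves(responses, config.analysis)
    except Exception as err:
        raise PipelineError(f"psychometrics stage failed: {err}") from err
    try:
        ellipses, excluded = fit_subject_ellipses(orientation_fits, config.analysis)
    except Exception as err:
        raise PipelineError(f"contours stage failed: {err}") from err
    try:
        jnd_records = fit_radial_jnds(responses, config.analysis)
    except Exception as err:
        raise PipelineError(f"radial stage failed: {err}") from err
    try:
        seeds = np.random.SeedSequence(config.seed).spawn(2)
        stats_seed = int(seeds[1].generate_state(1)[0] % 2**31)
        report = run_group_stats(
            ellipses, jnd_records, responses, config.analysis,
            design_cfg=config.design, seed=stats_seed,
        )
    except Exception as err:
        raise PipelineError(f"stats stage failed: {err}") from err
    report["excluded_from_orientation"] = [
        {"subject_id": s, "reason": r} for s, r in excluded
    ]
    result = PipelineResult(
        config=config,
        responses=responses,
        orientation_fits=orientation_fits,
        ellipses=ellipses,
        excluded_subjects=excluded,
        jnd_records=jnd_records,
        stats_report=report,
        observers=observers,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _write_csv(df: pd.DataFrame, path: Path, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=False)


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the report bundle: CSV tables, JSON stats, YAML config, summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    note = f"config_hash={config_hash(result.config)} seed={result.config.seed}"
    _write_csv(result.responses, out / "responses.csv", note)
    _write_csv(result.orientation_fits, out / "orientation_fits.csv", note)
    _write_csv(result.ellipses, out / "ellipses.csv", note)
    _write_csv(result.jnd_records, out / "jnd_records.csv", note)
    _write_csv(result.observers, out / "observers.csv", note)
    report = {"meta": {"config_hash": config_hash(result.config),
                       "seed": result.config.seed}}
    report.update(result.stats_report)
    (out / "stats.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(
        f"# {note}\n" + result.config.to_yaml()
    )
    (out / "summary.txt").write_text(render_summary(result))


def render_summary(result: PipelineResult) -> str:
    """Short human-readable account of one run."""
    rep = result.stats_report
    lines = [
        f"speedcontours pipeline summary (seed={result.config.seed}, "
        f"config={config_hash(result.config)})",
        f"subjects: {result.responses['subject_id'].nunique()}  "
        f"trials: {len(result.responses)}",
        "",
        "Ellipse orientation (deg from the vertical distance axis):",
    ]
    for g, df in result.ellipses.groupby("group"):
        th = stats.wrap_axial(df["theta_deg"].to_numpy())
        lines.append(
            f"  {g}: mean {np.mean(th):6.2f}, sd {np.std(th, ddof=1):5.2f} "
            f"(n={len(df)})"
        )
    if result.excluded_subjects:
        lines.append(
            "  excluded from orientation stats: "
            + ", ".join(s for s, _ in result.excluded_subjects)
        )
    for g, entry in rep["orientation"].items():
        if g == "between_groups":
            lines.append(
                f"  between groups: t={entry['statistic']:.2f} p={entry['p_value']:.4g}"
            )
            continue
        for name, t in entry["vs_dominant"].items():
            lines.append(
                f"  {g} vs {name}-dominant: t={t['statistic']:.2f} "
                f"p={t['p_value']:.4g} (bonf {t['p_bonferroni']:.4g}) "
                f"g={t['effect_size']:.2f}"
            )
    lines.append("")
    lines.append("Speed-discrimination precision (JND_conv):")
    for g, df in result.jnd_records.groupby("group"):
        lines.append(f"  {g}: mean {df['jnd_conv'].mean():.3f}")
    for eff, d in rep["precision"]["anova"]["effects"].items():
        lines.append(
            f"  ANOVA {eff}: F={d['F']:.2f} p_perm={d['p_perm']:.4g} "
            f"partial_eta2={d['partial_eta_sq']:.3f}"
        )
    lines.append("")
    lines.append("Corner comparison (temporal assumption):")
    for g in result.jnd_records["group"].unique():
        d = rep["corner_chi_square"][g]
        lines.append(
            f"  {g}: chi2={d['statistic']:.2f} p={d['p_value']:.4g} "
            f"V={d['effect_size']:.2f}"
        )
    return "\n".join(lines) + "\n"
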