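"""Cohort-level experiment: the 2x2(x2) individualization design.

For every synthetic subject the sensor data are always generated with the
subject's TRUE head and electrode positions; the four analysis
configurations (anatomy x electrodes, each template or individual) differ
only in the forward model handed to the inverse solver, exactly the
situation an experimenter faces when deciding which individualization steps
to pay for. Component metrics (P1/N1 amplitude and latency), the ROI power
ratio, and the localization error are computed per hemisphere for dSPM and
sLORETA.

The statistical pipeline mirrors common ERP practice: within-subject
z-scoring, Box-Cox transformation, a fully-within-subject 2x2
repeated-measures ANOVA with Levene and residual-normality checks, and an
aligned-rank-transform ANOVA with Bonferroni-corrected Wilcoxon post-hocs
as the non-parametric fallback (effect sizes reported only for the
parametric branch).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from . import metrics as _metrics
from .inverse import apply_inverse, estimate_noise_covariance, make_inverse_operator
from .preprocess import baseline_correct, preprocess_chain
from .simulate import CohortBundle, SubjectRecord

__all__ = [
    "METRIC_NAMES",
    "run_configuration",
    "run_design",
    "zscore_within_subject",
    "boxcox",
    "rm_anova_2x2",
    "assumption_checks",
    "art_anova_fallback",
    "run_statistics",
    "paired_individualization_test",
]

METRIC_NAMES = (
    "P1_amp",
    "P1_lat",
    "N1_amp",
    "N1_lat",
    "power_ratio_P1",
    "power_ratio_N1",
    "loc_error",
)
LEVELS = ("template", "individual")
RESULT_COLUMNS = [
    "subject",
    "hemisphere",
    "method",
    "anatomy",
    "electrodes",
    "metric",
    "value",
    "missing",
]


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-configuration metric extraction


def run_configuration(
    subject: SubjectRecord,
    anatomy: str,
    electrodes: str,
    method: str,
    evoked: np.ndarray | None = None,
    noisecov=None,
    times: np.ndarray | None = None,
) -> list[dict]:
    """All per-hemisphere metrics for one (anatomy, electrodes, method) cell.

    ``evoked`` (sensors x time trial average of the preprocessed data) and
    ``noisecov`` may be precomputed once per subject — they do not depend on
    the analysis configuration; if omitted they are derived here.
    """
    leadfield = subject.leadfields[(anatomy, electrodes)]
    srcspace = (
        subject.template_sourcespace if anatomy == "template" else subject.sourcespace
    )
    if evoked is None or noisecov is None:
        epochs = subject.make_epochs()
        clean, _ = preprocess_chain(epochs)
        noisecov = estimate_noise_covariance(clean)
        evoked = clean.data.mean(axis=0)
        times = clean.times
    operator = make_inverse_operator(leadfield, noisecov, method)
    stc = apply_inverse(evoked, operator, times=times)
    stc_bc = baseline_correct(stc.values, stc.times, _metrics.BASELINE)

    records = []
    fs = subject.spec.fs
    for h in ("L", "R"):
        pac = srcspace.rois[f"PAC_{h}"]
        ext = srcspace.rois[f"EXT_{h}"]
        roi_ts = _metrics.extract_roi_timeseries(stc, pac)
        post = _metrics.postprocess_timeseries(roi_ts, stc.times, fs)
        p1 = _metrics.find_component_peak(post, stc.times, _metrics.P1_WINDOW, +1, "P1", h)
        n1 = _metrics.find_component_peak(post, stc.times, _metrics.N1_WINDOW, -1, "N1", h)

        values = {
            "P1_amp": (p1.amplitude, p1.missing),
            "P1_lat": (p1.latency, p1.missing),
            "N1_amp": (n1.amplitude, n1.missing),
            "N1_lat": (n1.latency, n1.missing),
        }
        for comp, meas in (("P1", p1), ("N1", n1)):
            if meas.missing:
                values[f"power_ratio_{comp}"] = (np.nan, True)
            else:
                leak = _metrics.roi_power_ratio(
                    stc_bc, pac, ext, meas.latency, times=stc.times, component=comp
                )
                values[f"power_ratio_{comp}"] = (leak.power_ratio, False)
        loc_lat = p1.latency if not p1.missing else subject.spec.template.p1_latency
        hemi_vertices = np.flatnonzero(srcspace.hemisphere == h)
        err = _metrics.localization_error(
            stc,
            srcspace,
            srcspace.metadata["seed_vertices"][h],
            loc_lat,
            candidates=hemi_vertices,
        )
        values["loc_error"] = (err, False)

        for name in METRIC_NAMES:
            val, miss = values[name]
            records.append(
                {
                    "subject": subject.index,
                    "hemisphere": h,
                    "method": method,
                    "anatomy": anatomy,
                    "electrodes": electrodes,
                    "metric": name,
                    "value": val,
                    "missing": miss,
                }
            )
    return records


def run_design(
    cohort: CohortBundle, methods: tuple[str, ...] = ("dSPM", "sLORETA")
) -> pd.DataFrame:
    """Long-format results table over subjects x 2x2 conditions x methods."""
    rows = []
    for subject in cohort.subjects:
        epochs = subject.make_epochs()
        clean, _ = preprocess_chain(epochs)
        del epochs
        noisecov = estimate_noise_covariance(clean)
        evoked = clean.data.mean(axis=0)
        times = clean.times
        del clean
        for anatomy, electrodes, method in itertools.product(LEVELS, LEVELS, methods):
            rows.extend(
                run_configuration(
                    subject, anatomy, electrodes, method, evoked, noisecov, times
                )
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# statistics


def zscore_within_subject(df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Z-score each subject's condition cells (per metric/hemisphere/method).

    A subject with zero within-subject variance gets zeros and a
    ``degenerate`` flag instead of a division by zero.
    """
    out = df.copy()
    out["degenerate"] = False
    group_cols = [c for c in ("metric", "hemisphere", "method", "subject") if c in df.columns]

    def _z(g):
        v = g[value_col].astype(float)
        if v.notna().sum() < 2:
            raise InsufficientDataError("need >= 2 non-missing cells per subject")
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            g[value_col] = 0.0
            g["degenerate"] = True
        else:
            g[value_col] = (v - v.mean()) / sd
        return g

    return out.groupby(group_cols, group_keys=False)[out.columns].apply(_z)


def boxcox(values: np.ndarray, lam_grid: np.ndarray | None = None):
    """Box-Cox transform with grid-search MLE for lambda.

    Non-positive input is shifted by ``1 - min`` (shift returned; already
    strictly positive data are left in place so their shape is preserved);
    constant input is passed through with ``lam = None``.
    """
    x = np.asarray(values, dtype=float)
    if lam_grid is None:
        lam_grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    if np.all(x == x[0]):
        return x.copy(), None, 0.0
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    xs = x + shift
    llf = np.array([stats.boxcox_llf(l, xs) for l in lam_grid])
    lam = float(lam_grid[np.argmax(llf)])
    y = np.log(xs) if lam == 0.0 else (xs**lam - 1.0) / lam
    return y, lam, shift


def _cell_table(df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Complete-cell check + convenience pivot for a single metric slice."""
    need = {"subject", "anatomy", "electrodes", value_col}
    if not need.issubset(df.columns):
        raise ValueError(f"table must have columns {need}")
    return df


def rm_anova_2x2(df: pd.DataFrame, value_col: str = "value") -> dict:
    """Fully-within-subject 2x2 ANOVA (subject as random blocking factor).

    Returns {effect: {'F', 'p', 'np2', 'df1', 'df2'}} for effects
    'anatomy', 'electrodes' and 'interaction'.
    """
    df = _cell_table(df, value_col)
    if df["subject"].nunique() < 3:
        raise InsufficientDataError("need at least 3 subjects")
    aov = pg.rm_anova(
        data=df,
        dv=value_col,
        within=["anatomy", "electrodes"],
        subject="subject",
        detailed=True,
    )
    key = {"anatomy": "anatomy", "electrodes": "electrodes",
           "anatomy * electrodes": "interaction"}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    out = {}
    for _, row in aov.iterrows():
        name = key.get(row["Source"])
        if name is None:
            continue
        f, df1, df2 = float(row["F"]), float(row["ddof1"]), float(row["ddof2"])
        p = float(row[p_col])
        if not np.isfinite(f):  # 0/0: the effect is exactly absent
            f, p = 0.0, 1.0
        out[name] = {
            "F": f,
            "p": p,
            # partial eta^2 from the F statistic (exact for this design)
            "np2": f * df1 / (f * df1 + df2),
            "df1": df1,
            "df2": df2,
        }
    return out


def _effect_decomposition(df: pd.DataFrame, value_col: str = "value"):
    """Balanced means decomposition of the 2x2 within design."""
    grand = df[value_col].mean()
    subj = df.groupby("subject")[value_col].mean() - grand
    a_eff = df.groupby("anatomy")[value_col].mean() - grand
    b_eff = df.groupby("electrodes")[value_col].mean() - grand
    cell = df.groupby(["anatomy", "electrodes"])[value_col].mean()
    inter = cell - grand
    for (a, b) in inter.index:
        inter.loc[(a, b)] -= a_eff.loc[a] + b_eff.loc[b]
    return grand, subj, a_eff, b_eff, inter, cell


def model_residuals(df: pd.DataFrame, value_col: str = "value") -> np.ndarray:
    """Residuals of the additive subject + cell model (balanced design)."""
    grand, subj, a_eff, b_eff, inter, cell = _effect_decomposition(df, value_col)
    fitted = (
        grand
        + subj.reindex(df["subject"]).to_numpy()
        + cell.reindex(pd.MultiIndex.from_frame(df[["anatomy", "electrodes"]])).to_numpy()
        - grand
    )
    return df[value_col].to_numpy() - fitted


def assumption_checks(df: pd.DataFrame, value_col: str = "value", alpha: float = 0.05) -> dict:
    """Levene (centre = median) across the four cells and Shapiro normality
    of the model residuals; booleans route to the non-parametric fallback."""
    groups = [g[value_col].to_numpy() for _, g in df.groupby(["anatomy", "electrodes"])]
    levene_p = float(stats.levene(*groups, center="median").pvalue)
    resid = model_residuals(df, value_col)
    if np.allclose(resid, resid[0]):
        normality_p = 1.0
    else:
        normality_p = float(stats.shapiro(resid).pvalue)
    return {
        "levene_p": levene_p,
        "normality_p": normality_p,
        "homogeneous": levene_p > alpha,
        "normal": normality_p > alpha,
        "passed": (levene_p > alpha) and (normality_p > alpha),
    }


def _safe_wilcoxon(x: np.ndarray, y: np.ndarray | None = None, alternative="two-sided") -> float:
    d = x - y if y is not None else np.asarray(x, dtype=float)
    if np.allclose(d, 0):
        return 1.0  # no signed ranks: no evidence against the null
    return float(stats.wilcoxon(d, alternative=alternative).pvalue)


def art_anova_fallback(df: pd.DataFrame, value_col: str = "value") -> dict:
    """Aligned-rank-transform ANOVA with Wilcoxon post-hocs (Bonferroni).

    Each effect is tested on its own aligned-and-ranked data: the additive
    estimates of all *other* effects (and the subject term) are subtracted,
    the chosen effect's estimate is added back, values are ranked, and the
    rank table is fed to the same 2x2 within-subject ANOVA, keeping only the
    effect of interest. No effect sizes are reported on this branch.
    """
    df = _cell_table(df, value_col).copy()
    grand, subj, a_eff, b_eff, inter, cell = _effect_decomposition(df, value_col)
    resid = model_residuals(df, value_col)
    effect_values = {
        "anatomy": a_eff.reindex(df["anatomy"]).to_numpy(),
        "electrodes": b_eff.reindex(df["electrodes"]).to_numpy(),
        "interaction": inter.reindex(
            pd.MultiIndex.from_frame(df[["anatomy", "electrodes"]])
        ).to_numpy(),
    }
    out = {}
    for effect, est in effect_values.items():
        aligned = resid + est
        ranked = stats.rankdata(aligned)
        tmp = df.copy()
        tmp["_rank"] = ranked
        res = rm_anova_2x2(tmp, value_col="_rank")
        out[effect] = {"F": res[effect]["F"], "p": res[effect]["p"]}

    # post-hoc paired Wilcoxon on the three contrasts, Bonferroni x3
    wide = df.pivot_table(index="subject", columns=["anatomy", "electrodes"],
                          values=value_col)
    a_contrast = wide["individual"].mean(axis=1) - wide["template"].mean(axis=1)
    b_contrast = (
        wide.xs("individual", axis=1, level="electrodes").mean(axis=1)
        - wide.xs("template", axis=1, level="electrodes").mean(axis=1)
    )
    i_contrast = (
        wide[("individual", "individual")]
        - wide[("individual", "template")]
        - wide[("template", "individual")]
        + wide[("template", "template")]
    )
    posthoc = {
        "anatomy": _safe_wilcoxon(a_contrast.to_numpy()),
        "electrodes": _safe_wilcoxon(b_contrast.to_numpy()),
        "interaction": _safe_wilcoxon(i_contrast.to_numpy()),
    }
    out["wilcoxon_posthoc"] = {k: min(1.0, 3.0 * p) for k, p in posthoc.items()}
    return out


def run_statistics(
    table: pd.DataFrame,
    alpha: float = 0.05,
    use_boxcox: bool = True,
    methods: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Full statistical pipeline over every (metric, hemisphere, method).

    Subjects with any missing cell for a metric are excluded listwise for
    that metric (logged, never silent). Returns the effect table and the
    exclusion log.
    """
    rows, exclusions = [], []
    slices = table.groupby(["metric", "hemisphere", "method"])
    for (metric, hemi, method), g in slices:
        if methods is not None and method not in methods:
            continue
        missing_subj = g.loc[g["missing"] | g["value"].isna(), "subject"].unique()
        for s in missing_subj:
            exclusions.append(
                {"metric": metric, "hemisphere": hemi, "method": method,
                 "subject": int(s), "reason": "missing cell"}
            )
        g = g[~g["subject"].isin(missing_subj)].copy()
        n_subj = g["subject"].nunique()
        if n_subj < 3:
            exclusions.append(
                {"metric": metric, "hemisphere": hemi, "method": method,
                 "subject": -1, "reason": f"only {n_subj} complete subjects"}
            )
            continue
        z = zscore_within_subject(g)
        if use_boxcox and not z["degenerate"].all():
            z["value"], lam, _ = boxcox(z["value"].to_numpy())
        else:
            lam = None
        checks = assumption_checks(z)
        if checks["passed"]:
            res = rm_anova_2x2(z)
            branch = "parametric"
            posthoc = {}
        else:
            res = art_anova_fallback(z)
            branch = "aligned-rank"
            posthoc = res.pop("wilcoxon_posthoc")
        for effect in ("anatomy", "electrodes", "interaction"):
            rows.append(
                {
                    "metric": metric,
                    "hemisphere": hemi,
                    "method": method,
                    "effect": effect,
                    "branch": branch,
                    "F": res[effect]["F"],
                    "p": res[effect]["p"],
                    # effect sizes only on the parametric branch
                    "np2": res[effect].get("np2", np.nan) if branch == "parametric" else np.nan,
                    "significant": res[effect]["p"] < alpha,
                    "n_subjects": n_subj,
                    "boxcox_lambda": lam,
                    "levene_p": checks["levene_p"],
                    "normality_p": checks["normality_p"],
                    "posthoc_p": posthoc.get(effect, np.nan),
                }
            )
    return pd.DataFrame(rows), exclusions


def paired_individualization_test(
    table: pd.DataFrame,
    metric: str,
    method: str,
    better: str = "lower",
) -> dict:
    """Directional paired test: fully-individual vs fully-template cells.

    Per subject the metric is averaged over hemispheres; the one-sided
    Wilcoxon signed-rank test asks whether full individualization improves
    the metric (``better`` = 'lower' or 'higher').
    """
    sel = table[(table["metric"] == metric) & (table["method"] == method)]
    wide = sel.pivot_table(index="subject", columns=["anatomy", "electrodes"],
                           values="value", aggfunc="mean")
    ind = wide[("individual", "individual")]
    tmp = wide[("template", "template")]
    ok = ind.notna() & tmp.notna()
    diff = (ind[ok] - tmp[ok]).to_numpy()
    alternative = "less" if better == "lower" else "greater"
    p = _safe_wilcoxon(ind[ok].to_numpy(), tmp[ok].to_numpy(), alternative=alternative)
    return {
        "n": int(ok.sum()),
        "mean_individual": float(ind[ok].mean()),
        "mean_template": float(tmp[ok].mean()),
        "mean_difference": float(diff.mean()),
        "p": p,
    }
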