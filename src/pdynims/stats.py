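"""Differential statistics for ROI peak areas and behavior.

Per m/z bin, the tested quantity is the within-animal side ratio
log2(lesioned-SN mean / intact-SN mean) — this matches percent-of-intact
reporting and removes animal-level intensity scaling — modeled by ordinary
least squares on treatment group (dummy coded, lesion-only controls as
reference) plus analysis run as a batch covariate, with Benjamini-Hochberg
step-up control of the false discovery rate across bins. Group comparisons
use one-way ANOVA with Tukey HSD; dyskinesia time courses use a two-way
mixed (between-group x within-session) ANOVA with per-session Bonferroni
post hoc tests; peak-behavior relationships use Pearson correlation with
the least-squares line reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinTestResult",
    "CorrelationResult",
    "build_design",
    "fit_linear_model",
    "fit_all_bins",
    "adjust_bh",
    "correlate_with_behavior",
    "anova_tukey",
    "repeated_measures_anova",
]


@dataclass(frozen=True)
class BinTestResult:
    """Treatment-contrast test for one m/z bin."""

    bin_mz: float
    effect: float  # log2 scale
    se: float
    t: float
    p: float
    df: int
    p_adj: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def build_design(
    summaries: pd.DataFrame,
    animals: pd.DataFrame,
    region: str | None = None,
    average_runs: bool = False,
) -> pd.DataFrame:
    """Assemble the per-bin design table of log2 side ratios.

    Parameters
    ----------
    summaries : DataFrame
        Stacked :func:`pdynims.roi.summarize_roi` output across sections,
        with additional ``animal_id`` and ``run_id`` columns.
    animals : DataFrame
        Columns ``animal_id, group`` (group in {LC, LD, HD}).
    region : str, optional
        Restrict to one region (e.g. ``"SN_lateral"``); default keeps all.
    average_runs : bool
        Average duplicate runs within animal before modeling (drops the run
        covariate downstream).

    Returns
    -------
    DataFrame with columns ``animal_id, group, run_id, region, bin_mz,
    log2_ratio``. Observations with a non-positive side mean are dropped
    (log2 undefined).
    """
    wide = summaries.pivot_table(
        index=["animal_id", "run_id", "region", "bin_mz"],
        columns="hemisphere",
        values="mean_area",
    ).reset_index()
    if "lesioned" not in wide.columns or "intact" not in wide.columns:
        raise ValueError("summaries must contain both hemispheres")
    ok = (wide["lesioned"] > 0) & (wide["intact"] > 0)
    wide = wide[ok].copy()
    wide["log2_ratio"] = np.log2(wide["lesioned"] / wide["intact"])
    design = wide.merge(animals[["animal_id", "group"]], on="animal_id", how="left")
    if design["group"].isna().any():
        missing = design.loc[design["group"].isna(), "animal_id"].unique()
        raise ValueError(f"animals without group label: {list(missing)}")
    if region is not None:
        design = design[design["region"] == region].copy()
    if average_runs:
        design = (
            design.groupby(["animal_id", "group", "region", "bin_mz"], as_index=False)[
                "log2_ratio"
            ]
            .mean()
            .assign(run_id=0)
        )
    return design[["animal_id", "group", "run_id", "region", "bin_mz", "log2_ratio"]]


def _design_matrix(design: pd.DataFrame, reference: str) -> tuple[np.ndarray, list[str]]:
    groups = [g for g in ("LC", "LD", "HD") if g in set(design["group"])]
    if reference not in groups:
        reference = groups[0]
    cols: list[np.ndarray] = [np.ones(len(design))]
    names = ["intercept"]
    for g in groups:
        if g == reference:
            continue
        cols.append((design["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    runs = sorted(set(design["run_id"]))
    for r in runs[1:]:
        cols.append((design["run_id"] == r).to_numpy(float))
        names.append(f"run[{r}]")
    return np.column_stack(cols), names


def fit_linear_model(
    design: pd.DataFrame,
    bin_mz: float | None = None,
    contrast: str = "HD",
    reference: str = "LC",
    value_col: str = "log2_ratio",
) -> BinTestResult:
    """OLS of log2 side ratio on treatment group + analysis run.

    Returns the t-test on the ``contrast`` vs ``reference`` group
    coefficient. With a two-group design and a single run this reduces
    exactly to the two-sample pooled t-test.
    """
    sub = design if bin_mz is None else design[np.isclose(design["bin_mz"], bin_mz)]
    if sub.empty:
        raise ValueError(f"no observations for bin {bin_mz}")
    if sub["group"].nunique() < 2:
        raise ValueError("at least 2 treatment groups required")
    X, names = _design_matrix(sub, reference)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _confounded_columns(X, names)
        raise ValueError(f"rank-deficient design; confounded columns: {bad}")
    import statsmodels.api as sm

    y = sub[value_col].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    try:
        k = names.index(f"group[{contrast}]")
    except ValueError:
        raise ValueError(f"contrast group {contrast!r} absent from design") from None
    effect = float(fit.params[k])
    se = float(fit.bse[k])
    dfres = int(fit.df_resid)
    y_scale = float(np.sum(y**2)) + 1.0
    degenerate = (se == 0) or not np.isfinite(se) or fit.ssr <= 1e-24 * y_scale
    if degenerate:
        # zero residual variance: degenerate but well-defined verdicts
        if abs(effect) <= 1e-12 * np.sqrt(y_scale):
            effect, t, p = 0.0, 0.0, 1.0
        else:
            t, p = np.inf * np.sign(effect), 0.0
    else:
        t = float(fit.tvalues[k])
        p = float(fit.pvalues[k])
    b = float(sub["bin_mz"].iloc[0]) if bin_mz is None else float(bin_mz)
    return BinTestResult(bin_mz=b, effect=effect, se=se, t=t, p=p, df=dfres)


def _confounded_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            bad.append(names[j])
        else:
            keep.append(j)
    return bad


def fit_all_bins(
    design: pd.DataFrame, contrast: str = "HD", reference: str = "LC"
) -> pd.DataFrame:
    """Per-bin OLS contrasts with BH-adjusted p-values.

    Returns a DataFrame sorted by bin m/z with columns ``bin_mz, effect,
    se, t, p, p_adj``.
    """
    rows = []
    for b in sorted(design["bin_mz"].unique()):
        res = fit_linear_model(design, b, contrast=contrast, reference=reference)
        rows.append(
            {"bin_mz": res.bin_mz, "effect": res.effect, "se": res.se, "t": res.t, "p": res.p}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_with_behavior(roi_values, scores) -> CorrelationResult:
    """Pearson correlation of ROI peak areas with cumulative AIM scores.

    Returns the correlation coefficient with its two-sided t-based p-value,
    together with the least-squares regression slope and intercept (the
    line is reported for its representative value; the correlation
    ascertains the nature of the relationship).
    """
    x = np.asarray(roi_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input vector")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    return CorrelationResult(r=float(r), p=float(p), slope=float(reg.slope),
                             intercept=float(reg.intercept), n=int(x.size))


def anova_tukey(groups: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    Returns ``(F, omnibus_p, pairwise)`` where ``pairwise`` has columns
    ``group1, group2, p_adj``. Identical groups (zero variance everywhere)
    yield F = 0, p = 1.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    allvals = np.concatenate(samples)
    if np.ptp(allvals) == 0:
        pairs = [
            {"group1": names[i], "group2": names[j], "p_adj": 1.0}
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return 0.0, 1.0, pd.DataFrame(pairs)
    F, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append(
                {"group1": names[i], "group2": names[j], "p_adj": float(hsd.pvalue[i, j])}
            )
    return float(F), float(p), pd.DataFrame(pairs)


def _f_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float]:
    if df_err <= 0:
        raise ValueError("no error degrees of freedom")
    ms_err = ss_err / df_err
    ms_eff = ss_eff / df_eff
    if ms_err <= 1e-300:
        if ms_eff <= 1e-300:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms_eff / ms_err
    return float(F), float(sps.f.sf(F, df_eff, df_err))


def repeated_measures_anova(
    scores: np.ndarray, group_labels, bonferroni: bool = True
) -> dict:
    """Two-way mixed ANOVA: between = group, within = session.

    ``scores`` is an (animals x sessions) matrix with no missing cells
    (imputation is out of scope). Classical sums-of-squares decomposition:
    subjects-within-groups is the error stratum for the group effect;
    session x subject-within-group is the error stratum for the session and
    interaction effects. Per-session pairwise two-sample t-tests follow,
    Bonferroni-corrected by the number of sessions.

    Returns a dict with ``F_group, p_group, F_time, p_time, F_interaction,
    p_interaction, posthoc`` (DataFrame: session, group1, group2, p, p_adj).
    """
    Y = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    if Y.ndim != 2:
        raise ValueError("scores must be an (animals x sessions) matrix")
    if np.any(~np.isfinite(Y)):
        raise ValueError("missing cells are not allowed")
    if labels.size != Y.shape[0]:
        raise ValueError("one group label per animal required")
    n_subj, n_sess = Y.shape
    names = sorted(set(labels.tolist()))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    sess_means = Y.mean(axis=0)
    group_idx = {g: np.where(labels == g)[0] for g in names}
    ng = {g: idx.size for g, idx in group_idx.items()}
    group_means = {g: Y[idx].mean() for g, idx in group_idx.items()}
    cell_means = {g: Y[idx].mean(axis=0) for g, idx in group_idx.items()}

    ss_between_subj = n_sess * np.sum((subj_means - grand) ** 2)
    ss_group = n_sess * sum(ng[g] * (group_means[g] - grand) ** 2 for g in names)
    ss_subj_wg = ss_between_subj - ss_group
    ss_within = np.sum((Y - subj_means[:, None]) ** 2)
    ss_time = n_subj * np.sum((sess_means - grand) ** 2)
    ss_inter = sum(
        ng[g] * np.sum((cell_means[g] - group_means[g] - sess_means + grand) ** 2)
        for g in names
    )
    ss_err_within = ss_within - ss_time - ss_inter

    a = len(names)
    df_group, df_subj_wg = a - 1, n_subj - a
    df_time = n_sess - 1
    df_inter = df_group * df_time
    df_err_within = df_subj_wg * df_time

    F_g, p_g = _f_p(ss_group, df_group, max(ss_subj_wg, 0.0), df_subj_wg)
    F_t, p_t = _f_p(ss_time, df_time, max(ss_err_within, 0.0), df_err_within)
    F_i, p_i = _f_p(max(ss_inter, 0.0), df_inter, max(ss_err_within, 0.0), df_err_within)

    rows = []
    factor = n_sess if bonferroni else 1
    for s in range(n_sess):
        for i in range(a):
            for j in range(i + 1, a):
                g1, g2 = names[i], names[j]
                x1, x2 = Y[group_idx[g1], s], Y[group_idx[g2], s]
                if np.ptp(np.concatenate([x1, x2])) == 0:
                    p = 1.0
                else:
                    p = float(sps.ttest_ind(x1, x2).pvalue)
                rows.append(
                    {"session": s + 1, "group1": g1, "group2": g2,
                     "p": p, "p_adj": min(p * factor, 1.0)}
                )
    return {
        "F_group": F_g,
        "p_group": p_g,
        "F_time": F_t,
        "p_time": p_t,
        "F_interaction": F_i,
        "p_interaction": p_i,
        "posthoc": pd.DataFrame(rows),
    }
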