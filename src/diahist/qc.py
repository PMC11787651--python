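"""Peptide ratios, replicate CV statistics and identification summaries.

A "region" is one peptide backbone (protein + span); the peptide ratio of a
form is its chromatographic area divided by the summed areas of all searched
forms of that region, after isomer splitting — so ratios within a region sum
to one in every replicate.  Replicate reproducibility is summarized by the
coefficient of variation (CV%) of retention time, peak area and peptide
ratio per form, with counts of forms below 5%/20% thresholds, mirroring how
DIA histone platforms are benchmarked.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "peptide_ratio",
    "cv_percent",
    "summarize_replicates",
    "plot_points_histogram",
    "plot_cv_counts",
]

REGION_KEYS = ["protein", "span_start", "span_end"]


def peptide_ratio(quant: pd.DataFrame, observed_only: bool = False) -> pd.DataFrame:
    """Append per-region ratios to a single-replicate quant table.

    ratio_i = area_i / sum_j area_j over all forms of the region, charge
    states combined.  By default the denominator runs over all searched
    forms (undetected contribute zero); ``observed_only`` restricts it to
    detected forms.  All-zero regions get NaN ratios and an ``all_zero``
    flag.
    """
    df = quant.copy()
    if df.empty:
        df["ratio"] = pd.Series(dtype=float)
        return df
    contrib = df["area"].where(df["detected"] | ~observed_only, 0.0)
    denom = contrib.groupby([df[k] for k in REGION_KEYS]).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = np.where(denom > 0, df["area"] / denom, np.nan)
    if "flags" in df.columns:
        zero = ~(denom > 0)
        df.loc[zero, "flags"] = (
            df.loc[zero, "flags"].fillna("").str.rstrip(";") + ";all_zero"
        ).str.lstrip(";")
    return df


def cv_percent(values: Sequence[float]) -> float:
    """100 x sample standard deviation (n-1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def _identified_mask(df: pd.DataFrame, min_points: int, include_low_confidence: bool) -> pd.Series:
    mask = df["detected"] & (df["points"] >= min_points)
    if not include_low_confidence and "low_confidence" in df.columns:
        mask &= ~df["low_confidence"].astype(bool)
    return mask


def summarize_replicates(
    tables: Sequence[pd.DataFrame],
    cv_thresholds: tuple[float, ...] = (5.0, 20.0),
    min_points: int = 6,
    include_low_confidence: bool = False,
) -> dict:
    """Replicate-level QC: identification counts and per-metric CV coverage.

    A form counts as identified in a replicate when its MS1 peak was found
    with at least ``min_points`` samples across the peak (and, by default,
    its isomer split was not low-confidence).  CVs of retention time, area
    and ratio are computed complete-case, i.e. only for forms identified in
    every replicate.  Returns ``per_form`` (long CV table), ``id_counts``
    (per replicate, with and without low-confidence groups) and
    ``cv_counts`` (forms below each threshold per metric).
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicates")
    frames = []
    for i, t in enumerate(tables):
        t = t.copy()
        t["replicate"] = i
        t["identified"] = _identified_mask(t, min_points, include_low_confidence)
        t["identified_incl_lowconf"] = _identified_mask(t, min_points, True)
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)

    id_counts = (
        long.groupby("replicate")[["identified", "identified_incl_lowconf"]]
        .sum()
        .astype(int)
        .rename(
            columns={
                "identified": "n_identified",
                "identified_incl_lowconf": "n_identified_incl_low_confidence",
            }
        )
        .reset_index()
    )

    n_reps = len(tables)
    complete = (
        long[long["identified"]]
        .groupby("label")["replicate"]
        .nunique()
        .pipe(lambda s: set(s[s == n_reps].index))
    )
    rows = []
    for label, sub in long[long["label"].isin(complete)].groupby("label"):
        row = {"label": label}
        for metric, col in (("rt", "apex_rt"), ("area", "area"), ("ratio", "ratio")):
            vals = sub[col].to_numpy(dtype=float)
            try:
                row[f"cv_{metric}"] = cv_percent(vals)
            except ValueError:
                row[f"cv_{metric}"] = np.nan
        row["mean_points"] = float(sub["points"].mean())
        rows.append(row)
    per_form = pd.DataFrame(rows)

    cv_rows = []
    for metric in ("rt", "area", "ratio"):
        col = f"cv_{metric}"
        for thr in sorted(cv_thresholds):
            n_below = (
                int((per_form[col] < thr).sum()) if not per_form.empty else 0
            )
            cv_rows.append(
                {"metric": metric, "cv_threshold_pct": thr, "n_forms_below": n_below}
            )
    cv_counts = pd.DataFrame(cv_rows)
    return {
        "per_form": per_form,
        "id_counts": id_counts,
        "cv_counts": cv_counts,
        "n_complete_case": len(complete),
    }


def plot_points_histogram(quant: pd.DataFrame, ax=None):
    """Histogram of points across the peak for detected forms."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    pts = quant.loc[quant["detected"], "points"]
    ax.hist(pts, bins=np.arange(0.5, max(pts.max(), 12) + 1.5), color="#4878CF")
    ax.set_xlabel("points across peak")
    ax.set_ylabel("forms")
    return ax


def plot_cv_counts(summary: dict, ax=None):
    """Grouped bars of forms below each CV threshold per metric."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cv = summary["cv_counts"]
    metrics = cv["metric"].unique()
    thresholds = sorted(cv["cv_threshold_pct"].unique())
    width = 0.8 / len(thresholds)
    for i, thr in enumerate(thresholds):
        sub = cv[cv["cv_threshold_pct"] == thr].set_index("metric").loc[metrics]
        ax.bar(
            np.arange(len(metrics)) + i * width,
            sub["n_forms_below"],
            width=width,
            label=f"CV < {thr:g}%",
        )
    ax.set_xticks(np.arange(len(metrics)) + 0.4 - width / 2)
    ax.set_xticklabels(metrics)
    ax.set_ylabel("forms")
    ax.legend()
    return ax
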