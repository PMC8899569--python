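"""Thallium-influx (FluxOR) fluorescence trace quantification.

Traces record fluorescence F(t) of an outer-hair-cell region of interest
after thallium addition at t = 0; recording runs to 120 s.  Per trace the
summary is F0 (fluorescence at stimulus time), the normalized change
dF(0-120)/F0 = (F(120) - F(0)) / F(0), and the influx slope from an ordinary
least-squares fit of F against t over the [0, 120] s window.  Channel
inhibitors (quinine on MET, XE991 on Kv7.4) flatten traces, so their groups
summarize to slopes and ratios near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FluxTrace:
    """One ROI's fluorescence time series (t = 0 at Tl+ addition)."""

    roi_id: str
    group: str
    t: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)
        if t.ndim != 1 or t.shape != f.shape or t.size < 2:
            raise ValueError("t and f must be matching 1-D arrays, length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence values must be finite")


@dataclass(frozen=True)
class FluxSummary:
    roi_id: str
    group: str
    f0: float
    delta_f_ratio: float | None
    slope: float
    slope_se: float
    ratio_defined: bool


def extract_traces(stack: np.ndarray,
                   roi_masks: Mapping[str, np.ndarray],
                   frame_interval_s: float = 1.0,
                   groups: Mapping[str, str] | None = None,
                   t_start_s: float = 0.0) -> list[FluxTrace]:
    """Mean-pixel traces per ROI from a single-channel image time series.

    ``stack`` has shape (frames, height, width); each mask is a boolean array
    of the frame shape.  Timestamps are ``t_start_s + k * frame_interval_s``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a (frames, height, width) array")
    t = t_start_s + np.arange(stack.shape[0]) * float(frame_interval_s)
    traces = []
    for roi_id, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape[1:]:
            raise ValueError(f"ROI {roi_id}: mask shape {mask.shape} does not "
                             f"match frame shape {stack.shape[1:]}")
        if not mask.any():
            raise ValueError(f"ROI {roi_id}: empty mask")
        f = stack[:, mask].mean(axis=1)
        group = groups.get(roi_id, "") if groups else ""
        traces.append(FluxTrace(roi_id=roi_id, group=group, t=t, f=f))
    return traces


def summarize_trace(tr: FluxTrace, t_end: float = 120.0,
                    baseline_frames: int = 1) -> FluxSummary:
    """F0, dF(0-t_end)/F0 and OLS influx slope for one trace.

    F0 is the sample nearest t = 0 by default; ``baseline_frames > 1``
    averages that many frames at/before the stimulus instead (for noisy
    recordings).  The slope is fit on samples with 0 <= t <= t_end.
    A nonpositive F0 leaves the ratio undefined (flagged), never infinite.
    """
    if tr.t[0] > 0 or tr.t[-1] < t_end:
        raise ValueError(f"trace must cover [0, {t_end}] s "
                         f"(covers [{tr.t[0]}, {tr.t[-1]}])")
    i0 = int(np.argmin(np.abs(tr.t)))
    if baseline_frames > 1:
        pre = np.flatnonzero(tr.t <= tr.t[i0])[-baseline_frames:]
        f0 = float(tr.f[pre].mean())
    else:
        f0 = float(tr.f[i0])
    i_end = int(np.argmin(np.abs(tr.t - t_end)))
    window = (tr.t >= tr.t[i0]) & (tr.t <= tr.t[i_end])
    fit = stats.linregress(tr.t[window], tr.f[window])
    ratio_defined = f0 > 0
    ratio = (float(tr.f[i_end]) - f0) / f0 if ratio_defined else None
    return FluxSummary(roi_id=tr.roi_id, group=tr.group, f0=f0,
                       delta_f_ratio=ratio, slope=float(fit.slope),
                       slope_se=float(fit.stderr), ratio_defined=ratio_defined)


def summaries_frame(summaries: Sequence[FluxSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "roi_id": s.roi_id, "group": s.group, "f0": s.f0,
        "delta_f_ratio": s.delta_f_ratio, "slope": s.slope,
        "slope_se": s.slope_se, "ratio_defined": s.ratio_defined,
    } for s in summaries])


def compare_groups(summaries: Sequence[FluxSummary]
                   ) -> tuple[pd.DataFrame, dict]:
    """Per-group mean +/- sd of ratio and slope, plus standard tests.

    Groups are ordered alphabetically (deterministic); empty groups are
    dropped with a warning.  Pairwise Welch t-tests on the ratio and a
    one-way ANOVA across groups are convenience output.
    """
    df = summaries_frame(summaries)
    counts = df.groupby("group").size()
    empty = [g for g in counts.index if counts[g] == 0]
    for g in empty:
        warnings.warn(f"group {g!r} has no traces; excluded")
    df = df[~df["group"].isin(empty)]
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 nonempty groups to compare")
    agg = (df.groupby("group", sort=True)
             .agg(n=("roi_id", "size"),
                  mean_ratio=("delta_f_ratio", "mean"),
                  sd_ratio=("delta_f_ratio", "std"),
                  mean_slope=("slope", "mean"),
                  sd_slope=("slope", "std"))
             .reset_index())
    groups = list(agg["group"])
    ratios = {g: df.loc[df["group"] == g, "delta_f_ratio"].dropna().to_numpy()
              for g in groups}
    tests: dict = {"pairwise_ttests": {}, "anova_p": None}
    for a, b in combinations(groups, 2):
        if len(ratios[a]) > 1 and len(ratios[b]) > 1:
            t = stats.ttest_ind(ratios[a], ratios[b], equal_var=False)
            tests["pairwise_ttests"][f"{a} vs {b}"] = {
                "t": float(t.statistic), "p": float(t.pvalue)}
    if all(len(v) > 1 for v in ratios.values()):
        tests["anova_p"] = float(stats.f_oneway(*ratios.values()).pvalue)
    return agg, tests
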