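"""Before/after drug comparison and cohort summaries.

Drug-response recordings consist of 30 frames before and ~50 frames
after inhibitor addition in the same cells; tracks are split at the
boundary frame (tracks spanning it are truncated, each part kept only
if it still meets the minimum track length) and per-cell means of solo
track metrics are compared across cells with the Wilcoxon
matched-pairs signed-rank test.  Significance labels follow the
printed convention: p <= 0.001 '***', p <= 0.01 '**', p <= 0.05 '*',
otherwise 'ns'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .kinematics import persistence, summarize_track
from .msd import axis_msd, fit_alpha, msd
from .tracking import LinkingParams, Track, TrackGraph

EXACT_MAX_N = 25


@dataclass
class WilcoxonResult:
    statistic: float     # W+ = sum of positive ranks (NaN if all zero)
    p_value: float
    n_nonzero: int
    method: str          # "exact" or "approx"


@dataclass
class PairedComparison:
    """Paired before/after comparison of one metric across cells."""

    metric: str
    n: int
    before_mean: float
    before_sd: float
    after_mean: float
    after_sd: float
    statistic: float
    p_value: float
    label: str
    before_values: list[float] = field(default_factory=list)
    after_values: list[float] = field(default_factory=list)


def split_before_after(graph: TrackGraph, boundary_frame: int,
                       params: LinkingParams | None = None
                       ) -> tuple[list[Track], list[Track]]:
    """Split tracks into before/after sets at the boundary frame.

    Tracks fully before the boundary go to "before", fully at or after
    it to "after"; spanning tracks are truncated at the boundary and
    each part is kept only if it still has at least ``min_track_len``
    spots.  Class labels (solo/main/sub) carry over to the parts.
    """
    params = params or LinkingParams()
    before: list[Track] = []
    after: list[Track] = []
    for t in graph.tracks:
        if t.end_frame < boundary_frame:
            before.append(t)
        elif t.start_frame >= boundary_frame:
            after.append(t)
        else:
            pre = [s for s in t.spots if s.frame < boundary_frame]
            post = [s for s in t.spots if s.frame >= boundary_frame]
            for part, dest in ((pre, before), (post, after)):
                if len(part) >= params.min_track_len:
                    dest.append(Track(track_id=t.track_id, spots=part,
                                      group_id=t.group_id, cls=t.cls))
    return before, after


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Differences are ``x - y`` (or ``x`` directly if ``y`` is None);
    zero differences are dropped.  For up to 25 nonzero pairs the
    exact null distribution of W+ (sum of positive ranks, average
    ranks for ties) is enumerated by dynamic programming; beyond that
    a normal approximation with tie correction is used.  If every
    difference is zero the statistic is NaN and p = 1.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.size == 0:
        raise ValueError("wilcoxon_signed_rank needs at least one pair")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(float("nan"), 1.0, 0, "exact")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")
    mu = n * (n + 1) / 4.0
    tie_sum = 0.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_sum / 48.0
    z = (w_plus - mu) / math.sqrt(var)
    p = float(min(2.0 * norm.sf(abs(z)), 1.0))
    return WilcoxonResult(w_plus, p, n, "approx")


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, via DP on the
    doubled (hence integer) rank sums."""
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[:-r]
    n_patterns = counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def significance_label(p: float) -> str:
    """Printed significance convention with inclusive thresholds."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_paired(metric: str, before, after) -> PairedComparison:
    """Paired comparison of one metric across cells (one value per cell
    and condition)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must be paired (equal length)")
    res = wilcoxon_signed_rank(before, after)
    return PairedComparison(
        metric=metric,
        n=int(before.size),
        before_mean=float(before.mean()),
        before_sd=float(before.std(ddof=1)) if before.size > 1 else 0.0,
        after_mean=float(after.mean()),
        after_sd=float(after.std(ddof=1)) if after.size > 1 else 0.0,
        statistic=res.statistic,
        p_value=res.p_value,
        label=significance_label(res.p_value),
        before_values=before.tolist(),
        after_values=after.tolist(),
    )


def cohort_summary(per_cell_values: dict[str, list[float]]) -> pd.DataFrame:
    """Mean ± SD and whisker-box quantiles per metric across cells."""
    rows = []
    for metric, vals in per_cell_values.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError("cohort_summary needs at least 2 cells")
        rows.append({
            "metric": metric,
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "min": float(v.min()),
            "q1": float(np.quantile(v, 0.25)),
            "median": float(np.median(v)),
            "q3": float(np.quantile(v, 0.75)),
            "max": float(v.max()),
        })
    return pd.DataFrame(rows)


def solo_track_metrics(tracks, frame_interval_s: float = 20.0) -> dict[str, float]:
    """Per-cell means over solo tracks of the four drug-response
    metrics: overall track speed, persistence, MSD alpha, and the
    perpendicular-axis alpha (accepted fits only for the alphas)."""
    solos = [t for t in tracks if getattr(t, "cls", "solo") == "solo"]
    speeds, persists, alphas, alpha_perp = [], [], [], []
    for t in solos:
        if len(t) < 2:
            continue
        s = summarize_track(t, frame_interval_s)
        if np.isfinite(s.overall_track_speed):
            speeds.append(s.overall_track_speed)
        p = persistence(t)
        if np.isfinite(p):
            persists.append(p)
        if len(t) >= 10:
            fit = fit_alpha(msd(t, frame_interval_s))
            if fit.accepted:
                alphas.append(fit.alpha)
            try:
                _, fit_y = axis_msd(t, frame_interval_s)
            except ValueError:
                pass
            else:
                if fit_y.accepted:
                    alpha_perp.append(fit_y.alpha)
    def _m(v):
        return float(np.mean(v)) if v else float("nan")
    return {
        "overall_track_speed_um_per_min": _m(speeds),
        "persistence": _m(persists),
        "alpha": _m(alphas),
        "alpha_perpendicular": _m(alpha_perp),
    }


def drug_experiment(graphs: list[TrackGraph], boundary_frame: int = 30,
                    frame_interval_s: float = 20.0,
                    params: LinkingParams | None = None
                    ) -> list[PairedComparison]:
    """Full before/after analysis over a cohort of cells.

    ``graphs`` holds one classified track graph per cell.  Returns one
    paired comparison per metric, pairing per-cell means of solo-track
    values before and after the boundary frame.
    """
    per_metric_before: dict[str, list[float]] = {}
    per_metric_after: dict[str, list[float]] = {}
    for g in graphs:
        before, after = split_before_after(g, boundary_frame, params)
        mb = solo_track_metrics(before, frame_interval_s)
        ma = solo_track_metrics(after, frame_interval_s)
        for k in mb:
            if np.isfinite(mb[k]) and np.isfinite(ma[k]):
                per_metric_before.setdefault(k, []).append(mb[k])
                per_metric_after.setdefault(k, []).append(ma[k])
    return [compare_paired(k, per_metric_before[k], per_metric_after[k])
            for k in per_metric_before]
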