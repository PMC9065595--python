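"""White-matter-tract ROI statistics for vein strain / strain-rate.

Vein beam elements are assigned to tracts of a (JHU-style) atlas by the
voxel containing their midpoint, the atlas having been expanded by one
modal-label dilation to catch elements just outside the nominal tract
extent.  Tracts containing at least one microbleed-mask voxel form the
"with microbleed" group.  Groups are compared with the Mann-Whitney U
test; individual tracts with a tie-corrected Kruskal-Wallis test
followed by Dunn's pairwise z tests under Bonferroni correction.
Elements (not voxels) are the statistical unit; tracts with fewer than
40 elements are flagged and can be excluded in a sensitivity re-run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .image import LabelImage

__all__ = [
    "LOW_COUNT_THRESHOLD",
    "GroupComparison",
    "TractReport",
    "prepare_atlas",
    "tract_values",
    "group_compare",
    "tract_compare",
    "modal_dilate_labels",
    "summary_stats",
]

#: Tracts with fewer elements than this are flagged as low-count.
LOW_COUNT_THRESHOLD = 40


def modal_dilate_labels(voxels: np.ndarray, n: int = 1) -> np.ndarray:
    """Modal label dilation: background voxels take the most frequent
    neighbouring label in the 3x3x3 footprint; existing labels are never
    overwritten; ties resolve to the lowest id.
    """
    out = voxels.copy()
    fp = np.ones((3, 3, 3))
    for _ in range(n):
        ids = np.unique(out)
        ids = ids[ids != 0]
        if ids.size == 0:
            break
        counts = np.stack(
            [ndimage.correlate((out == lid).astype(np.int32), fp.astype(np.int32),
                               mode="constant", cval=0) for lid in ids]
        )
        best = np.argmax(counts, axis=0)  # first (lowest id) wins ties
        best_count = np.take_along_axis(counts, best[None], axis=0)[0]
        fill = (out == 0) & (best_count > 0)
        out[fill] = ids[best[fill]]
    return out


def prepare_atlas(
    atlas: LabelImage,
    microbleed_mask: np.ndarray,
    n_dilations: int = 1,
) -> tuple[LabelImage, dict[int, bool]]:
    """Dilate the tract atlas and classify tracts by microbleed presence.

    Returns the dilated atlas and a map tract id -> True when at least
    one microbleed voxel lies inside the (dilated) tract extent.
    """
    mb = np.asarray(microbleed_mask) > 0
    if mb.shape != atlas.shape:
        raise ValueError("microbleed mask and atlas geometry differ")
    dilated = modal_dilate_labels(atlas.voxels, n=n_dilations)
    out = LabelImage(dilated, atlas.affine.copy(), dict(atlas.label_table))
    groups: dict[int, bool] = {}
    hit_any = False
    for lid in np.unique(dilated):
        if lid == 0:
            continue
        has = bool(np.any(mb & (dilated == lid)))
        groups[int(lid)] = has
        hit_any |= has
    if mb.any() and not hit_any:
        warnings.warn("microbleed mask lies outside all tracts: "
                      "every tract classed 'without microbleed'", stacklevel=2)
    return out, groups


def tract_values(
    element_values: np.ndarray,
    element_world_mm: np.ndarray,
    atlas: LabelImage,
) -> tuple[dict[int, np.ndarray], int]:
    """Assign element peak values to the tract at each element's voxel.

    ``element_world_mm`` are the element midpoint coordinates (mm).
    Elements whose voxel carries the background label (or falls outside
    the grid) appear in no tract list; their number is returned as the
    unassigned tally.  Values should be the raw (unfiltered, unsmoothed)
    per-element peaks.
    """
    vals = np.asarray(element_values, dtype=float)
    xyz = np.atleast_2d(np.asarray(element_world_mm, dtype=float))
    if vals.shape[0] != xyz.shape[0]:
        raise ValueError("value/coordinate length mismatch")
    vox = atlas.voxel_from_world(xyz)
    idx = np.floor(np.atleast_2d(vox)).astype(int)
    shape = np.asarray(atlas.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    labels = np.zeros(vals.shape[0], dtype=np.int64)
    labels[inside] = atlas.voxels[tuple(idx[inside].T)]
    out: dict[int, np.ndarray] = {}
    for lid in np.unique(labels):
        if lid == 0:
            continue
        out[int(lid)] = vals[labels == lid]
    unassigned = int(np.sum(labels == 0))
    return out, unassigned


def summary_stats(values: np.ndarray) -> dict[str, float]:
    """n, median, mean, SD (sample) and 95th percentile (linear interp)."""
    v = np.asarray(values, dtype=float)
    return {
        "n": int(v.size),
        "median": float(np.median(v)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "p95": float(np.percentile(v, 95, method="linear")),
    }


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of with- vs without-microbleed values."""

    u_statistic: float
    p_value: float
    method: str
    with_summary: dict[str, float]
    without_summary: dict[str, float]


def group_compare(with_vals: np.ndarray, without_vals: np.ndarray) -> GroupComparison:
    """Two-tailed Mann-Whitney U with tie correction.

    Exact enumeration when n1*n2 <= 1e4 and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(with_vals, dtype=float)
    y = np.asarray(without_vals, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # degenerate case: every value identical, no evidence of a shift
        return GroupComparison(
            u_statistic=x.size * y.size / 2.0,
            p_value=1.0,
            method="degenerate",
            with_summary=summary_stats(x),
            without_summary=summary_stats(y),
        )
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= 10_000 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        with_summary=summary_stats(x),
        without_summary=summary_stats(y),
    )


def _dunn(values_by_tract: dict[int, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dunn pairwise z from pooled ranks with tie correction; Bonferroni."""
    ids = sorted(values_by_tract)
    pooled = np.concatenate([values_by_tract[i] for i in ids])
    sizes = np.array([values_by_tract[i].size for i in ids])
    ranks = stats.rankdata(pooled)
    big_n = pooled.size
    mean_rank = {}
    start = 0
    for lid, sz in zip(ids, sizes):
        mean_rank[lid] = ranks[start:start + sz].mean()
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (big_n - 1)) if big_n > 1 else 0.0
    base_var = big_n * (big_n + 1) / 12.0 - tie_term
    k = len(ids)
    m = k * (k - 1) // 2
    z = pd.DataFrame(np.zeros((k, k)), index=ids, columns=ids)
    p_raw = pd.DataFrame(np.ones((k, k)), index=ids, columns=ids)
    p_adj = pd.DataFrame(np.ones((k, k)), index=ids, columns=ids)
    for a in range(k):
        for b in range(a + 1, k):
            ia, ib = ids[a], ids[b]
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            zz = (mean_rank[ia] - mean_rank[ib]) / se if se > 0 else 0.0
            pr = 2 * stats.norm.sf(abs(zz))
            pa = min(1.0, m * pr)
            z.loc[ia, ib] = zz
            z.loc[ib, ia] = -zz
            p_raw.loc[ia, ib] = p_raw.loc[ib, ia] = pr
            p_adj.loc[ia, ib] = p_adj.loc[ib, ia] = pa
    return z, p_raw, p_adj


@dataclass
class TractReport:
    """Per-tract summaries plus Kruskal-Wallis and Dunn test results."""

    summaries: pd.DataFrame
    h_statistic: float
    df: int
    p_value: float
    dunn_z: pd.DataFrame
    dunn_p_raw: pd.DataFrame
    dunn_p_adj: pd.DataFrame
    low_count_tracts: list[int] = field(default_factory=list)
    sensitivity: "TractReport | None" = None
    percentile_method: str = "linear interpolation between order statistics"


def tract_compare(
    values_by_tract: dict[int, np.ndarray],
    low_count_threshold: int = LOW_COUNT_THRESHOLD,
    sensitivity: bool = False,
) -> TractReport:
    """Tie-corrected Kruskal-Wallis across tracts plus Dunn post-hoc tests.

    ``sensitivity=True`` additionally re-runs the analysis excluding
    tracts flagged as low-count (n below ``low_count_threshold``).
    All-identical values across every tract yield H = 0, p = 1 rather
    than an error.
    """
    clean = {int(k): np.asarray(v, dtype=float) for k, v in values_by_tract.items()
             if np.asarray(v).size > 0}
    if len(clean) < 2:
        raise ValueError("need at least 2 non-empty tracts")
    ids = sorted(clean)
    samples = [clean[i] for i in ids]
    pooled = np.concatenate(samples)
    if np.unique(pooled).size == 1:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    dz, dpr, dpa = _dunn(clean)
    rows = []
    flagged = []
    for lid in ids:
        s = summary_stats(clean[lid])
        s["tract"] = lid
        s["low_count"] = s["n"] < low_count_threshold
        if s["low_count"]:
            flagged.append(lid)
        rows.append(s)
    summaries = pd.DataFrame(rows).set_index("tract")
    report = TractReport(
        summaries=summaries,
        h_statistic=float(h),
        df=len(ids) - 1,
        p_value=float(p),
        dunn_z=dz,
        dunn_p_raw=dpr,
        dunn_p_adj=dpa,
        low_count_tracts=flagged,
    )
    if sensitivity and flagged and len(ids) - len(flagged) >= 2:
        kept = {i: clean[i] for i in ids if i not in flagged}
        report.sensitivity = tract_compare(kept, low_count_threshold, sensitivity=False)
    return report
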