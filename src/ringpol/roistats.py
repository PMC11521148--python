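"""Downstream ROI analysis of parameter maps.

Covers the analysis that turns per-pixel polarimetric maps into
sample-level conclusions: MAD-based tissue masking (defect exclusion),
masked ROI summaries, radial line profiles across the ring with
heterogeneity metrics, and the non-parametric statistical battery
(Spearman correlations, Kruskal-Wallis across time points with unadjusted
pairwise rank-sum post hoc tests, control-vs-treated rank-sum tests per
time point, and an optional Shapiro-Wilk normality report that motivates
the non-parametric choice).

The sample table is a plain :class:`pandas.DataFrame` with one row per
ROI acquisition; ``day`` and ``group`` are the only design variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TissueMask",
    "LineProfile",
    "GroupTestReport",
    "mad_mask",
    "roi_summary",
    "radial_profile",
    "spearman_battery",
    "group_tests",
]

#: scaled-MAD constant: median(|x - med|) * 1.4826 estimates sigma for
#: normal data, so k = 3 reproduces a 3-sigma outlier rule.
MAD_SCALE = 1.4826


@dataclass
class TissueMask:
    """Boolean retention mask: True = normal tissue pixel kept for
    averaging; False = MAD outlier or non-finite pixel."""

    mask: np.ndarray
    source: str = "Delta"
    k: float = 3.0
    scale: float = MAD_SCALE

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.mask))


def mad_mask(param_map, k: float = 3.0, scale: float = MAD_SCALE,
             source: str = "Delta", within=None) -> TissueMask:
    """Flag outliers exceeding ``k`` scaled median absolute deviations.

    A pixel is excluded iff ``|x - median| > k * scale * MAD`` (with
    ``MAD = median(|x - median|)``) or is non-finite.  An all-constant map
    has MAD 0 and no outliers.  Applied by default to the total
    depolarization map, where tissue defects show up as high-depolarization
    spots.

    ``within`` optionally restricts both the median/MAD statistics and the
    returned mask to a tissue region (boolean map); without it the rule is
    computed over the whole frame, which is only appropriate when the
    frame is mostly tissue.
    """
    x = np.asarray(param_map, dtype=float)
    finite = np.isfinite(x)
    if within is not None:
        finite = finite & np.asarray(within, dtype=bool)
    if np.count_nonzero(finite) < 2:
        raise ValueError("need at least two finite values to build a mask")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    if mad == 0:
        keep = finite
    else:
        keep = finite & (np.abs(x - med) <= k * scale * mad)
    return TissueMask(mask=keep, source=source, k=k, scale=scale)


def roi_summary(maps: dict, mask: TissueMask, **row_meta) -> dict:
    """Masked mean and maximum of every parameter map, as one sample-table
    row.  ``row_meta`` (sample_id, batch_id, day, group, ...) is carried
    through.  Raises on an empty mask."""
    m = mask.mask
    if not np.any(m):
        raise ValueError("empty tissue mask: nothing to summarize")
    row = dict(row_meta)
    row["n_pixels"] = int(np.count_nonzero(m))
    for name, arr in maps.items():
        vals = np.asarray(arr, dtype=float)[m]
        vals = vals[np.isfinite(vals)]
        row[f"{name}_mean"] = float(np.mean(vals)) if vals.size else np.nan
        row[f"{name}_max"] = float(np.max(vals)) if vals.size else np.nan
    return row


@dataclass
class LineProfile:
    """Radial line profile of one parameter across the ring width."""

    distance_um: np.ndarray     # strictly increasing bin centers
    values: np.ndarray          # per-bin mean (NaN where the bin is empty)
    n_pixels: np.ndarray
    profile_std: float          # heterogeneity metric of the profile
    peak_distance_um: float
    peak_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance_um": self.distance_um, "value": self.values,
             "n_pixels": self.n_pixels}
        )


def radial_profile(
    param_map,
    center,
    inner_radius_um: float,
    ring_width_um: float,
    pixel_pitch_um: float = 1.0,
    n_bins: int = 30,
    sector_deg: tuple | None = None,
    mask: TissueMask | None = None,
) -> LineProfile:
    """Average a parameter map in radial bins from the inner ring edge.

    ``center`` is (row, col) in pixels; distances are reported in microns
    from the inner edge.  ``sector_deg = (a, b)`` restricts to an angular
    band (degrees, counter-clockwise from +x).  Empty bins are NaN, never
    interpolated.  The profile standard deviation (computed over non-empty
    bins) quantifies spatial heterogeneity across the ring width.
    """
    x = np.asarray(param_map, dtype=float)
    H, W = x.shape
    rr, cc = np.mgrid[0:H, 0:W]
    dy = (rr - center[0]) * pixel_pitch_um
    dx = (cc - center[1]) * pixel_pitch_um
    r = np.hypot(dx, dy)
    dist = r - inner_radius_um
    sel = (dist >= 0) & (dist <= ring_width_um) & np.isfinite(x)
    if mask is not None:
        sel &= mask.mask
    if sector_deg is not None:
        ang = np.rad2deg(np.arctan2(-dy, dx)) % 360.0  # image rows grow downward
        a, b = (s % 360.0 for s in sector_deg)
        in_sector = (ang >= a) & (ang <= b) if a <= b else (ang >= a) | (ang <= b)
        sel &= in_sector
    edges = np.linspace(0.0, ring_width_um, n_bins + 1)
    idx = np.digitize(dist[sel], edges) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    vals = x[sel]
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = cnts > 0
    if not np.any(ok):
        raise ValueError("ring geometry does not intersect the finite map")
    std = float(np.std(means[ok]))
    peak = int(np.nanargmax(np.where(ok, means, -np.inf)))
    return LineProfile(
        distance_um=centers,
        values=means,
        n_pixels=cnts,
        profile_std=std,
        peak_distance_um=float(centers[peak]),
        peak_value=float(means[peak]),
    )


def fit_ring_geometry(mask: np.ndarray, pixel_pitch_um: float = 1.0):
    """Least-squares circle fit of the annulus in a boolean tissue mask.

    Returns ``(center_rc, inner_radius_um, ring_width_um)``.  Algebraic
    (Kasa) fit of the mid-ring circle from the mask pixels, with the radial
    extent read from the pixel radius distribution.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if ys.size < 10:
        raise ValueError("mask too small to fit ring geometry")
    Amat = np.column_stack([2 * xs, 2 * ys, np.ones_like(xs)])
    bvec = xs**2 + ys**2
    sol, *_ = np.linalg.lstsq(Amat, bvec, rcond=None)
    cx, cy, c = sol
    r = np.hypot(xs - cx, ys - cy)
    inner = float(np.percentile(r, 1))
    outer = float(np.percentile(r, 99))
    return (
        (float(cy), float(cx)),
        inner * pixel_pitch_um,
        (outer - inner) * pixel_pitch_um,
    )


# ---------------------------------------------------------------------------
# statistical battery


def _spearman(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_battery(table: pd.DataFrame, params: list | None = None):
    """Spearman rank correlations among parameter means and against the
    design variables (day as ordinal, group as binary).

    Returns a dict with DataFrames ``rho`` and ``p`` (parameter x
    parameter) and ``design`` (parameter x {day, group} with rho and p).
    Constant columns give NaN (undefined correlation), reported missing.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    if params is None:
        params = [c for c in table.columns if c.endswith("_mean")]
    n = len(params)
    rho = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            r, p = _spearman(table[params[i]], table[params[j]])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    design_rows = []
    group_codes = (table["group"].astype(str) != "control").astype(int)
    for name in params:
        r_day, p_day = _spearman(table[name], table["day"])
        r_grp, p_grp = _spearman(table[name], group_codes)
        design_rows.append(
            {"parameter": name, "rho_day": r_day, "p_day": p_day,
             "rho_group": r_grp, "p_group": p_grp}
        )
    return {
        "rho": pd.DataFrame(rho, index=params, columns=params),
        "p": pd.DataFrame(pval, index=params, columns=params),
        "design": pd.DataFrame(design_rows).set_index("parameter"),
    }


def rank_sum_test(x, y, exact_max_n: int = 12):
    """Two-sample two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null distribution when both arms have <= ``exact_max_n``
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with midranks, tie correction and continuity correction.
    Degenerate case (all pooled values identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each compared cell needs n >= 2")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and max(x.size, y.size) <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupTestReport:
    kruskal: pd.DataFrame          # per group: H statistic, p across days
    pairwise_days: pd.DataFrame    # per group: unadjusted day-pair rank sums
    between_groups: pd.DataFrame   # per day: control vs treated rank sum
    shapiro: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "kruskal": self.kruskal.to_dict(orient="records"),
            "pairwise_days": self.pairwise_days.to_dict(orient="records"),
            "between_groups": self.between_groups.to_dict(orient="records"),
        }
        if self.shapiro is not None:
            out["shapiro"] = self.shapiro.to_dict(orient="records")
        return out


def group_tests(
    table: pd.DataFrame,
    param: str = "delta_deg_mean",
    adjust: str | None = None,
    shapiro: bool = True,
) -> GroupTestReport:
    """The non-parametric battery over one parameter column.

    Per treatment group: Kruskal-Wallis across days, then unadjusted
    pairwise two-sample rank-sum tests between all day pairs (original
    p values; Holm adjustment available via ``adjust="holm"``).  Per day:
    rank-sum test of control vs treated.  Optionally a Shapiro-Wilk
    normality report per (group, day) cell.
    """
    groups = sorted(table["group"].astype(str).unique())
    days = sorted(table["day"].unique())

    kw_rows, pair_rows, sw_rows = [], [], []
    for g in groups:
        sub = table[table["group"].astype(str) == g]
        cells = [sub.loc[sub["day"] == d, param].dropna().to_numpy() for d in days]
        used = [(d, c) for d, c in zip(days, cells) if c.size >= 2]
        if len(used) >= 2:
            H, p = stats.kruskal(*[c for _, c in used])
            kw_rows.append({"group": g, "H": float(H), "p": float(p),
                            "n_total": int(sum(c.size for _, c in used))})
        for (d1, c1), (d2, c2) in itertools.combinations(used, 2):
            U, p = rank_sum_test(c1, c2)
            pair_rows.append({"group": g, "day_a": d1, "day_b": d2,
                              "U": U, "p": p, "n_a": c1.size, "n_b": c2.size})
        if shapiro:
            for d, c in used:
                if c.size >= 3 and np.ptp(c) > 0:
                    w, p = stats.shapiro(c)
                    sw_rows.append({"group": g, "day": d, "W": float(w),
                                    "p": float(p), "n": c.size})

    between_rows = []
    if len(groups) == 2:
        g0, g1 = groups
        for d in days:
            c0 = table.loc[(table["group"].astype(str) == g0) & (table["day"] == d),
                           param].dropna().to_numpy()
            c1 = table.loc[(table["group"].astype(str) == g1) & (table["day"] == d),
                           param].dropna().to_numpy()
            if c0.size >= 2 and c1.size >= 2:
                U, p = rank_sum_test(c0, c1)
                between_rows.append({"day": d, "U": U, "p": p,
                                     "n_a": c0.size, "n_b": c1.size})

    pairwise = pd.DataFrame(pair_rows)
    if adjust == "holm" and len(pairwise):
        for g in groups:
            sel = pairwise["group"] == g
            p = pairwise.loc[sel, "p"].to_numpy()
            order = np.argsort(p)
            adj = np.empty_like(p)
            m = p.size
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * p[i])
                adj[i] = min(1.0, running)
            pairwise.loc[sel, "p_holm"] = adj

    return GroupTestReport(
        kruskal=pd.DataFrame(kw_rows),
        pairwise_days=pairwise,
        between_groups=pd.DataFrame(between_rows),
        shapiro=pd.DataFrame(sw_rows) if shapiro else None,
    )
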