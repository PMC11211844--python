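"""Evaluation utilities: branch-length error, diffusion-rate bias,
displacement-radius sweeps, and the division-angle analysis.

The division-angle analysis quantifies the evidence for symmetric
displacement in tracked data: for every division, the angle at the
parent's last recorded position subtended by the two daughters ``tau``
frames later is 180 degrees under pure symmetric displacement, while under
pure Brownian motion the daughters' displacement vectors are isotropic and
independent, making the angle uniform on [0, 180] — the null distribution
used by the uniformity test.  As the lag grows, diffusion washes out the
initial displacement and the angle distribution relaxes toward uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import trees

__all__ = [
    "mape",
    "mape_trees",
    "sigma_bias",
    "TripletRecord",
    "extract_triplets",
    "dpd_angle",
    "angles_at_lag",
    "angle_uniformity",
    "angle_lag_profile",
    "r_sweep_report",
]


def mape(truth, estimate) -> float:
    """Mean absolute percentage error, as a fraction (0.75 = 75%).

    ``mean(|est_i - true_i| / true_i)`` over matched branch pairs; truths
    must be strictly positive.
    """
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("truth and estimate must be equal-length 1D")
    if (t <= 0).any():
        raise ValueError("zero or negative true branch length: MAPE "
                         "term undefined")
    return float(np.mean(np.abs(e - t) / t))


def _edge_lengths_by_name(tree: trees.LineageTree) -> dict[str, float]:
    out = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        name = tree.leaf_name.get(v) or tree.label.get(v)
        if not name:
            raise ValueError(
                "edge matching needs named nodes (leaf names / internal "
                f"labels); node {v} is unnamed"
            )
        out[name] = tree.branch_length[v]
    return out


def mape_trees(true_tree: trees.LineageTree,
               fitted_tree: trees.LineageTree) -> float:
    """MAPE between two length assignments of the same labeled topology.

    Edges are matched by the name of their child node (leaf name or
    internal label), so the comparison is independent of node-id order.
    """
    t = _edge_lengths_by_name(true_tree)
    e = _edge_lengths_by_name(fitted_tree)
    if set(t) != set(e):
        raise ValueError("trees do not share edge names")
    names = sorted(t)
    return mape([t[n] for n in names], [e[n] for n in names])


def sigma_bias(fits, truth_sigma: float) -> dict:
    """Bias summary of estimated diffusion rates, grouped by
    (modality, r).

    ``fits`` is an iterable of FitResult (or of plain floats, treated as a
    single anonymous group).  Returns
    ``{(modality, r): {n, mean_bias, sd, se}}``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits given")
    groups: dict[tuple, list[float]] = {}
    for f in fits:
        if hasattr(f, "sigma"):
            if f.sigma is None:
                raise ValueError("fit has no spatial component")
            groups.setdefault((f.modality, f.r), []).append(f.sigma)
        else:
            groups.setdefault(("", None), []).append(float(f))
    out = {}
    for key, vals in groups.items():
        arr = np.asarray(vals) - truth_sigma
        out[key] = {
            "n": len(arr),
            "mean_bias": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "se": (float(arr.std(ddof=1) / math.sqrt(len(arr)))
                   if len(arr) > 1 else 0.0),
        }
    return out


# ---------------------------------------------------------------------------
# division-angle analysis
# ---------------------------------------------------------------------------

@dataclass
class TripletRecord:
    """A parent position right before division and its two daughters'
    positions ``lag`` frames later."""

    parent: tuple[float, float]
    daughter1: tuple[float, float]
    daughter2: tuple[float, float]
    lag: int

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        for p in (self.parent, self.daughter1, self.daughter2):
            if not all(np.isfinite(p)):
                raise ValueError("non-finite position")


def extract_triplets(
    frames: pd.DataFrame, lag: int = 1
) -> tuple[list[TripletRecord], int]:
    """Collect division triplets from a (frame, cell, parent, x, y) table.

    For each cell whose track ends in a division (two cells list it as
    parent), the record pairs its last recorded position with both
    daughters' positions ``lag`` frames later.  Divisions where either
    daughter is not tracked that long are skipped and counted; returns
    (records, n_skipped).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    records: list[TripletRecord] = []
    skipped = 0
    pos = {(r.cell, int(r.frame)): (float(r.x), float(r.y))
           for r in frames.itertuples()}
    last_frame = frames.groupby("cell")["frame"].max()
    children: dict[str, list[str]] = {}
    for cell, parent in frames[["cell", "parent"]].drop_duplicates() \
                                                  .itertuples(index=False):
        if isinstance(parent, str) and parent:
            children.setdefault(parent, [])
            if cell not in children[parent]:
                children[parent].append(cell)
    for parent, kids in children.items():
        if len(kids) != 2 or parent not in last_frame.index:
            continue
        t = int(last_frame[parent])
        p = pos.get((parent, t))
        d1 = pos.get((kids[0], t + lag))
        d2 = pos.get((kids[1], t + lag))
        if p is None or d1 is None or d2 is None:
            skipped += 1
            continue
        records.append(TripletRecord(parent=p, daughter1=d1,
                                     daughter2=d2, lag=lag))
    if not children:
        import warnings
        warnings.warn("no divisions found in frames table")
    return records, skipped


def dpd_angle(record: TripletRecord) -> float:
    """Daughter-parent-daughter angle in degrees, in [0, 180].

    The angle at the parent between the two daughter displacement vectors;
    invariant to translation and rotation.  Raises if either daughter
    coincides with the parent.
    """
    p = np.asarray(record.parent)
    v1 = np.asarray(record.daughter1) - p
    v2 = np.asarray(record.daughter2) - p
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("degenerate triplet: daughter at parent position")
    c = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def angles_at_lag(frames: pd.DataFrame, lag: int = 1) -> np.ndarray:
    """All non-degenerate division angles at one lag, in degrees."""
    records, _ = extract_triplets(frames, lag)
    out = []
    for rec in records:
        try:
            out.append(dpd_angle(rec))
        except ValueError:
            continue
    return np.asarray(out)


def angle_uniformity(angles, n_bins: int = 18) -> dict:
    """Test division angles against the Brownian null Uniform[0, 180].

    Returns the empirical histogram, the two-sided Kolmogorov-Smirnov
    statistic and p-value against the uniform CDF, and the histogram mode.
    Requires at least 20 angles.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 20:
        raise ValueError("need >= 20 angles for the uniformity test")
    if (a < 0).any() or (a > 180).any():
        raise ValueError("angles must lie in [0, 180] degrees")
    ks = stats.kstest(a, stats.uniform(loc=0.0, scale=180.0).cdf)
    hist, edges = np.histogram(a, bins=n_bins, range=(0.0, 180.0))
    mode_bin = int(np.argmax(hist))
    return {
        "n": int(a.size),
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
        "mode_degrees": float(0.5 * (edges[mode_bin] + edges[mode_bin + 1])),
        "mean_degrees": float(a.mean()),
    }


def angle_lag_profile(frames: pd.DataFrame, lags) -> dict:
    """Distance from the uniform null across a grid of lags.

    Returns per-lag uniformity summaries plus a monotone-trend summary
    (Spearman correlation of KS distance against lag); a negative trend
    means the angle distribution relaxes toward the Brownian null with
    time since division.
    """
    lags = sorted(int(t) for t in lags)
    if len(lags) < 1:
        raise ValueError("need at least one lag")
    rows = []
    for lag in lags:
        a = angles_at_lag(frames, lag)
        if a.size >= 20:
            summ = angle_uniformity(a)
            rows.append({"lag": lag, **summ})
        else:
            rows.append({"lag": lag, "n": int(a.size),
                         "ks_statistic": None, "p_value": None})
    ks = [(r["lag"], r["ks_statistic"]) for r in rows
          if r["ks_statistic"] is not None]
    trend = None
    if len(ks) >= 3:
        rho = stats.spearmanr([k[0] for k in ks], [k[1] for k in ks])
        trend = float(rho.statistic)
    return {"per_lag": rows, "ks_trend_spearman": trend}


# ---------------------------------------------------------------------------
# displacement-radius sweep
# ---------------------------------------------------------------------------

def r_sweep_report(fits_by_r: dict, true_trees, truth_sigma: float) -> dict:
    """Summarize fits across a grid of displacement magnitudes.

    ``fits_by_r`` maps r to a list of FitResult; ``true_trees`` is the
    matched list of generating trees (shared across r).  Reports per-r mean
    sigma bias and mean branch-length MAPE, and the r minimizing mean MAPE
    (ties broken toward the smallest r).  Requires at least 3 r values.
    """
    if len(fits_by_r) < 3:
        raise ValueError("need >= 3 r values for a sweep")
    rows = []
    for r in sorted(fits_by_r):
        fits = fits_by_r[r]
        if len(fits) != len(true_trees):
            raise ValueError("fits and true_trees must be matched lists")
        mapes = [mape_trees(tt, f.tree) for tt, f in zip(true_trees, fits)]
        biases = [f.sigma - truth_sigma for f in fits if f.sigma is not None]
        rows.append({
            "r": float(r),
            "mean_sigma_bias": (float(np.mean(biases)) if biases else None),
            "mean_mape": float(np.mean(mapes)),
            "n": len(fits),
        })
    best = min(rows, key=lambda row: (row["mean_mape"], row["r"]))
    return {"per_r": rows, "argmin_r": best["r"]}
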