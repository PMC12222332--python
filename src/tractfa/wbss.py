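"""Whole-brain voxel-wise statistics on FA maps.

Group contrasts use Welch's unequal-variance t-test per voxel inside an
FA > 0.2 analysis mask; clinical-score analyses use per-voxel Pearson
correlation. Multiplicity is handled by Benjamini–Hochberg FDR at
alpha = 0.05, followed by a cluster-extent filter (default 256 voxels)
that removes isolated voxels and small clusters on the scale of the
smoothing kernel. Surviving clusters are reported with peak world
coordinates, extent, peak statistic, and sign, in descending size order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from statsmodels.stats.multitest import multipletests

from .grids import ScalarMap

FA_MASK_THRESHOLD = 0.2
ALPHA_DEFAULT = 0.05
CLUSTER_MIN_VOXELS = 256


@dataclass
class ClusterRecord:
    peak_xyz_mm: tuple[float, float, float]
    size_voxels: int
    peak_stat: float
    sign: int                    # +1 FA increase / positive stat, -1 decrease
    corrected_p: float           # q-value at the peak voxel
    peak_r: float | None = None  # Pearson R at peak, correlation analyses only
    coords: np.ndarray | None = None   # (n, 3) voxel indices of the cluster

    def as_row(self) -> dict:
        x, y, z = self.peak_xyz_mm
        row = dict(hemisphere="L" if x < 0 else "R", x=x, y=y, z=z,
                   n_voxels=self.size_voxels, peak_stat=self.peak_stat,
                   sign=self.sign, corrected_p=self.corrected_p)
        if self.peak_r is not None:
            row["R"] = self.peak_r
        return row


@dataclass
class StatReport:
    stat_map: ScalarMap
    p_map: ScalarMap
    q_map: ScalarMap
    rejection: np.ndarray
    surviving: np.ndarray
    clusters: list[ClusterRecord]
    mask: np.ndarray
    descriptor: str = ""
    flagged_voxels: int = 0

    def cluster_table(self) -> pd.DataFrame:
        cols = ["hemisphere", "x", "y", "z", "n_voxels", "peak_stat",
                "sign", "corrected_p", "R"]
        rows = [c.as_row() for c in self.clusters]
        df = pd.DataFrame(rows)
        if rows and "R" not in df.columns:
            cols = [c for c in cols if c != "R"]
        return df.reindex(columns=cols) if rows else pd.DataFrame(columns=cols[:-1])


def analysis_mask(fa_maps: list[ScalarMap],
                  threshold: float = FA_MASK_THRESHOLD) -> np.ndarray:
    """Voxels where the grand-mean FA across all subjects exceeds threshold."""
    if not fa_maps:
        raise ValueError("need at least one FA map")
    grand = np.mean(np.stack([m.data for m in fa_maps]), axis=0)
    return grand > threshold


def welch_from_stacks(a: np.ndarray, b: np.ndarray):
    """Vectorized Welch t, Welch–Satterthwaite df, and two-sided p.

    ``a`` and ``b`` stack subjects along axis 0. Voxels with zero variance
    in both groups get t = 0, p = 1.
    """
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("Welch test needs at least 2 subjects per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 <= 0
    se2_safe = np.where(degenerate, 1.0, se2)
    t = np.where(degenerate, 0.0, (ma - mb) / np.sqrt(se2_safe))
    with np.errstate(invalid="ignore", divide="ignore"):
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    df = np.where(degenerate | ~np.isfinite(df), 1.0, df)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, df, p


def welch_map(group_a: list[ScalarMap], group_b: list[ScalarMap],
              mask: np.ndarray) -> tuple[ScalarMap, ScalarMap, int]:
    """Voxel-wise Welch test (A minus B) inside the mask; returns (t, p, n_degenerate)."""
    ref = group_a[0]
    a = np.stack([m.data for m in group_a])
    b = np.stack([m.data for m in group_b])
    t, _, p = welch_from_stacks(a, b)
    t = np.where(mask, t, 0.0)
    p = np.where(mask, p, 1.0)
    flagged = int(np.sum(mask & (np.ptp(a, axis=0) == 0) & (np.ptp(b, axis=0) == 0)))
    return ref.like(t, "t"), ref.like(p, "p"), flagged


def fdr_correct(p_map: ScalarMap, mask: np.ndarray,
                alpha: float = ALPHA_DEFAULT,
                method: str = "fdr_bh") -> tuple[ScalarMap, np.ndarray]:
    """Benjamini–Hochberg step-up over in-mask voxels.

    Returns the q-value map (1 outside the mask) and the rejection mask
    (q <= alpha). ``method='fdr_by'`` switches to Benjamini–Yekutieli.
    """
    pvals = p_map.data[mask]
    q = np.ones_like(p_map.data)
    rej = np.zeros(p_map.shape, dtype=bool)
    if pvals.size:
        rejected, qvals, _, _ = multipletests(pvals, alpha=alpha, method=method)
        q[mask] = qvals
        rej[mask] = rejected
    return p_map.like(q, "q"), rej


def cluster_filter(rejection: np.ndarray, min_voxels: int = CLUSTER_MIN_VOXELS,
                   stat_map: ScalarMap | None = None,
                   q_map: ScalarMap | None = None,
                   r_map: ScalarMap | None = None,
                   connectivity: int = 3) -> tuple[np.ndarray, list[ClusterRecord]]:
    """Connected-component extent filter with signed cluster reporting.

    Components (26-connectivity by default; ``connectivity`` counts the
    orthogonal steps allowed, 1=6-conn, 3=26-conn) smaller than
    ``min_voxels`` are removed. Positive- and negative-statistic voxels are
    labelled separately so a decrease touching an increase is not merged.
    Records are sorted by size, descending.
    """
    rejection = np.asarray(rejection, dtype=bool)
    stat = stat_map.data if stat_map is not None else np.ones(rejection.shape)
    surviving = np.zeros_like(rejection)
    records: list[ClusterRecord] = []
    for sign in (1, -1):
        part = rejection & ((stat > 0) if sign > 0 else (stat <= 0)) \
            if stat_map is not None else (rejection if sign > 0 else np.zeros_like(rejection))
        if not part.any():
            continue
        labels = measure.label(part, connectivity=connectivity)
        for region in measure.regionprops(labels):
            if region.area < min_voxels:
                continue
            coords = region.coords
            surviving[tuple(coords.T)] = True
            vals = stat[tuple(coords.T)]
            peak_idx = coords[np.argmax(np.abs(vals))]
            ref = stat_map if stat_map is not None else \
                (q_map if q_map is not None else None)
            if ref is not None:
                peak_world = tuple(np.round(ref.voxel_to_world(peak_idx)[0], 6))
            else:
                peak_world = tuple(float(c) for c in peak_idx)
            records.append(ClusterRecord(
                peak_xyz_mm=peak_world,
                size_voxels=int(region.area),
                peak_stat=float(stat[tuple(peak_idx)]) if stat_map is not None else 1.0,
                sign=sign,
                corrected_p=float(q_map.data[tuple(peak_idx)]) if q_map is not None else np.nan,
                peak_r=float(r_map.data[tuple(peak_idx)]) if r_map is not None else None,
                coords=coords))
    records.sort(key=lambda r: r.size_voxels, reverse=True)
    return surviving, records


def group_compare(group_a: list[ScalarMap], group_b: list[ScalarMap],
                  mask: np.ndarray, alpha: float = ALPHA_DEFAULT,
                  min_voxels: int = CLUSTER_MIN_VOXELS,
                  descriptor: str = "") -> StatReport:
    """Full WBSS contrast: Welch map -> BH FDR -> cluster-extent filter."""
    t_map, p_map, flagged = welch_map(group_a, group_b, mask)
    q_map, rej = fdr_correct(p_map, mask, alpha)
    surviving, records = cluster_filter(rej, min_voxels, stat_map=t_map, q_map=q_map)
    return StatReport(t_map, p_map, q_map, rej, surviving, records, mask,
                      descriptor or "welch", flagged)


def pearson_from_stack(maps: np.ndarray, scores: np.ndarray):
    """Vectorized per-voxel Pearson r and two-sided p against a score vector."""
    n = maps.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 subjects")
    s = np.asarray(scores, dtype=float)
    if np.ptp(s) == 0:
        r = np.zeros(maps.shape[1:])
        return r, np.ones_like(r), True
    sc = s - s.mean()
    mc = maps - maps.mean(axis=0)
    num = np.tensordot(sc, mc, axes=([0], [0]))
    den = np.linalg.norm(sc) * np.sqrt(np.sum(mc ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(den > 0, p, 1.0)
    return r, p, False


def correlation_map(fa_maps: list[ScalarMap], scores: np.ndarray,
                    mask: np.ndarray, alpha: float = ALPHA_DEFAULT,
                    min_voxels: int = CLUSTER_MIN_VOXELS,
                    descriptor: str = "fa~score") -> StatReport:
    """Voxel-wise Pearson correlation of FA with a clinical score,
    FDR- and cluster-corrected; cluster records carry R at the peak."""
    ref = fa_maps[0]
    stack = np.stack([m.data for m in fa_maps])
    r, p, degenerate = pearson_from_stack(stack, scores)
    r = np.where(mask, r, 0.0)
    p = np.where(mask, p, 1.0)
    r_map, p_map = ref.like(r, "r"), ref.like(p, "p")
    q_map, rej = fdr_correct(p_map, mask, alpha)
    surviving, records = cluster_filter(rej, min_voxels, stat_map=r_map,
                                        q_map=q_map, r_map=r_map)
    flagged = int(np.sum(mask)) if degenerate else 0
    return StatReport(r_map, p_map, q_map, rej, surviving, records, mask,
                      descriptor, flagged)


def peak_spheres(report: StatReport, radius_mm: float = 5.0) -> list[np.ndarray]:
    """One spherical ROI mask per surviving cluster, centred at its peak,
    clipped to the analysis mask. radius 0 gives the single peak voxel."""
    ref = report.stat_map
    shape = ref.shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = ref.voxel_to_world(vox)
    rois = []
    for cl in report.clusters:
        d = np.linalg.norm(world - np.asarray(cl.peak_xyz_mm), axis=1)
        roi = (d <= radius_mm + 1e-9).reshape(shape) & report.mask
        rois.append(roi)
    return rois


def longitudinal_compare(patient_maps_t0: list[ScalarMap],
                         patient_maps_t1: list[ScalarMap],
                         control_maps: list[ScalarMap],
                         mask: np.ndarray,
                         alpha: float = ALPHA_DEFAULT,
                         min_voxels: int = CLUSTER_MIN_VOXELS):
    """Patients-vs-controls WBSS at each timepoint against the same controls,
    plus a per-cluster size-change table.

    Baseline clusters are matched to follow-up clusters of the same sign by
    maximal voxel overlap (robust against the peak drifting along a tract);
    an unmatched baseline cluster is reported with size 0 at follow-up.
    """
    rep0 = group_compare(patient_maps_t0, control_maps, mask, alpha, min_voxels,
                         "t0 vs controls")
    rep1 = group_compare(patient_maps_t1, control_maps, mask, alpha, min_voxels,
                         "t1 vs controls")

    def vox_set(c):
        return set(map(tuple, c.coords)) if c.coords is not None else set()

    rows = []
    used = set()
    for i, c0 in enumerate(rep0.clusters):
        s0 = vox_set(c0)
        best_j, best_ov = None, 0
        for j, c1 in enumerate(rep1.clusters):
            if j in used or c1.sign != c0.sign:
                continue
            ov = len(s0 & vox_set(c1))
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j is not None:
            used.add(best_j)
            c1 = rep1.clusters[best_j]
            rows.append(dict(cluster=i, size_t0=c0.size_voxels,
                             size_t1=c1.size_voxels,
                             growth=c1.size_voxels - c0.size_voxels,
                             overlap_voxels=best_ov, sign=c0.sign))
        else:
            rows.append(dict(cluster=i, size_t0=c0.size_voxels, size_t1=0,
                             growth=-c0.size_voxels, overlap_voxels=0,
                             sign=c0.sign))
    growth = pd.DataFrame(rows, columns=["cluster", "size_t0", "size_t1",
                                         "growth", "overlap_voxels", "sign"])
    return rep0, rep1, growth
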