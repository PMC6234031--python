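"""Time-course expression classification into transient/stable/down-regulated groups.

Procedure (normalized counts in, gene groups out):

1. per-gene control baseline by linear interpolation through the 0/6/12 hr untreated
   samples, subtracted from the treated samples;
2. gene filter: keep genes with (a) absolute fold-change > 2 at some treated time
   relative to the 0 hr control (computed on baseline-adjusted values re-anchored to
   the 0 hr level, with a pseudocount) and (b) a normalized read count > 100 at some
   treated time;
3. z-score each kept gene's adjusted profile across time points;
4. hierarchical clustering with centered-correlation distance and average linkage;
5. cut into k clusters (default 12: enough for noise outliers to form their own
   small clusters instead of forcing distinct response shapes to merge) and assign
   each cluster to the transient-up / stable-up / down template by Pearson
   correlation of its mean z-profile (below 0.5 -> unassigned).

Also provides median-of-ratios count normalization, a hypergeometric gene-set
enrichment with Benjamini-Hochberg correction, and RT-PCR relative quantification
(reference-gene and pre-stimulus double normalization; 2^-ddCt for Ct input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix
from .synth import class_template

__all__ = [
    "FilterParams",
    "normalize_counts",
    "interpolate_baseline",
    "subtract_baseline",
    "filter_genes",
    "zscore_profiles",
    "hcluster",
    "assign_groups",
    "geneset_enrichment",
    "rtpcr_relative",
    "run_timecourse_analysis",
]

GROUP_LABELS = ("transient_up", "stable_up", "down")


@dataclass
class FilterParams:
    fc_threshold: float = 2.0
    min_count: float = 100.0
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.min_count <= 0 or self.pseudocount < 0:
            raise ValueError("min_count > 0 and pseudocount >= 0 required")


def normalize_counts(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization (genes x samples in, same shape out).

    Size factor of a sample = median over genes of count / geometric mean across
    samples, using only genes with no zero count. With no usable gene (e.g. a single
    gene) the factors fall back to total-count ratios, with a warning. Returns
    (normalized matrix, size factors).
    """
    if raw.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    arr = raw.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    totals = arr.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a sample has all-zero counts")
    usable = np.all(arr > 0, axis=1)
    if usable.sum() >= 2:
        log_gm = np.log(arr[usable]).mean(axis=1)
        factors = np.exp(np.median(np.log(arr[usable]) - log_gm[:, None], axis=0))
    else:
        warnings.warn("too few all-positive genes; size factors from total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = pd.Series(factors, index=raw.columns, name="size_factor")
    return raw / factors, factors


def interpolate_baseline(
    control: pd.DataFrame,
    control_times,
    target_times,
) -> pd.DataFrame:
    """Per-gene piecewise-linear baseline through the control samples.

    ``control`` has one column per control time (in ``control_times`` order).
    Target times outside the control range are rejected (no extrapolation).
    """
    control_times = np.asarray(control_times, dtype=float)
    target_times = np.asarray(target_times, dtype=float)
    if control.shape[1] != control_times.size:
        raise ValueError("control columns must match control_times")
    order = np.argsort(control_times)
    ct = control_times[order]
    if target_times.min() < ct[0] or target_times.max() > ct[-1]:
        raise ValueError("target times outside the control range; no extrapolation")
    vals = control.to_numpy(dtype=float)[:, order]
    out = np.empty((control.shape[0], target_times.size))
    # locate the control segment per target time, then blend the two knot columns
    for j, t in enumerate(target_times):
        k = np.searchsorted(ct, t, side="right") - 1
        k = min(max(k, 0), len(ct) - 2)
        w = 0.0 if ct[k + 1] == ct[k] else (t - ct[k]) / (ct[k + 1] - ct[k])
        out[:, j] = (1 - w) * vals[:, k] + w * vals[:, k + 1]
    return pd.DataFrame(out, index=control.index,
                        columns=[f"baseline_{t:g}hr" for t in target_times])


def subtract_baseline(treated: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Element-wise treated minus baseline (may be negative: down-regulation keeps sign)."""
    if treated.shape != baseline.shape or not treated.index.equals(baseline.index):
        raise ValueError("treated and baseline matrices are not aligned")
    return pd.DataFrame(treated.to_numpy() - baseline.to_numpy(),
                        index=treated.index, columns=treated.columns)


def filter_genes(
    treated: pd.DataFrame,
    adjusted: pd.DataFrame,
    t0: pd.Series,
    params: FilterParams = FilterParams(),
) -> pd.Index:
    """Genes with fold-change > threshold (either direction) and sufficient counts.

    The fold-change is computed on baseline-adjusted values re-anchored to the 0 hr
    control level: R_t = (adjusted_t + t0 + pseudocount) / (t0 + pseudocount); a gene
    is kept iff max_t max(R_t, 1/R_t) > fc_threshold AND max_t treated_t > min_count.
    """
    if not treated.index.equals(adjusted.index):
        raise ValueError("treated and adjusted matrices are not aligned")
    t0v = t0.reindex(treated.index).to_numpy(dtype=float)
    denom = t0v + params.pseudocount
    R = (adjusted.to_numpy(dtype=float) + t0v[:, None] + params.pseudocount) / denom[:, None]
    R = np.maximum(R, 1e-12)
    fc = np.max(np.maximum(R, 1.0 / R), axis=1)
    count_ok = treated.to_numpy(dtype=float).max(axis=1) > params.min_count
    keep = (fc > params.fc_threshold) & count_ok
    return treated.index[keep]


def zscore_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across time points (sample SD); zero-SD genes are dropped."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 time points to z-score")
    arr = matrix.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluded {int((~keep).sum())} zero-variance genes from z-scoring")
    z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def hcluster(z: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration with centered-correlation distance.

    Distance between genes = 1 - Pearson correlation of their (mean-centered)
    profiles. Returns a scipy linkage matrix.
    """
    if z.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    arr = z.to_numpy(dtype=float)
    if np.any(arr.std(axis=1) == 0):
        raise ValueError("constant rows must be excluded before clustering")
    return linkage(arr, method="average", metric="correlation")


def _canonical_templates(times) -> dict:
    """Z-scored class templates evaluated on the treated time grid."""
    out = {}
    for name in GROUP_LABELS:
        prof = class_template(name, times, effect_size=2.0) - 1.0
        out[name] = (prof - prof.mean()) / prof.std(ddof=1)
    return out


def assign_groups(
    Z: np.ndarray,
    z: pd.DataFrame,
    times,
    n_clusters: int = 12,
    min_correlation: float = 0.5,
) -> pd.DataFrame:
    """Cut the tree into clusters and label each cluster by its best-matching template.

    Each cluster's mean z-profile is correlated (Pearson) against the canonical
    transient-up / stable-up / down templates evaluated at the treated times; the
    best template wins unless its correlation is below ``min_correlation``, in which
    case the cluster is left unassigned. Returns a per-gene table (gene, cluster,
    group).
    """
    if n_clusters > z.shape[0]:
        raise ValueError("more clusters requested than genes")
    clusters = fcluster(Z, t=n_clusters, criterion="maxclust")
    templates = _canonical_templates(np.asarray(times, dtype=float))
    groups = pd.Series("unassigned", index=z.index, name="group")
    for c in np.unique(clusters):
        sel = clusters == c
        prof = z.to_numpy()[sel].mean(axis=0)
        if prof.std(ddof=1) == 0:
            continue
        best_name, best_r = None, -np.inf
        for name, tmpl in templates.items():
            r = np.corrcoef(prof, tmpl)[0, 1]
            if r > best_r:
                best_name, best_r = name, r
        if best_r >= min_correlation:
            groups.iloc[np.nonzero(sel)[0]] = best_name
    return pd.DataFrame({"gene": z.index, "cluster": clusters, "group": groups.to_numpy()}
                        ).set_index("gene")


def geneset_enrichment(groups: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """Hypergeometric enrichment of each gene group in each named set.

    The universe is all filtered genes (the index of ``groups``); sets are
    intersected with the universe and empty intersections skipped. Upper-tail
    p-values are Benjamini-Hochberg corrected across the whole table.
    """
    universe = set(groups.index)
    M = len(universe)
    rows = []
    for set_name, genes in gene_sets.items():
        members = universe & set(genes)
        if not members:
            continue
        n_set = len(members)
        for group_name in sorted(groups["group"].unique()):
            if group_name == "unassigned":
                continue
            group_genes = set(groups.index[groups["group"] == group_name])
            N = len(group_genes)
            k = len(group_genes & members)
            p = float(stats.hypergeom.sf(k - 1, M, n_set, N))
            rows.append({"group": group_name, "gene_set": set_name, "overlap": k,
                         "group_size": N, "set_size": n_set, "p_value": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def rtpcr_relative(
    table: pd.DataFrame,
    t0_sample: str,
    reference_gene: str = "GAPDH",
    input_kind: str = "expression",
) -> pd.DataFrame:
    """Relative expression normalized to a reference gene and the pre-stimulus sample.

    ``table`` is genes x samples of expression values (``input_kind='expression'``) or
    Ct values (``'ct'``, quantified as 2^-ddCt). Each gene is divided by the reference
    gene within each sample, then by the same ratio in ``t0_sample``; the reference
    gene and the t0 sample map to 1 by construction.
    """
    if reference_gene not in table.index:
        raise ValueError(f"reference gene {reference_gene!r} missing")
    if t0_sample not in table.columns:
        raise ValueError(f"t0 sample {t0_sample!r} missing")
    arr = table.to_numpy(dtype=float)
    ref = table.loc[reference_gene].to_numpy(dtype=float)
    if input_kind == "expression":
        if np.any(ref <= 0):
            raise ValueError("reference gene has non-positive expression")
        ratio = arr / ref[None, :]
        t0 = ratio[:, table.columns.get_loc(t0_sample)]
        out = ratio / t0[:, None]
    elif input_kind == "ct":
        dct = arr - ref[None, :]
        ddct = dct - dct[:, [table.columns.get_loc(t0_sample)]]
        out = 2.0 ** (-ddct)
    else:
        raise ValueError("input_kind must be 'expression' or 'ct'")
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def run_timecourse_analysis(
    cm: CountMatrix,
    params: FilterParams = FilterParams(),
    n_clusters: int = 12,
    min_correlation: float = 0.5,
) -> dict:
    """Full classification of a normalized count time course.

    Returns a dict with the adjusted matrix, filtered gene index, z-profiles, linkage
    and the per-gene group table.
    """
    treated_cols = cm.columns_for("treated")
    control_cols = cm.columns_for("control")
    treated_times = cm.times_for("treated")
    control_times = cm.times_for("control")
    treated = cm.counts[treated_cols]
    control = cm.counts[control_cols]
    baseline = interpolate_baseline(control, control_times, treated_times)
    baseline.columns = treated_cols
    adjusted = subtract_baseline(treated, baseline)
    t0_col = control_cols[int(np.argmin(control_times))]
    kept = filter_genes(treated, adjusted, cm.counts[t0_col], params)
    z = zscore_profiles(adjusted.loc[kept])
    result = {
        "adjusted": adjusted,
        "filtered_genes": kept,
        "z_profiles": z,
        "treated_times": treated_times,
    }
    if z.shape[0] >= max(n_clusters, 2):
        Z = hcluster(z)
        result["linkage"] = Z
        result["groups"] = assign_groups(Z, z, treated_times, n_clusters, min_correlation)
    return result
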