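"""Condition comparison of single-cell IF intensity distributions via KS distance.

Biological replicates may differ in absolute intensity, so distributions are never
pooled across replicates: within each replicate every condition's empirical CDF is
compared to the reference condition's CDF by the Kolmogorov-Smirnov (sup) distance,
and conditions are then compared across replicates by one-way ANOVA with Tukey HSD
pairwise tests against the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EmpiricalCDF",
    "empirical_cdf",
    "ks_distance",
    "ks_to_reference",
    "test_ks_differences",
    "significance_class",
]

# significance stars at the conventional thresholds
_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class EmpiricalCDF:
    """Right-continuous step CDF of a sample (jumps 1/n at sorted values; ties add)."""

    values: np.ndarray
    marker: str = ""
    condition: str = ""
    replicate: object = None
    n: int = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample contains non-finite values")
        self.values = np.sort(v)
        self.n = v.size

    def __call__(self, x):
        """F(x) = fraction of sample values <= x."""
        xs = np.asarray(x, dtype=float)
        out = np.searchsorted(self.values, xs, side="right") / self.n
        return float(out) if np.isscalar(x) else out


def empirical_cdf(values, **kwargs) -> EmpiricalCDF:
    return EmpiricalCDF(values, **kwargs)


def ks_distance(a: EmpiricalCDF, b: EmpiricalCDF) -> float:
    """sup_x |F_a(x) - F_b(x)| over the merged sample points (and just below them).

    For step CDFs the supremum is attained at a sample point or infinitesimally
    below one; both one-sided evaluations are taken at every merged point.
    """
    if not isinstance(a, EmpiricalCDF):
        a = EmpiricalCDF(a)
    if not isinstance(b, EmpiricalCDF):
        b = EmpiricalCDF(b)
    pts = np.concatenate([a.values, b.values])
    fa_hi = np.searchsorted(a.values, pts, side="right") / a.n
    fb_hi = np.searchsorted(b.values, pts, side="right") / b.n
    fa_lo = np.searchsorted(a.values, pts, side="left") / a.n
    fb_lo = np.searchsorted(b.values, pts, side="left") / b.n
    return float(max(np.max(np.abs(fa_hi - fb_hi)), np.max(np.abs(fa_lo - fb_lo))))


def ks_to_reference(
    samples: pd.DataFrame,
    reference: str,
    value_col: str = "value",
) -> pd.DataFrame:
    """KS distance of every (marker, condition, replicate) sample to the reference CDF.

    ``samples`` is a tidy table with columns ``marker``, ``condition``, ``replicate``
    and ``value_col``. Within each (marker, replicate) the reference condition's
    sample defines the reference CDF; replicates missing the reference are skipped
    with a warning. Samples are never pooled across replicates.
    """
    required = {"marker", "condition", "replicate", value_col}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns {sorted(missing)}")
    if reference not in set(samples["condition"]):
        raise ValueError(f"reference condition {reference!r} not present")
    rows = []
    for (marker, rep), grp in samples.groupby(["marker", "replicate"], sort=True):
        ref_vals = grp.loc[grp["condition"] == reference, value_col].to_numpy()
        if ref_vals.size == 0:
            warnings.warn(
                f"replicate {rep!r} of marker {marker!r} lacks the reference "
                f"condition; skipped"
            )
            continue
        ref_cdf = EmpiricalCDF(ref_vals)
        for cond, sub in grp.groupby("condition", sort=True):
            rows.append(
                {
                    "marker": marker,
                    "condition": cond,
                    "replicate": rep,
                    "n": len(sub),
                    "ks_distance": ks_distance(
                        EmpiricalCDF(sub[value_col].to_numpy()), ref_cdf
                    ),
                }
            )
    out = pd.DataFrame(rows, columns=["marker", "condition", "replicate", "n", "ks_distance"])
    out.attrs["reference"] = reference
    return out


def significance_class(p: float) -> str:
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "n.s."


def test_ks_differences(ks_table: pd.DataFrame, reference: str | None = None) -> dict:
    """Per-marker one-way ANOVA on replicate KS distances, plus Tukey HSD vs reference.

    Returns ``{marker: {"anova_F", "anova_p", "conditions": {condition:
    {"mean_ks", "n_replicates", "p_vs_reference", "class"}}}}``. With fewer than two
    replicates per condition only descriptive output is produced (no test).
    """
    reference = reference or ks_table.attrs.get("reference")
    if reference is None:
        raise ValueError("reference condition required")
    out = {}
    for marker, grp in ks_table.groupby("marker", sort=True):
        conds = sorted(grp["condition"].unique())
        by_cond = {c: grp.loc[grp["condition"] == c, "ks_distance"].to_numpy()
                   for c in conds}
        entry = {
            "conditions": {
                c: {"mean_ks": float(v.mean()), "n_replicates": int(v.size)}
                for c, v in by_cond.items()
            }
        }
        testable = (
            len(conds) >= 2
            and all(v.size >= 2 for v in by_cond.values())
            and reference in by_cond
        )
        if testable:
            values = [by_cond[c] for c in conds]
            if max(v.max() for v in values) - min(v.min() for v in values) == 0:
                entry["anova_F"], entry["anova_p"] = 0.0, 1.0
                for c in conds:
                    entry["conditions"][c]["p_vs_reference"] = 1.0
                    entry["conditions"][c]["class"] = "n.s."
            else:
                F, p = stats.f_oneway(*values)
                entry["anova_F"], entry["anova_p"] = float(F), float(p)
                tukey = stats.tukey_hsd(*values)
                i_ref = conds.index(reference)
                for i, c in enumerate(conds):
                    p_pair = 1.0 if i == i_ref else float(tukey.pvalue[i, i_ref])
                    entry["conditions"][c]["p_vs_reference"] = p_pair
                    entry["conditions"][c]["class"] = (
                        "n.s." if i == i_ref else significance_class(p_pair)
                    )
        else:
            entry["anova_F"] = None
            entry["anova_p"] = None
        out[marker] = entry
    return out
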