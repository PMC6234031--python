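"""Trajectory summarization, stable-vs-adaptive classification, and dose-response fits.

A population trajectory is reduced to four features: the pre-stimulus baseline, the
peak of the mean curve after stimulation, the peak time, and the post-stimulation
baseline (mean readout at more than ``t_post_offset`` hours — 8 by default — after
ligand addition). The adaptation index

    (peak - post_baseline) / (peak - pre_baseline), clipped to [0, 1],

is 0 for a sustained (stable) response and 1 for a fully relaxing pulse; responses
with index >= 0.5 are classified adaptive. Dose dependence of any feature is
summarized by a Hill fit ``floor + A c^h / (K^h + c^h)`` with the floor fixed at the
zero-dose response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import Trajectory

__all__ = [
    "TrajectorySummary",
    "HillFit",
    "summarize_trajectory",
    "classify_dynamics",
    "fit_hill",
    "compare_trajectories",
]


@dataclass
class TrajectorySummary:
    pre_baseline: float = np.nan
    peak: float = np.nan
    t_peak: float = np.nan
    post_baseline: float = np.nan
    adaptation_index: float = np.nan
    valid: bool = True
    reason: str = ""

    def as_dict(self) -> dict:
        return {
            "pre_baseline": self.pre_baseline,
            "peak": self.peak,
            "t_peak": self.t_peak,
            "post_baseline": self.post_baseline,
            "adaptation_index": self.adaptation_index,
            "valid": self.valid,
            "reason": self.reason,
        }


@dataclass
class HillFit:
    amplitude_max: float
    K_half: float
    hill_h: float
    floor: float
    residual: float

    def __post_init__(self):
        if self.K_half <= 0 or self.hill_h <= 0:
            raise ValueError("K_half and hill_h must be positive")

    def __call__(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.floor + self.amplitude_max * dose**self.hill_h / (
            self.K_half**self.hill_h + dose**self.hill_h
        )


def summarize_trajectory(
    traj: Trajectory,
    t_stim: float,
    t_post_offset: float = 8.0,
    smooth: bool = False,
) -> TrajectorySummary:
    """Dynamic features of a population mean curve.

    Requires at least one pre-stimulus point and coverage beyond
    ``t_stim + t_post_offset`` (else an invalid summary with a reason is returned).
    The peak is taken on the raw mean curve; ``smooth=True`` applies 3-point median
    smoothing first for noisy inputs. A degenerate flat trajectory gets adaptation
    index 0 (a non-response is not adaptive).
    """
    t = traj.times_hr
    y = traj.mean.astype(float)
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if not np.any(t < t_stim):
        return TrajectorySummary(valid=False, reason="no pre-stimulus time point")
    if t.size == 0 or t.max() <= t_stim + t_post_offset:
        return TrajectorySummary(
            valid=False, reason=f"trajectory does not span t_stim + {t_post_offset} hr"
        )
    if smooth and y.size >= 3:
        pad = np.concatenate([y[:1], y, y[-1:]])
        y = np.array([np.median(pad[i:i + 3]) for i in range(y.size)])
    pre = float(y[t < t_stim].mean())
    post_sel = t > t_stim + t_post_offset
    post = float(y[post_sel].mean())
    on = t >= t_stim
    i_peak = int(np.argmax(y[on]))
    peak = float(y[on][i_peak])
    t_peak = float(t[on][i_peak])
    if peak > pre:
        adapt = float(np.clip((peak - post) / (peak - pre), 0.0, 1.0))
    else:
        adapt = 0.0
    return TrajectorySummary(
        pre_baseline=pre, peak=peak, t_peak=t_peak, post_baseline=post,
        adaptation_index=adapt,
    )


def classify_dynamics(summary: TrajectorySummary, adapt_threshold: float = 0.5) -> str:
    """'adaptive' iff the adaptation index reaches the threshold, else 'stable'."""
    if not summary.valid:
        raise ValueError(f"invalid summary: {summary.reason}")
    return "adaptive" if summary.adaptation_index >= adapt_threshold else "stable"


def fit_hill(doses, responses, floor: float | None = None) -> HillFit:
    """Least-squares Hill fit of a dose-response series.

    ``floor`` defaults to the response measured at dose 0 when present, else the
    minimum response. Needs >= 4 distinct positive doses; a flat series is
    unidentifiable and rejected.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must align")
    if len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct doses")
    span = responses.max() - responses.min()
    if span <= 1e-12 * max(abs(responses.max()), 1.0):
        raise ValueError("flat responses: Hill parameters unidentifiable")
    if floor is None:
        at_zero = responses[doses == 0]
        floor = float(at_zero.mean()) if at_zero.size else float(responses.min())
    pos = doses > 0
    d, r = doses[pos], responses[pos]

    def model(c, A, K, h):
        return floor + A * c**h / (K**h + c**h)

    A0 = max(r.max() - floor, 1e-6)
    K0 = float(np.median(d))
    popt, _ = curve_fit(
        model, d, r, p0=[A0, K0, 1.5],
        bounds=([0.0, d.min() / 100.0, 0.1], [10 * A0 + 1.0, d.max() * 100.0, 10.0]),
        maxfev=20000,
    )
    resid = float(np.sqrt(np.mean((model(d, *popt) - r) ** 2)))
    return HillFit(amplitude_max=float(popt[0]), K_half=float(popt[1]),
                   hill_h=float(popt[2]), floor=float(floor), residual=resid)


def compare_trajectories(
    traj_a: Trajectory,
    traj_b: Trajectory,
    t_stim: float | None = None,
    t_post_offset: float = 8.0,
) -> dict:
    """Symmetric difference metrics between two trajectories.

    Both mean curves are linearly interpolated onto the coarser grid restricted to
    the overlapping time range. Returns RMS and max absolute differences, and —
    when ``t_stim`` is given and both summaries are valid — per-feature deltas
    (b minus a).
    """
    lo = max(traj_a.times_hr.min(), traj_b.times_hr.min())
    hi = min(traj_a.times_hr.max(), traj_b.times_hr.max())
    if hi <= lo:
        raise ValueError("trajectories do not overlap in time")
    coarse = traj_a if len(traj_a.times_hr) <= len(traj_b.times_hr) else traj_b
    grid = coarse.times_hr[(coarse.times_hr >= lo) & (coarse.times_hr <= hi)]
    ya = np.interp(grid, traj_a.times_hr, traj_a.mean)
    yb = np.interp(grid, traj_b.times_hr, traj_b.mean)
    diff = yb - ya
    out = {
        "rms_difference": float(np.sqrt(np.mean(diff**2))),
        "max_difference": float(np.max(np.abs(diff))),
        "n_grid": int(len(grid)),
    }
    if t_stim is not None:
        sa = summarize_trajectory(traj_a, t_stim, t_post_offset)
        sb = summarize_trajectory(traj_b, t_stim, t_post_offset)
        if sa.valid and sb.valid:
            out["feature_deltas"] = {
                k: getattr(sb, k) - getattr(sa, k)
                for k in ("pre_baseline", "peak", "t_peak", "post_baseline",
                          "adaptation_index")
            }
    return out
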