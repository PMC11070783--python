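"""Hind-leg opening angle and its relation to immobility.

A relaxed, folded hind-leg posture accompanies the sleep-like state in
crickets.  The posture proxy is the unsigned planar angle at the abdomen
vertex between the two hind-leg keypoints::

    theta = arccos( u . v / (|u| |v|) ),  u = left - abdomen, v = right - abdomen

in degrees, range [0, 180].  The angle is invariant to translation, rotation
and uniform scaling of the three points, and is only defined on frames where
all three contributing keypoints were observed directly (not imputed) — a
filled-in coordinate carries no shape information.

The per-animal angle distribution is trimmed at the 2.5th and 97.5th
percentiles (postures such as legs brought to the mouth produce extreme
values), checked for normality (Shapiro–Wilk, Kolmogorov–Smirnov, Q-Q
points), and then related to the sleep-like state two ways: hourly mean angle
against hourly mean SLS count, and mean angle as a function of current
immobility duration (0..20 min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DegenerateGeometryError
from .io import DAY_MIN, RecordingConfig, TrackTable
from .rhythm import linear_regression


def hind_leg_angle(abdomen, left, right) -> float:
    """Angle (degrees) at the abdomen between the two hind-leg keypoints."""
    a = np.asarray(abdomen, dtype=float)
    u = np.asarray(left, dtype=float) - a
    v = np.asarray(right, dtype=float) - a
    nu = np.hypot(*u)
    nv = np.hypot(*v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("hind-leg keypoint coincides with abdomen")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _angles_vectorised(abdomen: np.ndarray, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    u = left - abdomen
    v = right - abdomen
    nu = np.hypot(u[:, 0], u[:, 1])
    nv = np.hypot(v[:, 0], v[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.degrees(np.arccos(c))
    theta[(nu == 0) | (nv == 0)] = np.nan
    return theta


@dataclass
class AngleSeries:
    """Per-frame hind-leg opening angle with an outlier mask.

    ``theta`` is NaN where any contributing keypoint is missing or imputed;
    ``outlier_mask`` is True for trimmed frames (see :func:`trim_outliers`);
    a retained angle is one that is defined and not an outlier.
    """

    t: np.ndarray
    theta: np.ndarray
    outlier_mask: np.ndarray
    trim_quantiles: tuple[float, float] = (2.5, 97.5)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.theta)

    @property
    def retained(self) -> np.ndarray:
        return self.defined & ~self.outlier_mask

    def retained_values(self) -> np.ndarray:
        return self.theta[self.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "theta_deg": self.theta, "outlier": self.outlier_mask.astype(int)}
        )


def compute_angle_series(track: TrackTable, include_imputed: bool = False) -> AngleSeries:
    """Hind-leg angle per frame from the abdomen and hind-leg keypoints.

    Frames where any of the three keypoints is imputed are marked undefined
    unless ``include_imputed`` is set (shape statistics should not be built
    from filled-in coordinates).
    """
    abdomen = track.xy("abdomen")
    left = track.xy("left_hind_leg")
    right = track.xy("right_hind_leg")
    theta = _angles_vectorised(abdomen, left, right)
    if not include_imputed:
        imputed_any = (
            track.is_imputed("abdomen")
            | track.is_imputed("left_hind_leg")
            | track.is_imputed("right_hind_leg")
        )
        theta = theta.copy()
        theta[imputed_any] = np.nan
    return AngleSeries(
        t=track.t, theta=theta, outlier_mask=np.zeros(len(theta), dtype=bool)
    )


def trim_outliers(
    angles: AngleSeries, lower_pct: float = 2.5, upper_pct: float = 97.5
) -> AngleSeries:
    """Mark the extreme tails of the per-animal angle distribution as outliers.

    Angles strictly below the ``lower_pct`` or strictly above the
    ``upper_pct`` percentile (linear-interpolation percentiles of all defined
    angles over the whole recording) are flagged; roughly 95% of defined
    angles are retained.
    """
    defined = angles.defined
    values = angles.theta[defined]
    if len(values) < 40:
        raise DegenerateDataError(
            f"need >= 40 defined angles to trim {lower_pct}/{upper_pct}% tails, "
            f"got {len(values)}"
        )
    lo, hi = np.percentile(values, [lower_pct, upper_pct])
    mask = np.zeros_like(angles.outlier_mask)
    mask[defined] = (values < lo) | (values > hi)
    return AngleSeries(
        t=angles.t,
        theta=angles.theta,
        outlier_mask=mask,
        trim_quantiles=(lower_pct, upper_pct),
    )


def normality_check(values) -> dict:
    """Shapiro–Wilk and Kolmogorov–Smirnov normality diagnostics plus Q-Q points.

    The KS test compares against a normal with the sample mean and standard
    deviation.  Returns ``shapiro_p``, ``ks_p`` and ``qq`` (theoretical,
    ordered-sample quantile pairs); a constant sample is reported as
    degenerate with NaN p-values rather than raising.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise DegenerateDataError("need at least 3 values for normality tests")
    if np.ptp(x) == 0:
        return {
            "shapiro_p": float("nan"),
            "ks_p": float("nan"),
            "qq": None,
            "degenerate": True,
            "n": int(len(x)),
        }
    sw = stats.shapiro(x)
    ks = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    (theoretical, ordered), _ = stats.probplot(x, dist="norm")
    return {
        "shapiro_p": float(sw.pvalue),
        "ks_p": float(ks.pvalue),
        "qq": np.column_stack([theoretical, ordered]),
        "degenerate": False,
        "n": int(len(x)),
    }


# ---------------------------------------------------------------------------
# Angle vs Zeitgeber time and vs immobility
# ---------------------------------------------------------------------------


def angle_by_zt_hour(
    angles: AngleSeries, config: RecordingConfig
) -> tuple[pd.DataFrame, dict]:
    """Mean retained angle per ZT hour (24 rows) and 12-h light/dark means.

    Hours with no retained angle get NaN, never zero.
    """
    retained = angles.retained
    zt = config.zt(angles.t)
    hour = (zt // 60).astype(int)
    table = []
    for h in range(24):
        sel = retained & (hour == h)
        table.append(
            {
                "zt_hour": h,
                "mean_angle_deg": float(angles.theta[sel].mean()) if sel.any() else float("nan"),
                "n": int(sel.sum()),
            }
        )
    df = pd.DataFrame(table)
    light_sel = retained & (zt < config.light_min)
    dark_sel = retained & (zt >= config.light_min)
    halves = {
        "light_mean_deg": float(angles.theta[light_sel].mean()) if light_sel.any() else float("nan"),
        "dark_mean_deg": float(angles.theta[dark_sel].mean()) if dark_sel.any() else float("nan"),
    }
    return df, halves


def angle_vs_sls_hourly(angle_hourly: pd.DataFrame, sls_hourly: pd.DataFrame) -> dict:
    """OLS of hourly mean angle (y) on hourly mean SLS count (x), 24 points.

    ``angle_hourly`` comes from :func:`angle_by_zt_hour`; ``sls_hourly`` from
    :func:`gryllometry.rhythm.mean_per_slot` on the SLS event series.
    """
    x = sls_hourly["mean"].to_numpy(dtype=float)
    y = angle_hourly["mean_angle_deg"].to_numpy(dtype=float)
    return linear_regression(x, y)


def angle_by_immobility_duration(
    angles: AngleSeries,
    runlength: np.ndarray,
    max_d: int = 20,
    mode: str = "pool",
) -> tuple[pd.DataFrame, dict]:
    """Mean retained angle per current immobility duration d = 0..max_d, plus OLS.

    A frame's immobility duration is the number of consecutive immobile frame
    pairs ending at that frame (the first frame has d = 0).  Durations above
    ``max_d`` are pooled into the ``max_d`` bin (``mode='pool'``) or dropped
    (``mode='drop'``).  The regression fits mean angle on d over the observed
    bins.
    """
    if mode not in {"pool", "drop"}:
        raise ValueError("mode must be 'pool' or 'drop'")
    runlength = np.asarray(runlength)
    # pair i ends at frame i+1; frame 0 has no preceding pair
    d_frame = np.concatenate([[0], runlength])
    if len(d_frame) != len(angles.theta):
        raise ValueError(
            "runlength must have one entry per frame pair (n_frames - 1)"
        )
    retained = angles.retained
    if mode == "pool":
        d_eff = np.minimum(d_frame, max_d)
        keep = retained
    else:
        d_eff = d_frame
        keep = retained & (d_frame <= max_d)
    rows = []
    for d in range(max_d + 1):
        sel = keep & (d_eff == d)
        rows.append(
            {
                "immobility_min": d,
                "mean_angle_deg": float(angles.theta[sel].mean()) if sel.any() else float("nan"),
                "n": int(sel.sum()),
            }
        )
    df = pd.DataFrame(rows)
    ok = np.isfinite(df["mean_angle_deg"].to_numpy())
    reg = linear_regression(
        df["immobility_min"].to_numpy()[ok], df["mean_angle_deg"].to_numpy()[ok]
    )
    return df, reg
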