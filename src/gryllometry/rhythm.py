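"""Circadian rhythm analysis of per-minute behavioural event series.

Implements the standard actigraphy toolkit for an entrained LD 12:12
recording: Zeitgeber-time slot averaging, double-plotted actogram matrices,
the Sokolove–Bushell chi-square periodogram, the classical normalized
Lomb–Scargle periodogram, the count-weighted circular-mean acrophase, and the
light/dark Student's t-test.

Chi-square periodogram
----------------------
For a candidate period ``P`` (minutes) the first ``K*P`` samples
(``K = floor(N/P)``) are folded into a K x P array with column means ``M_h``
and grand mean ``M``.  With ``s^2`` the population variance of the folded
samples, the statistic is::

    Q_P = K * sum_h (M_h - M)^2 / s^2

which under the null of no rhythm is approximately chi-square with ``P - 1``
degrees of freedom.  Significance across the scanned period grid uses a
Bonferroni-corrected alpha by default (a "pointwise" mode reproduces the
classic single-period test).

Lomb–Scargle periodogram
------------------------
The classical normalized power ``z = P_LS / s^2`` (mean subtracted, sample
variance with ``ddof=1``) evaluated on the scanned period grid; the peak's
false-alarm probability is ``1 - (1 - exp(-z))^M`` with ``M`` the number of
scanned frequencies.  That correction is calibrated when the scanned
frequencies are approximately independent (spacing >= 1/T); a finely
oversampled grid makes it conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .io import DAY_MIN, RecordingConfig

# ---------------------------------------------------------------------------
# Event series
# ---------------------------------------------------------------------------


@dataclass
class EventSeries:
    """Per-minute event counts for one behaviour of one animal.

    ``values[i]`` is the count in minute ``i``; ``t0_zt`` is the Zeitgeber
    Time (minutes) of the first sample.
    """

    values: np.ndarray
    t0_zt: int = 0
    frame_interval_min: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("event counts must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def zt(self) -> np.ndarray:
        """Zeitgeber Time of each sample, minutes in [0, 1440)."""
        idx = np.arange(len(self.values)) * self.frame_interval_min
        return (self.t0_zt + idx) % DAY_MIN


def _as_series(series) -> EventSeries:
    if isinstance(series, EventSeries):
        return series
    return EventSeries(np.asarray(series, dtype=float))


def _daily_matrix(series: EventSeries, truncate: bool = False) -> np.ndarray:
    """Reshape to (days, 1440) aligned so that column 0 is ZT0."""
    s = _as_series(series)
    if s.frame_interval_min != 1:
        raise NotImplementedError("slot averaging assumes 1-min sampling")
    values = s.values
    if s.t0_zt % DAY_MIN != 0:
        lead = DAY_MIN - (s.t0_zt % DAY_MIN)
        if not truncate:
            raise ValueError(
                "series does not start at ZT0; pass truncate=True to drop the "
                "leading partial day"
            )
        values = values[lead:]
    n_days, rem = divmod(len(values), DAY_MIN)
    if rem:
        if not truncate:
            raise ValueError(
                f"series length {len(values)} is not a whole number of days; "
                "pass truncate=True to drop the partial final day"
            )
        values = values[: n_days * DAY_MIN]
    if n_days == 0:
        raise ValueError("series shorter than one day")
    return values.reshape(n_days, DAY_MIN)


def mean_per_slot(series, slot: str = "1h", truncate: bool = False) -> pd.DataFrame:
    """Average event count per ZT slot across days.

    For each slot (24 hourly slots, or the 12-h light/dark halves), event
    counts are summed within the slot for each day and the per-day sums are
    averaged over the recording.  Returns a table with columns
    ``zt_start_min``, ``slot``, ``mean``, ``sd``, ``n_days``.
    """
    slot_min = {"1h": 60, "12h": 720}.get(slot)
    if slot_min is None:
        raise ValueError("slot must be '1h' or '12h'")
    mat = _daily_matrix(series, truncate=truncate)
    n_slots = DAY_MIN // slot_min
    per_day = mat.reshape(mat.shape[0], n_slots, slot_min).sum(axis=2)
    labels = (
        [f"ZT{h:02d}" for h in range(24)]
        if slot == "1h"
        else ["light (ZT0-12)", "dark (ZT12-24)"]
    )
    return pd.DataFrame(
        {
            "zt_start_min": np.arange(n_slots) * slot_min,
            "slot": labels,
            "mean": per_day.mean(axis=0),
            "sd": per_day.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.nan,
            "n_days": mat.shape[0],
        }
    )


def double_plot_matrix(series, truncate: bool = False) -> np.ndarray:
    """Double-plotted actogram matrix: row d = day d followed by day d+1.

    Shape (days, 2880); the second half of the final row is NaN-padded.
    """
    mat = _daily_matrix(series, truncate=truncate)
    n_days = mat.shape[0]
    out = np.full((n_days, 2 * DAY_MIN), np.nan)
    out[:, :DAY_MIN] = mat
    out[:-1, DAY_MIN:] = mat[1:]
    return out


# ---------------------------------------------------------------------------
# Periodograms
# ---------------------------------------------------------------------------


@dataclass
class Periodogram:
    """Rhythm statistic versus candidate period with significance threshold.

    ``statistic[i]`` is Q_P (chi-square) or normalized power z (Lomb–Scargle)
    at ``periods[i]``; ``threshold[i]`` is the pointwise significance cutoff
    at the (possibly corrected) alpha.  ``peak_period`` is the period of the
    maximal statistic among significant periods when any exists, else the
    overall argmax with ``significant=False``.
    """

    method: str
    periods: np.ndarray
    statistic: np.ndarray
    threshold: np.ndarray
    alpha: float
    correction: str
    peak_period: float
    peak_statistic: float
    significant: bool
    peak_p_value: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period_min": self.periods,
                "statistic": self.statistic,
                "threshold": self.threshold,
                "significant": self.statistic > self.threshold,
            }
        )


def chi_square_periodogram(
    series,
    p_min: int = 1200,
    p_max: int = 1680,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> Periodogram:
    """Sokolove–Bushell chi-square periodogram over integer periods (minutes).

    ``correction='bonferroni'`` (default) tests each period at
    ``alpha / n_periods``; ``'pointwise'`` tests each at ``alpha`` as classic
    actogram software does.
    """
    s = _as_series(series)
    x = s.values
    n = len(x)
    if 2 * p_max > n:
        raise ValueError(
            f"series too short ({n}) to test periods up to {p_max} (need >= 2*p_max)"
        )
    if np.var(x) == 0:
        raise DegenerateDataError("constant series")
    if correction not in {"bonferroni", "pointwise"}:
        raise ValueError("correction must be 'bonferroni' or 'pointwise'")

    periods = np.arange(int(p_min), int(p_max) + 1)
    m = len(periods)
    alpha_eff = alpha / m if correction == "bonferroni" else alpha
    q = np.empty(m)
    thr = np.empty(m)
    for i, p in enumerate(periods):
        k = n // p
        folded = x[: k * p].reshape(k, p)
        col_means = folded.mean(axis=0)
        grand = folded.mean()
        s2 = folded.var()  # population variance over the K*P folded samples
        q[i] = k * np.sum((col_means - grand) ** 2) / s2
        thr[i] = stats.chi2.ppf(1 - alpha_eff, df=p - 1)

    sig = q > thr
    if sig.any():
        idx = np.flatnonzero(sig)[np.argmax(q[sig])]
        significant = True
    else:
        idx = int(np.argmax(q))
        significant = False
    k_peak = n // periods[idx]
    p_val = float(stats.chi2.sf(q[idx], df=periods[idx] - 1))
    return Periodogram(
        method="chi_square",
        periods=periods,
        statistic=q,
        threshold=thr,
        alpha=alpha,
        correction=correction,
        peak_period=float(periods[idx]),
        peak_statistic=float(q[idx]),
        significant=bool(significant),
        peak_p_value=p_val,
    )


def lomb_power(t: np.ndarray, y: np.ndarray, ang_freqs: np.ndarray,
               chunk: int = 64) -> np.ndarray:
    """Unnormalized Lomb periodogram P(omega) with the phase-offset tau.

    Classical least-squares power at each angular frequency::

        tan(2*omega*tau) = sum sin(2*omega*t) / sum cos(2*omega*t)
        P = 0.5 * [ (sum y*cos(omega*(t-tau)))^2 / sum cos^2(omega*(t-tau))
                  + (sum y*sin(omega*(t-tau)))^2 / sum sin^2(omega*(t-tau)) ]

    ``y`` is used as given (subtract the mean first for the standard
    mean-removed power).  Vectorised over frequencies in chunks to bound the
    memory of the trig tables.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ang_freqs = np.asarray(ang_freqs, dtype=float)
    out = np.empty(len(ang_freqs))
    for i0 in range(0, len(ang_freqs), chunk):
        w = ang_freqs[i0 : i0 + chunk][:, None]  # (m, 1)
        wt = w * t[None, :]
        c = np.cos(wt)
        s = np.sin(wt)
        # double-angle sums for tau without extra trig evaluations
        sin2 = 2.0 * (s * c).sum(axis=1)
        cos2 = (c * c - s * s).sum(axis=1)
        tau = 0.5 * np.arctan2(sin2, cos2) / w[:, 0]
        cw = np.cos(w[:, 0, None] * tau[:, None])
        sw = np.sin(w[:, 0, None] * tau[:, None])
        # cos(w(t-tau)) = cos(wt)cos(w tau) + sin(wt)sin(w tau)
        ct = c * cw + s * sw
        st = s * cw - c * sw
        yc = (y[None, :] * ct).sum(axis=1)
        ys = (y[None, :] * st).sum(axis=1)
        cc = (ct * ct).sum(axis=1)
        ss = (st * st).sum(axis=1)
        out[i0 : i0 + chunk] = 0.5 * (yc**2 / cc + ys**2 / ss)
    return out


def lomb_scargle_periodogram(
    series,
    p_min: float = 1200,
    p_max: float = 1680,
    alpha: float = 0.05,
    periods: np.ndarray | None = None,
    grid_step_min: float = 1.0,
) -> Periodogram:
    """Classical normalized Lomb–Scargle periodogram over a period grid.

    Power is normalized by the sample variance (``z = P_LS / s^2``); the
    peak's false-alarm probability ``1 - (1 - e^{-z})^M`` uses ``M`` = number
    of scanned frequencies, which is well calibrated only when the scanned
    frequencies are close to independent (spacing of order 1/T).
    """
    s = _as_series(series)
    x = s.values
    n = len(x)
    var = np.var(x, ddof=1)
    if var == 0:
        raise DegenerateDataError("constant series")
    if periods is None:
        periods = np.arange(p_min, p_max + grid_step_min / 2, grid_step_min)
    periods = np.asarray(periods, dtype=float)
    t = np.arange(n, dtype=float) * s.frame_interval_min
    y = x - x.mean()
    ang_freqs = 2 * np.pi / periods
    power = lomb_power(t, y, ang_freqs)
    z = power / var
    m = len(periods)
    # peak false-alarm probability and the matching pointwise z threshold
    z_thr = -np.log1p(-((1 - alpha) ** (1.0 / m)))
    idx = int(np.argmax(z))
    with np.errstate(over="ignore"):
        p_val = float(-np.expm1(m * np.log1p(-np.exp(-z[idx]))))
    p_val = min(max(p_val, 0.0), 1.0)
    return Periodogram(
        method="lomb_scargle",
        periods=periods,
        statistic=z,
        threshold=np.full(m, z_thr),
        alpha=alpha,
        correction="sidak_m_frequencies",
        peak_period=float(periods[idx]),
        peak_statistic=float(z[idx]),
        significant=bool(z[idx] > z_thr),
        peak_p_value=p_val,
    )


# ---------------------------------------------------------------------------
# Acrophase
# ---------------------------------------------------------------------------


@dataclass
class AcrophaseResult:
    """Count-weighted circular mean phase of an event series.

    ``acrophase_zt`` in minutes of Zeitgeber Time in [0, 1440);
    ``resultant_length`` r in [0, 1] measures phase concentration; ``defined``
    is False for (near-)uniform event distributions (r ~ 0).
    ``per_day_zt`` holds one acrophase per recording day where that day has
    events; ``daily_circular_mean_zt`` is their unweighted circular mean.
    """

    acrophase_zt: float
    resultant_length: float
    n_events: float
    defined: bool
    per_day_zt: list[float] | None = None
    daily_circular_mean_zt: float = float("nan")


def _circular_mean_minutes(angles: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    vec = np.sum(w * np.exp(1j * angles)) / total
    phase = (np.angle(vec) % (2 * np.pi)) * DAY_MIN / (2 * np.pi)
    return float(phase % DAY_MIN), float(np.abs(vec))


def acrophase(series, per_day: bool = True) -> AcrophaseResult:
    """Acrophase (peak phase within the 24-h cycle) via the vector method.

    Each minute's count is a vector at angle ``2*pi*ZT/1440``; the acrophase
    is the direction of the resultant, its length r the rhythm concentration.
    """
    s = _as_series(series)
    counts = s.values
    total = counts.sum()
    if total <= 0:
        raise DegenerateDataError("no events: acrophase undefined")
    angles = 2 * np.pi * s.zt / DAY_MIN
    phase, r = _circular_mean_minutes(angles, counts)
    defined = r >= 1e-9
    per_day_zt = None
    daily_mean = float("nan")
    if per_day and len(s) >= DAY_MIN and s.t0_zt % DAY_MIN == 0:
        try:
            mat = _daily_matrix(s, truncate=True)
        except ValueError:
            mat = None
        if mat is not None:
            day_angles = 2 * np.pi * np.arange(DAY_MIN) / DAY_MIN
            per_day_zt = []
            for row in mat:
                if row.sum() > 0:
                    ph, rr = _circular_mean_minutes(day_angles, row)
                    if rr >= 1e-9:
                        per_day_zt.append(ph)
            if per_day_zt:
                daily_mean, _ = _circular_mean_minutes(
                    np.asarray(per_day_zt) * 2 * np.pi / DAY_MIN,
                    np.ones(len(per_day_zt)),
                )
    return AcrophaseResult(
        acrophase_zt=phase if defined else float("nan"),
        resultant_length=r,
        n_events=float(total),
        defined=bool(defined),
        per_day_zt=per_day_zt,
        daily_circular_mean_zt=daily_mean,
    )


# ---------------------------------------------------------------------------
# Light/dark contrast and regression
# ---------------------------------------------------------------------------


def light_dark_ttest(series, config: RecordingConfig | None = None) -> dict:
    """Student's t-test of daily dark-phase totals versus light-phase totals.

    The unit of replication is the day within one animal: each recorded day
    contributes one light-phase and one dark-phase event total, compared with
    a two-sample pooled-variance (Student's) t-test, two-sided.
    """
    s = _as_series(series)
    mat = _daily_matrix(s)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 days for the light/dark t-test")
    light_min = config.light_min if config is not None else DAY_MIN // 2
    light_totals = mat[:, :light_min].sum(axis=1)
    dark_totals = mat[:, light_min:].sum(axis=1)
    if np.var(light_totals, ddof=1) == 0 and np.var(dark_totals, ddof=1) == 0:
        if light_totals.mean() == dark_totals.mean():
            t_stat, p = 0.0, 1.0
        else:
            raise DegenerateDataError(
                "zero variance in both phases with unequal means: t undefined"
            )
    else:
        t_stat, p = stats.ttest_ind(dark_totals, light_totals, equal_var=True)
    return {
        "t": float(t_stat),
        "p": float(p),
        "mean_dark": float(dark_totals.mean()),
        "mean_light": float(light_totals.mean()),
        "n_days": int(mat.shape[0]),
    }


def linear_regression(x, y) -> dict:
    """Ordinary least squares of y on x with R^2 and the two-sided slope p.

    The p-value is the t-test of zero slope with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DegenerateDataError("need at least 3 points for regression")
    if np.var(x) == 0:
        raise DegenerateDataError("x has zero variance")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p": float(res.pvalue),
        "stderr": float(res.stderr),
        "n": int(len(x)),
    }
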