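"""Pose-table I/O, likelihood-based quality filtering, and imputation.

The pipeline's raw input is a DeepLabCut-dialect pose table: one row per video
frame, a three-level column header (scorer / bodyparts / coords) and, for each
tracked bodypart, an ``x``/``y`` pixel coordinate plus a network confidence
``likelihood`` in ``[0, 1]``.  Recordings are time-lapse at one frame per
minute, one animal per file.

Coordinates whose likelihood falls below a threshold (default 0.95) are
treated as missing and filled by *flanking-mean imputation*: every missing run
is replaced by the arithmetic mean of the nearest preceding and nearest
following valid coordinate; runs touching the start or end of the recording
take the single nearest valid value.  Linear interpolation is available as an
explicit alternative.

Conventions: image pixel coordinates with the origin at the top-left corner
and y increasing downward; 0-based frame index; timestamps in minutes since
recording start.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from .errors import (
    ConfigurationError,
    FormatError,
    PoseParseError,
    UnrecoverableTrackError,
)

#: Canonical bodyparts tracked on a single cricket, in canonical order.
BODYPARTS = (
    "head",
    "thorax",
    "abdomen",
    "abdominal_tip",
    "left_hind_leg",
    "right_hind_leg",
)

COORDS = ("x", "y", "likelihood")

#: Minutes in one circadian day.
DAY_MIN = 1440

_NAME_ALIASES = {
    "abdominaltip": "abdominal_tip",
    "abdomen_tip": "abdominal_tip",
    "lefthindleg": "left_hind_leg",
    "left_hindleg": "left_hind_leg",
    "righthindleg": "right_hind_leg",
    "right_hindleg": "right_hind_leg",
}


def _canonical_bodypart(name: str) -> str:
    key = str(name).strip().lower().replace(" ", "_").replace("-", "_")
    return _NAME_ALIASES.get(key, _NAME_ALIASES.get(key.replace("_", ""), key))


# ---------------------------------------------------------------------------
# Recording configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedingSegment:
    """Feeding-area geometry valid for the half-open time span [start_t, end_t).

    The area is either an axis-aligned rectangle ``(x0, y0, x1, y1)`` or a
    polygon given as a vertex sequence; containment is boundary-inclusive.
    """

    start_t: int
    end_t: int
    area: tuple

    def __post_init__(self):
        if self.end_t <= self.start_t:
            raise ConfigurationError(
                f"feeding segment span [{self.start_t}, {self.end_t}) is empty"
            )

    @property
    def is_rectangle(self) -> bool:
        return len(self.area) == 4 and np.isscalar(self.area[0])

    def contains(self, x, y):
        """Vectorised boundary-inclusive point-in-area test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.is_rectangle:
            x0, y0, x1, y1 = (float(v) for v in self.area)
            x0, x1 = min(x0, x1), max(x0, x1)
            y0, y1 = min(y0, y1), max(y0, y1)
            return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        poly = Polygon(self.area)
        flat_x = np.atleast_1d(x).ravel()
        flat_y = np.atleast_1d(y).ravel()
        out = np.fromiter(
            (poly.intersects(Point(px, py)) for px, py in zip(flat_x, flat_y)),
            dtype=bool,
            count=flat_x.size,
        )
        return out.reshape(np.shape(x)) if np.ndim(x) else bool(out[0])


@dataclass
class RecordingConfig:
    """Recording design: light schedule, arena and feeding-area geometry.

    Parameters
    ----------
    lights_on_clock_min : wall-clock minutes-of-day at which lights turn on
        (bookkeeping only; analyses work in Zeitgeber Time).
    light_min, dark_min : photoperiod in minutes; must sum to 1440 (LD cycle).
    recording_days : length of the recording in days.
    start_zt_min : Zeitgeber Time of the first frame (ZT0 = lights-on).
    feeding_segments : feeding-area geometry per time segment; segments must
        tile the recording span without gaps or overlap.
    arena_size : (width, height) of the cropped arena in pixels.
    likelihood_threshold : pose-confidence cutoff below which a coordinate is
        treated as missing.
    frame_interval_min : sampling interval in minutes.
    """

    lights_on_clock_min: int = 360
    light_min: int = 720
    dark_min: int = 720
    recording_days: int = 14
    start_zt_min: int = 0
    feeding_segments: list[FeedingSegment] = field(default_factory=list)
    arena_size: tuple[float, float] = (735.0, 490.0)
    likelihood_threshold: float = 0.95
    frame_interval_min: int = 1

    def __post_init__(self):
        if self.light_min + self.dark_min != DAY_MIN:
            raise ConfigurationError(
                f"photoperiod must sum to {DAY_MIN} min, got "
                f"{self.light_min}+{self.dark_min}"
            )
        if not (0 < self.likelihood_threshold <= 1):
            raise ConfigurationError("likelihood_threshold must be in (0, 1]")
        self.feeding_segments = [
            fs if isinstance(fs, FeedingSegment) else FeedingSegment(**fs)
            for fs in self.feeding_segments
        ]
        segs = sorted(self.feeding_segments, key=lambda s: s.start_t)
        for a, b in zip(segs, segs[1:]):
            if b.start_t < a.end_t:
                raise ConfigurationError(
                    f"feeding segments overlap at t={b.start_t}"
                )
        self.feeding_segments = segs

    @property
    def total_min(self) -> int:
        return self.recording_days * DAY_MIN

    def zt(self, t):
        """Zeitgeber Time (minutes in [0, 1440)) of recording time ``t``."""
        return (np.asarray(t) + self.start_zt_min) % DAY_MIN

    def is_light(self, t):
        """True where frame time ``t`` falls in the light phase (ZT < light_min)."""
        return self.zt(t) < self.light_min

    def feeding_segment_at(self, t: float) -> FeedingSegment:
        for seg in self.feeding_segments:
            if seg.start_t <= t < seg.end_t:
                return seg
        raise ConfigurationError(f"no feeding segment covers t={t}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lights_on_clock_min": self.lights_on_clock_min,
            "light_min": self.light_min,
            "dark_min": self.dark_min,
            "recording_days": self.recording_days,
            "start_zt_min": self.start_zt_min,
            "feeding_segments": [
                {
                    "start_t": s.start_t,
                    "end_t": s.end_t,
                    "area": [list(v) if isinstance(v, (tuple, list)) else v for v in s.area],
                }
                for s in self.feeding_segments
            ],
            "arena_size": list(self.arena_size),
            "likelihood_threshold": self.likelihood_threshold,
            "frame_interval_min": self.frame_interval_min,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingConfig":
        d = dict(d)
        if "arena_size" in d:
            d["arena_size"] = tuple(d["arena_size"])
        segs = []
        for s in d.get("feeding_segments", []):
            area = s["area"]
            area = tuple(tuple(v) if isinstance(v, list) else v for v in area)
            segs.append(FeedingSegment(int(s["start_t"]), int(s["end_t"]), area))
        d["feeding_segments"] = segs
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RecordingConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# TrackTable
# ---------------------------------------------------------------------------


@dataclass
class TrackTable:
    """Time-indexed (x, y, likelihood) per bodypart for a single animal.

    ``data`` has a three-level column MultiIndex (scorer, bodypart, coord) and
    an integer index of minutes since recording start.  Missing coordinates
    (removed by the likelihood filter) are NaN.  ``imputed`` is a boolean
    frame (index t, columns bodyparts) marking coordinates filled in by
    :func:`impute_missing`; it is None before imputation.
    """

    data: pd.DataFrame
    animal_id: str = "animal0"
    frame_interval_min: int = 1
    imputed: pd.DataFrame | None = None

    def __post_init__(self):
        t = np.asarray(self.data.index)
        if len(t) > 1:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise FormatError("timestamps must be strictly increasing")
            if not np.all(steps == self.frame_interval_min):
                raise FormatError(
                    "timestamps must advance by the frame interval "
                    f"({self.frame_interval_min} min)"
                )
        lik = self.data.xs("likelihood", axis=1, level=-1)
        arr = lik.to_numpy(dtype=float)
        valid = arr[np.isfinite(arr)]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise FormatError("likelihood values must lie in [0, 1]")

    @property
    def scorer(self) -> str:
        return str(self.data.columns.get_level_values(0)[0])

    @property
    def bodyparts(self) -> tuple[str, ...]:
        seen: list[str] = []
        for bp in self.data.columns.get_level_values(1):
            if bp not in seen:
                seen.append(bp)
        return tuple(seen)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.data.index)

    def xy(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) float array of x, y for one bodypart (NaN if missing)."""
        sc = self.scorer
        return self.data.loc[:, [(sc, bodypart, "x"), (sc, bodypart, "y")]].to_numpy(
            dtype=float
        )

    def likelihood(self, bodypart: str) -> np.ndarray:
        return self.data[(self.scorer, bodypart, "likelihood")].to_numpy(dtype=float)

    def is_imputed(self, bodypart: str) -> np.ndarray:
        if self.imputed is None:
            return np.zeros(self.n_frames, dtype=bool)
        return self.imputed[bodypart].to_numpy(dtype=bool)

    def copy(self) -> "TrackTable":
        return replace(
            self,
            data=self.data.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        coords: dict[str, np.ndarray],
        likelihoods: dict[str, np.ndarray] | None = None,
        scorer: str = "gryllometry",
        animal_id: str = "animal0",
        frame_interval_min: int = 1,
    ) -> "TrackTable":
        """Build a table from per-bodypart (n, 2) coordinate arrays."""
        n = len(next(iter(coords.values())))
        cols = {}
        for bp in coords:
            xy = np.asarray(coords[bp], dtype=float)
            lik = (
                np.ones(n)
                if likelihoods is None or bp not in likelihoods
                else np.asarray(likelihoods[bp], dtype=float)
            )
            cols[(scorer, bp, "x")] = xy[:, 0]
            cols[(scorer, bp, "y")] = xy[:, 1]
            cols[(scorer, bp, "likelihood")] = lik
        df = pd.DataFrame(cols, index=pd.RangeIndex(n) * frame_interval_min)
        df.columns = pd.MultiIndex.from_tuples(
            df.columns, names=["scorer", "bodyparts", "coords"]
        )
        return cls(df, animal_id=animal_id, frame_interval_min=frame_interval_min)

    # -- output -------------------------------------------------------------

    def to_dlc_csv(self, path) -> None:
        self.data.to_csv(path, index_label=None)

    def to_dlc_hdf(self, path, key: str = "df_with_missing") -> None:
        self.data.to_hdf(path, key=key, mode="w")

    def to_tidy_csv(self, path) -> None:
        """Long-format export: one row per (t, bodypart)."""
        rows = []
        for bp in self.bodyparts:
            xy = self.xy(bp)
            rows.append(
                pd.DataFrame(
                    {
                        "t": self.t,
                        "bodypart": bp,
                        "x": xy[:, 0],
                        "y": xy[:, 1],
                        "likelihood": self.likelihood(bp),
                        "imputed": self.is_imputed(bp).astype(int),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_pose_table(
    source,
    dialect: str = "auto",
    animal_id: str | None = None,
    frame_interval_min: int = 1,
    required_bodyparts: Sequence[str] = BODYPARTS,
) -> TrackTable:
    """Read a DeepLabCut-dialect pose table (CSV or HDF5).

    The CSV dialect has three header rows (scorer / bodyparts / coords) and a
    leading frame-index column; the HDF5 equivalent is a pandas frame with the
    same column MultiIndex.  Bodypart names are normalised to the canonical
    six; extra bodyparts are tolerated with a warning, missing required ones
    raise :class:`FormatError`.  Rows are re-indexed to minutes in file order.
    """
    path = Path(source)
    if dialect == "auto":
        dialect = "hdf5" if path.suffix.lower() in {".h5", ".hdf5", ".hdf"} else "csv"
    if dialect == "hdf5":
        df = pd.read_hdf(path)
    elif dialect == "csv":
        df = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.columns.nlevels != 3:
        raise FormatError(
            "expected a three-level column header (scorer / bodyparts / coords)"
        )

    # normalise bodypart names
    scorer = str(df.columns.get_level_values(0)[0])
    df.columns = pd.MultiIndex.from_tuples(
        [(sc, _canonical_bodypart(bp), str(co).strip().lower()) for sc, bp, co in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    present = set(df.columns.get_level_values(1))
    for bp in required_bodyparts:
        if bp not in present:
            raise FormatError(f"bodypart {bp} absent")
    extras = present - set(required_bodyparts)
    if extras:
        warnings.warn(
            f"ignoring unexpected bodyparts: {sorted(extras)}", stacklevel=2
        )
    # canonical bodypart order, coords x/y/likelihood (drops extras)
    df = df.loc[:, [(scorer, bp, co) for bp in required_bodyparts for co in COORDS]]

    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate timestamp/frame index: {dup!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise PoseParseError(f"non-numeric cell at data row {row}")

    numeric.index = pd.RangeIndex(len(numeric)) * frame_interval_min
    return TrackTable(
        numeric,
        animal_id=animal_id or path.stem,
        frame_interval_min=frame_interval_min,
    )


# ---------------------------------------------------------------------------
# Likelihood filtering and QC
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    """Per-bodypart labelling-quality summary.

    ``fractions`` maps bodypart -> {overall, light, dark} fraction of frames
    with likelihood >= threshold (light/dark are NaN without a config);
    ``imputed_counts`` maps bodypart -> number of missing (to-impute) frames;
    ``missing_run_histogram`` maps run length -> count, pooled over bodyparts.
    """

    threshold: float
    n_frames: int
    n_light: int
    n_dark: int
    fractions: dict[str, dict[str, float]]
    imputed_counts: dict[str, int]
    missing_run_histogram: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bodypart": bp,
                    "frac_overall": f["overall"],
                    "frac_light": f["light"],
                    "frac_dark": f["dark"],
                    "n_missing": self.imputed_counts[bp],
                }
                for bp, f in self.fractions.items()
            ]
        )

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "n_frames": self.n_frames,
            "n_light": self.n_light,
            "n_dark": self.n_dark,
            "fractions": self.fractions,
            "imputed_counts": self.imputed_counts,
            "missing_run_histogram": {
                str(k): v for k, v in sorted(self.missing_run_histogram.items())
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _missing_runs(missing: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, length) of maximal True runs."""
    m = np.asarray(missing, dtype=bool)
    if not m.any():
        return
    padded = np.concatenate(([False], m, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        yield int(s), int(e - s)


def filter_by_likelihood(
    track: TrackTable,
    threshold: float = 0.95,
    config: RecordingConfig | None = None,
) -> tuple[TrackTable, QcReport]:
    """Mark low-confidence coordinates missing and report retention fractions.

    A coordinate pair is removed (set NaN) when its likelihood is *strictly
    below* ``threshold``; ties at the threshold are retained.  The QC report
    gives, per bodypart, the fraction of frames at or above threshold overall
    and split by light/dark phase when a config is supplied.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out = track.copy()
    sc = out.scorer
    n = out.n_frames
    if config is not None:
        light = np.asarray(config.is_light(out.t))
    else:
        light = np.zeros(n, dtype=bool)
    n_light = int(light.sum()) if config is not None else 0
    n_dark = n - n_light if config is not None else 0

    fractions: dict[str, dict[str, float]] = {}
    imputed_counts: dict[str, int] = {}
    hist: dict[int, int] = {}
    for bp in out.bodyparts:
        lik = out.likelihood(bp)
        ok = lik >= threshold
        missing = ~ok
        out.data.loc[missing, [(sc, bp, "x"), (sc, bp, "y")]] = np.nan
        fractions[bp] = {
            "overall": float(ok.mean()),
            "light": float(ok[light].mean()) if config is not None and n_light else float("nan"),
            "dark": float(ok[~light].mean()) if config is not None and n_dark else float("nan"),
        }
        imputed_counts[bp] = int(missing.sum())
        for _, length in _missing_runs(missing):
            hist[length] = hist.get(length, 0) + 1

    report = QcReport(
        threshold=threshold,
        n_frames=n,
        n_light=n_light,
        n_dark=n_dark,
        fractions=fractions,
        imputed_counts=imputed_counts,
        missing_run_histogram=hist,
    )
    return out, report


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_missing(track: TrackTable, method: str = "flanking_mean") -> TrackTable:
    """Fill missing coordinates and return a gap-free track with a mask.

    ``flanking_mean`` (default) replaces each maximal missing run by the mean
    of the nearest valid coordinate before and after the run — a constant fill
    per run; runs at either end of the recording take the single nearest valid
    value.  ``linear`` interpolates linearly across runs instead.  Likelihood
    values are left untouched; imputed frames are flagged in the returned
    track's ``imputed`` mask.
    """
    if method not in {"flanking_mean", "linear"}:
        raise ValueError(f"unknown imputation method {method!r}")
    out = track.copy()
    sc = out.scorer
    mask = pd.DataFrame(
        False, index=out.data.index, columns=list(out.bodyparts), dtype=bool
    )
    for bp in out.bodyparts:
        xy_cols = [(sc, bp, "x"), (sc, bp, "y")]
        sub = out.data.loc[:, xy_cols]
        missing = sub.isna().any(axis=1).to_numpy()
        if not missing.any():
            continue
        if missing.all():
            raise UnrecoverableTrackError(
                f"bodypart {bp} has no valid observations"
            )
        if method == "flanking_mean":
            fwd = sub.ffill()
            bwd = sub.bfill()
            both = (fwd + bwd) / 2.0
            filled = both.where(fwd.notna() & bwd.notna(), fwd.where(fwd.notna(), bwd))
        else:
            filled = sub.interpolate(method="linear", limit_direction="both")
        out.data.loc[:, xy_cols] = filled
        mask[bp] = missing
    out.imputed = mask
    return out
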