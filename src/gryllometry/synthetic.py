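"""Seeded simulator of single-cricket keypoint trajectories with ground truth.

Emulates a 14-day LD 12:12 time-lapse recording (one frame per minute) of a
nocturnal cricket tracked at six keypoints (head, thorax, abdomen, abdominal
tip, left/right hind leg), so that every pipeline stage can be exercised
end-to-end without video or a trained network.

The behavioural process is a time-inhomogeneous Markov chain over four
states with phase-dependent per-minute transition probabilities:

* ``locomote`` — the abdomen jumps at least one body length in a random
  direction (more probable in the dark phase: nocturnal activity);
* ``active`` — sub-body-length wandering steps;
* ``quiescent`` — abdomen jitter well below the 3 px immobility threshold,
  with geometrically distributed bout lengths (entry more probable in the
  light phase, producing light-phase sleep-like-state bouts);
* ``feed`` — the head is placed inside the currently active feeding area;
  feeding bouts persist for a few minutes and entry probability is boosted
  around the light/dark transitions.

The six keypoints are laid out as a rigid template around the abdomen along
a heading direction, the hind legs opening at a state-dependent angle: the
angle relaxes linearly with time spent quiescent (a smaller opening in
longer immobility), mimicking hind-leg relaxation during the sleep-like
state.  Isotropic Gaussian pixel noise is added to every keypoint, and
likelihood dropouts (confidence < 0.95) occur at a higher rate in the dark
phase, as infrared-illuminated frames are harder to label.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BODYPARTS, DAY_MIN, FeedingSegment, RecordingConfig, TrackTable
from .rhythm import EventSeries

ACTIVE, LOCOMOTE, QUIESCENT, FEED = 0, 1, 2, 3
STATE_NAMES = {ACTIVE: "active", LOCOMOTE: "locomote", QUIESCENT: "quiescent", FEED: "feed"}


def _default_feeding_segments() -> list[dict]:
    # food replenished three times (3/4-day intervals) shifts the arena, so the
    # feeding-area coordinates change per segment
    rects = [
        (100.0, 100.0, 180.0, 160.0),
        (112.0, 96.0, 192.0, 156.0),
        (104.0, 108.0, 184.0, 168.0),
        (96.0, 102.0, 176.0, 162.0),
    ]
    bounds = [0, 3 * DAY_MIN, 7 * DAY_MIN, 10 * DAY_MIN, 14 * DAY_MIN]
    return [
        {"start_t": bounds[i], "end_t": bounds[i + 1], "area": rects[i]}
        for i in range(4)
    ]


@dataclass
class SimParams:
    """Simulation parameters; the defaults reproduce the reference recording
    design (14 days, LD 12:12, 1 frame/min, nocturnal locomotion, light-phase
    sleep-like state, dark-phase likelihood dropout excess)."""

    days: int = 14
    frame_interval_min: int = 1
    light_min: int = 720
    dark_min: int = 720
    arena: tuple[float, float] = (735.0, 490.0)
    body_length_px: float = 147.0
    keypoint_noise_sd: float = 1.0
    # per-minute transition probabilities by phase
    p_locomote: dict = field(default_factory=lambda: {"light": 0.03, "dark": 0.30})
    p_quiescent: dict = field(default_factory=lambda: {"light": 0.12, "dark": 0.03})
    p_feed_entry: dict = field(default_factory=lambda: {"light": 0.002, "dark": 0.002})
    feed_stay_prob: float = 0.8
    feed_jitter_sd: float = 2.5
    feeding_bump_factor: float = 4.0
    feeding_bump_halfwidth_min: int = 120
    sls_mean_bout_min: float = 10.0
    quiescent_jitter_sd: float = 0.4
    # hind-leg angle model (degrees)
    angle_active_mean_deg: float = 130.0
    angle_relaxed_mean_deg: float = 100.0
    angle_per_min_relaxation_deg: float = 1.5
    angle_relaxation_cap_min: int = 20
    angle_sd_deg: float = 10.0
    # likelihood dropout rates per keypoint per frame
    dropout_rate: dict = field(default_factory=lambda: {"light": 0.03, "dark": 0.10})
    feeding_segments: list = field(default_factory=_default_feeding_segments)
    seed: int = 0

    def __post_init__(self):
        for d in (self.p_locomote, self.p_quiescent, self.p_feed_entry, self.dropout_rate):
            for v in d.values():
                if not (0 <= v <= 1):
                    raise ValueError("probabilities must be in [0, 1]")
        if not (0 < self.angle_active_mean_deg < 180):
            raise ValueError("angle means must be in (0, 180)")
        margin = 0.6 * self.body_length_px
        if 2 * margin >= min(self.arena):
            raise ValueError("body length too large for the arena")

    def to_config(self) -> RecordingConfig:
        return RecordingConfig(
            light_min=self.light_min,
            dark_min=self.dark_min,
            recording_days=self.days,
            start_zt_min=0,
            feeding_segments=[FeedingSegment(**s) if isinstance(s, dict) else s
                              for s in self.feeding_segments],
            arena_size=self.arena,
            frame_interval_min=self.frame_interval_min,
        )

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["arena"] = list(d["arena"])
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def default_paper_params() -> SimParams:
    """Parameters matching the reference recording design."""
    return SimParams()


@dataclass
class GroundTruth:
    """Generator-side record of states and true behaviour/posture series."""

    states: np.ndarray  # per frame, int codes
    locomotion: np.ndarray  # per frame pair
    immobile: np.ndarray  # per frame pair
    sls: np.ndarray  # per frame pair
    feeding: np.ndarray  # per frame
    runlength: np.ndarray  # per frame pair
    theta_deg: np.ndarray  # per frame, angle actually laid out (pre pixel noise)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.states)
        pad = lambda a: np.concatenate([np.asarray(a, dtype=int), [0]])[:n]  # noqa: E731
        return pd.DataFrame(
            {
                "t": np.arange(n),
                "state": [STATE_NAMES[s] for s in self.states],
                "locomotion": pad(self.locomotion),
                "immobile": pad(self.immobile),
                "sls": pad(self.sls),
                "feeding": np.asarray(self.feeding, dtype=int),
                "runlength": pad(self.runlength),
                "theta_deg": self.theta_deg,
            }
        )


@dataclass
class SimResult:
    track: TrackTable
    truth: GroundTruth
    config: RecordingConfig
    params: SimParams

    def write(self, out_dir) -> dict[str, Path]:
        """Serialise pose table (DLC CSV dialect), ground truth and config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pose": out / "pose.csv",
            "truth_ethogram": out / "truth_ethogram.csv",
            "truth_angles": out / "truth_angles.csv",
            "params": out / "params.json",
            "config": out / "config.yaml",
        }
        self.track.to_dlc_csv(paths["pose"])
        self.truth.to_frame().drop(columns=["theta_deg"]).to_csv(
            paths["truth_ethogram"], index=False
        )
        pd.DataFrame(
            {"t": np.arange(len(self.truth.theta_deg)), "theta_deg": self.truth.theta_deg}
        ).to_csv(paths["truth_angles"], index=False)
        self.params.to_json(paths["params"])
        self.config.to_yaml(paths["config"])
        return paths


def _rot(vec: np.ndarray, deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _transition_distance(zt: float, light_min: int) -> float:
    """Circular distance (min) of a ZT time to the nearest phase transition."""
    d = []
    for edge in (0.0, float(light_min)):
        raw = abs(zt - edge)
        d.append(min(raw, DAY_MIN - raw))
    return min(d)


def simulate(params: SimParams | None = None, seed: int | None = None) -> SimResult:
    """Run the state machine and emit a noisy keypoint track plus ground truth.

    Deterministic given (params, seed); ``seed`` overrides ``params.seed``.
    """
    p = params or SimParams()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    n = p.days * DAY_MIN // p.frame_interval_min
    L = p.body_length_px
    w, h = p.arena
    margin = 0.6 * L
    lo = np.array([margin, margin])
    hi = np.array([w - margin, h - margin])
    config = p.to_config()

    stay_q = 1.0 - 1.0 / max(p.sls_mean_bout_min, 1.0)

    states = np.empty(n, dtype=int)
    pos = np.empty((n, 2))
    heading = np.empty(n)
    theta = np.empty(n)
    q_run = 0

    states[0] = ACTIVE
    pos[0] = [(w / 2), (h / 2)]
    heading[0] = rng.uniform(0, 2 * np.pi)
    theta[0] = np.clip(
        p.angle_active_mean_deg + rng.normal(0, p.angle_sd_deg), 5.0, 175.0
    )
    feed_anchor = None
    feed_heading = 0.0

    for i in range(1, n):
        t = i * p.frame_interval_min
        zt = t % DAY_MIN
        light = zt < p.light_min
        phase = "light" if light else "dark"

        prev = states[i - 1]
        # locomotion is an unconditional per-minute arousal event: it can
        # interrupt quiescent and feeding bouts, so the realised per-minute
        # locomotion rate equals p_locomote in each phase
        if rng.random() < p.p_locomote[phase]:
            state = LOCOMOTE
        elif prev == QUIESCENT and rng.random() < stay_q:
            state = QUIESCENT
        elif prev == FEED and rng.random() < p.feed_stay_prob:
            state = FEED
        else:
            p_feed = p.p_feed_entry[phase]
            if _transition_distance(zt, p.light_min) <= p.feeding_bump_halfwidth_min:
                p_feed = min(1.0, p_feed * p.feeding_bump_factor)
            r = rng.random()
            if r < p_feed:
                state = FEED
            elif r < p_feed + p.p_quiescent[phase]:
                state = QUIESCENT
            else:
                state = ACTIVE
        states[i] = state

        prev_pos = pos[i - 1]
        if state == LOCOMOTE:
            dist = L * (1.05 + 0.55 * rng.random())
            for _ in range(64):
                ang = rng.uniform(0, 2 * np.pi)
                target = prev_pos + dist * np.array([np.cos(ang), np.sin(ang)])
                if np.all(target >= lo) and np.all(target <= hi):
                    break
            else:  # aim at the arena centre as a safe fallback direction
                centre = (lo + hi) / 2
                vec = centre - prev_pos
                ang = np.arctan2(vec[1], vec[0])
                target = prev_pos + dist * np.array([np.cos(ang), np.sin(ang)])
                target = np.clip(target, lo, hi)
            pos[i] = target
            heading[i] = ang
        elif state == ACTIVE:
            step = rng.uniform(5.0, 40.0)
            ang = heading[i - 1] + rng.normal(0, 0.6)
            target = prev_pos + step * np.array([np.cos(ang), np.sin(ang)])
            if np.any(target < lo) or np.any(target > hi):
                # turn toward the arena interior instead of sliding along a wall
                centre = (lo + hi) / 2
                vec = centre - prev_pos
                ang = np.arctan2(vec[1], vec[0]) + rng.normal(0, 0.5)
                target = prev_pos + step * np.array([np.cos(ang), np.sin(ang)])
            pos[i] = np.clip(target, lo, hi)
            heading[i] = ang
        elif state == QUIESCENT:
            pos[i] = np.clip(prev_pos + rng.normal(0, p.quiescent_jitter_sd, 2), lo, hi)
            heading[i] = heading[i - 1] + rng.normal(0, 0.02)
        else:  # FEED
            seg = config.feeding_segment_at(t)
            x0, y0, x1, y1 = (float(v) for v in seg.area)
            if prev != FEED or feed_anchor is None:
                feed_anchor = np.array(
                    [rng.uniform(x0 + 5, x1 - 5), rng.uniform(y0 + 5, y1 - 5)]
                )
                for _ in range(32):
                    feed_heading = rng.uniform(0, 2 * np.pi)
                    u = np.array([np.cos(feed_heading), np.sin(feed_heading)])
                    abd = feed_anchor - 0.55 * L * u
                    if np.all(abd >= lo) and np.all(abd <= hi):
                        break
                else:
                    centre = (lo + hi) / 2
                    vec = feed_anchor - centre
                    feed_heading = np.arctan2(vec[1], vec[0])
                    u = np.array([np.cos(feed_heading), np.sin(feed_heading)])
                    abd = np.clip(feed_anchor - 0.55 * L * u, lo, hi)
            else:
                # pecking micro-movements around the anchor: the head stays in
                # the feeding area but the body is not immobile
                u = np.array([np.cos(feed_heading), np.sin(feed_heading)])
                abd = (
                    feed_anchor
                    - 0.55 * L * u
                    + rng.normal(0, p.feed_jitter_sd, 2)
                )
            pos[i] = abd
            heading[i] = feed_heading

        q_run = q_run + 1 if state == QUIESCENT else 0
        mean_angle = p.angle_active_mean_deg - p.angle_per_min_relaxation_deg * min(
            q_run, p.angle_relaxation_cap_min
        )
        theta[i] = np.clip(mean_angle + rng.normal(0, p.angle_sd_deg), 5.0, 175.0)

    # rigid template around the abdomen
    u = np.column_stack([np.cos(heading), np.sin(heading)])
    back = -u
    coords = {
        "head": pos + 0.55 * L * u,
        "thorax": pos + 0.20 * L * u,
        "abdomen": pos.copy(),
        "abdominal_tip": pos + 0.45 * L * back,
    }
    half = theta / 2.0
    leg_len = 0.40 * L
    for name, sign in (("left_hind_leg", +1.0), ("right_hind_leg", -1.0)):
        r = np.radians(sign * half)
        c, s = np.cos(r), np.sin(r)
        rotated = np.column_stack(
            [c * back[:, 0] - s * back[:, 1], s * back[:, 0] + c * back[:, 1]]
        )
        coords[name] = pos + leg_len * rotated

    # pixel noise and likelihoods
    light_frame = (np.arange(n) * p.frame_interval_min) % DAY_MIN < p.light_min
    drop_p = np.where(light_frame, p.dropout_rate["light"], p.dropout_rate["dark"])
    likelihoods = {}
    for bp in BODYPARTS:
        coords[bp] = np.clip(
            coords[bp] + rng.normal(0, p.keypoint_noise_sd, (n, 2)),
            [0.0, 0.0],
            [w, h],
        )
        dropped = rng.random(n) < drop_p
        lik = rng.uniform(0.95, 1.0, n)
        lik[dropped] = rng.uniform(0.30, 0.95, int(dropped.sum()))
        likelihoods[bp] = lik

    track = TrackTable.from_arrays(
        coords,
        likelihoods,
        scorer="gryllometry_sim",
        animal_id="sim",
        frame_interval_min=p.frame_interval_min,
    )

    truth = _ground_truth(states, theta)
    return SimResult(track=track, truth=truth, config=config, params=p)


def _ground_truth(states: np.ndarray, theta: np.ndarray) -> GroundTruth:
    """Derive true behaviour series from the state sequence (simple scans)."""
    n = len(states)
    locomotion = states[1:] == LOCOMOTE
    immobile = states[1:] == QUIESCENT
    feeding = states == FEED
    runlength = np.zeros(n - 1, dtype=int)
    run = 0
    for i, im in enumerate(immobile):
        run = run + 1 if im else 0
        runlength[i] = run
    sls = np.zeros(n - 1, dtype=bool)
    i = 0
    while i < n - 1:
        if immobile[i]:
            j = i
            while j < n - 1 and immobile[j]:
                j += 1
            if j - i >= 5:
                sls[i:j] = True
            i = j
        else:
            i += 1
    return GroundTruth(
        states=states,
        locomotion=locomotion,
        immobile=immobile,
        sls=sls,
        feeding=feeding,
        runlength=runlength,
        theta_deg=theta,
    )


def bernoulli_activity_series(
    p_light: float = 0.03,
    p_dark: float = 0.30,
    days: int = 14,
    light_min: int = 720,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> EventSeries:
    """Per-minute Bernoulli activity with phase-dependent rates (ZT0 start).

    A minimal nocturnal activity model: each minute is an independent event
    with probability ``p_dark`` in the dark phase and ``p_light`` in the
    light phase, giving an LD-driven 1440-min structure.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = days * DAY_MIN
    zt = np.arange(n) % DAY_MIN
    probs = np.where(zt < light_min, p_light, p_dark)
    return EventSeries((rng.random(n) < probs).astype(float), t0_zt=0)
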