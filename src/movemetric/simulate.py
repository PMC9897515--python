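"""Synthetic movement-learning data with known ground truth.

The generator emulates the statistical structure the method assumes, so
every other module can be exercised end to end without any recordings:

* a smooth four-phrase template gesture dominated by the (x, y) plane —
  slow horizontal arcs (cubic splines) punctuated by fast vertical strokes
  (Gaussian velocity bumps), with analytically consistent velocity and
  acceleration channels and plausible accelerometer/gyroscope proxies;
* learner performances = template + per-channel smooth error fields whose
  magnitude decays exponentially with practice time at channel-specific
  rates r_k, plus extra structured error inside designated salient template
  segments, plus a monotone random time warp whose strength also decays;
* raters whose judgement of a pair (A, A') is a noisy affine readout of the
  ground-truth weighted-DTW difference, clipped into [-1, 1].

Ground truth (channel weights w*, salient segments, rates, the rating gain)
is persisted so parameter-recovery can be measured.  Everything is
deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .dtw import dtw, per_channel_errors, per_segment_errors
from .io import (ALL_CHANNELS, AXES, MovementSeries, RatingRecord,
                 standardise, write_movement, write_ratings)
from .learning import MovementDataset, MovementKey

#: ground-truth channel weights (mean 1), echoing a planar gesture: large
#: weights on horizontal acceleration, wrist rotation and vertical-stroke
#: velocity; near-zero weight on depth position.
DEFAULT_TRUE_WEIGHTS = {
    "acc_x": 2.20, "acc_y": 1.05, "acc_z": 0.72,
    "gyr_x": 0.90, "gyr_y": 2.00, "gyr_z": 0.78,
    "p0_x": 0.62, "p0_y": 0.76, "p0_z": 0.12,
    "p1_x": 1.80, "p1_y": 1.20, "p1_z": 0.34,
    "p2_x": 1.10, "p2_y": 0.96, "p2_z": 0.45,
}


@dataclass
class SimConfig:
    """Study-scale defaults: 12 learners, 3 sessions, 180 rated pairs."""

    n_participants: int = 12
    n_sessions: int = 3
    trials_per_session: int = 8
    template_length: int = 1200      # samples at 100 Hz (12 s gesture)
    n_phrases: int = 4
    sample_rate: float = 100.0
    n_pairs: int = 180
    n_raters: int = 1
    rater_noise: float = 0.1         # sigma_r on the [-1, 1] rating scale
    kinematic_noise: float = 0.02    # white measurement noise, channel-SD units
    rating_basis: str = "feature"    # "feature" | "segment"
    true_feature_weights: np.ndarray = field(
        default_factory=lambda: np.array(
            [DEFAULT_TRUE_WEIGHTS[c] for c in ALL_CHANNELS]))
    segment_granularity: int = 25
    true_segment_saliency: tuple[int, ...] = (16, 17, 18, 19)
    salient_weight_share: float = 0.7
    learning_rates: np.ndarray | None = None  # r_k; default coupled to w*
    error_amplitude: float = 0.8     # initial error, channel-SD units
    error_floor: float = 0.15        # residual error after learning
    amplitude_jitter: float = 0.55   # lognormal sigma per performance/channel
    noise_correlation: float = 30.0  # smooth-error correlation, samples
    warp_strength: float = 0.06      # initial timing distortion
    warp_floor: float = 0.015
    warp_rate: float = 0.075
    salient_amplitude: float = 1.2   # extra error in salient segments
    salient_floor: float = 0.35
    salient_rate: float = 0.3   # faster than the mean channel rate, so the
                                # rater-salient segments are fast-learning
    seed: int = 0

    def __post_init__(self):
        self.true_feature_weights = np.asarray(self.true_feature_weights,
                                               dtype=np.float64)
        if self.true_feature_weights.size != len(ALL_CHANNELS):
            raise ValueError("true_feature_weights must cover all 15 channels")
        if (self.true_feature_weights <= 0).any():
            raise ValueError("true_feature_weights must be positive")
        # keep the mean-one convention of feature weights
        self.true_feature_weights = (
            self.true_feature_weights / self.true_feature_weights.mean())
        if self.learning_rates is None:
            # salient-to-raters channels are also the fast-learning ones:
            # rates follow the rank order of w*, spread over [0.04, 0.4] per
            # trial — mutually distinguishable, yet slow enough that
            # between-session differences persist for the raters to judge
            order = np.argsort(np.argsort(self.true_feature_weights))
            k = self.true_feature_weights.size
            self.learning_rates = 0.04 + 0.36 * order / (k - 1)
        self.learning_rates = np.asarray(self.learning_rates, np.float64)
        if (self.learning_rates < 0).any():
            raise ValueError("learning rates must be >= 0")
        for name in ("rater_noise", "kinematic_noise", "error_amplitude",
                     "error_floor", "warp_strength", "salient_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rating_basis not in ("feature", "segment"):
            raise ValueError("rating_basis must be 'feature' or 'segment'")
        bad = [j for j in self.true_segment_saliency
               if not 0 <= j < self.segment_granularity]
        if bad:
            raise ValueError(f"salient segments out of range: {bad}")
        if self.template_length < 10 * self.n_phrases:
            raise ValueError("template too short for the requested phrases")

    @property
    def true_segment_weights(self) -> np.ndarray:
        """Ground-truth segment weights (sum 1), concentrated on saliency."""
        g = self.segment_granularity
        sal = np.zeros(g, dtype=bool)
        sal[list(self.true_segment_saliency)] = True
        w = np.empty(g)
        w[sal] = self.salient_weight_share / sal.sum()
        w[~sal] = (1.0 - self.salient_weight_share) / (~sal).sum()
        return w

    def practice_time(self, session_idx: int, trial_idx: int) -> float:
        """Practice coordinate = number of previously performed trials.

        Improvement accrues per performed repetition (massed practice), so
        learning rates are per-trial quantities and the practice axis used
        for learning-curve fits coincides with this coordinate.
        """
        return session_idx * self.trials_per_session + trial_idx


@dataclass
class SimTruth:
    """Realised ground truth, sufficient to regenerate the data."""

    feature_weights: list[float]
    segment_weights: list[float]
    salient_segments: list[int]
    segment_granularity: int
    learning_rates: list[float]
    rating_gain: float
    rating_basis: str
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def phrase_boundaries(cfg: SimConfig) -> np.ndarray:
    """Sample indices splitting [0, template_length) into the phrases."""
    return np.linspace(0, cfg.template_length, cfg.n_phrases + 1).astype(int)


# ---------------------------------------------------------------------------
# template gesture
# ---------------------------------------------------------------------------

# hand-designed knot values tracing horizontal in/out arcs, a gently moving
# vertical baseline and minimal depth excursion
_X_KNOTS = [0.0, 0.30, -0.20, 0.25, -0.30, 0.10, -0.15, 0.35, -0.25,
            0.20, -0.30, 0.15, -0.10, 0.30, -0.20, 0.10, 0.0]
_Y_KNOTS = [0.0, 0.10, -0.05, 0.15, -0.10, 0.05, 0.20, -0.15, 0.10,
            -0.05, 0.15, -0.20, 0.05, 0.10, -0.10, 0.05, 0.0]
_Z_KNOTS = [0.0, 0.04, -0.02, 0.03, -0.04, 0.02, -0.03, 0.04, -0.02,
            0.02, -0.04, 0.02, -0.02, 0.03, -0.02, 0.01, 0.0]

_STROKE_AMPLITUDE = 0.9   # vertical stroke height (position units)
_STROKE_WIDTH = 0.06      # stroke Gaussian sigma (seconds)


def _stroke_terms(t: np.ndarray, mu: float, sigma: float, amp: float):
    """A Gaussian position bump and its first two time derivatives."""
    u = (t - mu) / sigma
    g = amp * np.exp(-0.5 * u * u)
    g1 = -g * u / sigma
    g2 = g * (u * u - 1.0) / (sigma * sigma)
    return g, g1, g2


def make_template(cfg: SimConfig) -> MovementSeries:
    """Build the template gesture with all 15 channels.

    Position is a cubic spline (horizontal arcs, small depth wiggle) plus
    two Gaussian vertical strokes per phrase; p1/p2 are the exact
    derivatives of that generating function.  The accelerometer channels
    are p2 plus a slowly rotating gravity-like component and a constant
    bias; the gyroscope channels are a smoothed angular-velocity proxy
    built from the velocity and acceleration vectors.
    """
    n = cfg.template_length
    dur = n / cfg.sample_rate
    t = np.arange(n) / cfg.sample_rate
    knot_t = np.linspace(0.0, dur, len(_X_KNOTS))

    p0 = np.empty((n, 3))
    p1 = np.empty((n, 3))
    p2 = np.empty((n, 3))
    for a, knots in enumerate((_X_KNOTS, _Y_KNOTS, _Z_KNOTS)):
        cs = CubicSpline(knot_t, knots, bc_type="natural")
        p0[:, a] = cs(t)
        p1[:, a] = cs.derivative(1)(t)
        p2[:, a] = cs.derivative(2)(t)

    # vertical strokes: two fast y-excursions per phrase
    phrase_dur = dur / cfg.n_phrases
    for ph in range(cfg.n_phrases):
        for frac in (0.25, 0.65):
            g, g1, g2 = _stroke_terms(t, (ph + frac) * phrase_dur,
                                      _STROKE_WIDTH, _STROKE_AMPLITUDE)
            p0[:, 1] += g
            p1[:, 1] += g1
            p2[:, 1] += g2

    # accelerometer: p2 plus a rotating gravity-like term (decorrelates the
    # two channel groups) and a constant bias
    orient = np.column_stack([
        np.sin(2 * np.pi * 0.35 * t),
        np.sin(2 * np.pi * 0.27 * t + 1.0),
        np.cos(2 * np.pi * 0.22 * t),
    ])
    acc = p2 + 0.6 * p2.std(axis=0) * orient + 0.05

    # gyroscope: smoothed angular-velocity proxy omega = (v x a) / |v|^2
    cross = np.cross(p1, p2)
    speed2 = (p1 ** 2).sum(axis=1)
    gyr = cross / (speed2 + 0.1 * speed2.mean())[:, None]
    gyr = gaussian_filter1d(gyr, sigma=5.0, axis=0)

    blocks = {"acc": acc, "gyr": gyr, "p0": p0, "p1": p1, "p2": p2}
    samples = np.column_stack([blocks[c.split("_")[0]][:, AXES.index(c[-1])]
                               for c in ALL_CHANNELS])
    return MovementSeries(samples, ALL_CHANNELS, participant_id="template",
                          session_id=0, trial_id=0,
                          sample_rate=cfg.sample_rate)


# ---------------------------------------------------------------------------
# learner performances
# ---------------------------------------------------------------------------

def _smooth_noise(rng, n: int, sigma: float) -> np.ndarray:
    """Unit-RMS noise with correlation length ~sigma samples."""
    x = gaussian_filter1d(rng.standard_normal(n), sigma=sigma)
    rms = np.sqrt((x ** 2).mean())
    return x / rms if rms > 0 else x


def _salient_window(cfg: SimConfig) -> np.ndarray:
    """Smoothed indicator of the salient template spans."""
    n = cfg.template_length
    g = cfg.segment_granularity
    edges = np.linspace(0, n, g + 1).astype(int)
    w = np.zeros(n)
    for j in cfg.true_segment_saliency:
        w[edges[j]:edges[j + 1]] = 1.0
    return gaussian_filter1d(w, sigma=0.02 * n / g + 5.0)


def make_performance(template: MovementSeries, participant: int, session: int,
                     trial: int, cfg: SimConfig) -> MovementSeries:
    """One learner performance at the given practice position (0-based ids).

    The per-channel error magnitude follows
    ``E0 * exp(-r_k * practice) + floor`` (channel-SD units) with a
    lognormal per-performance amplitude jitter; extra structured error is
    injected inside the salient template spans; the result is passed
    through a smooth monotone time warp whose strength also decays with
    practice.
    """
    rng = np.random.default_rng(
        [cfg.seed, 11, participant, session, trial])
    n = template.n_samples
    practice = cfg.practice_time(session, trial)
    chan_sd = template.samples.std(axis=0)
    amp = (cfg.error_amplitude * np.exp(-cfg.learning_rates * practice)
           + cfg.error_floor)
    sal_amp = (cfg.salient_amplitude * np.exp(-cfg.salient_rate * practice)
               + cfg.salient_floor)
    window = _salient_window(cfg)

    err = np.empty_like(template.samples)
    for k in range(template.n_channels):
        jitter = np.exp(rng.normal(0.0, cfg.amplitude_jitter))
        sal_jitter = np.exp(rng.normal(0.0, cfg.amplitude_jitter))
        e = amp[k] * jitter * _smooth_noise(rng, n, cfg.noise_correlation)
        e += (sal_amp * sal_jitter * window
              * _smooth_noise(rng, n, cfg.noise_correlation))
        e += cfg.kinematic_noise * rng.standard_normal(n)
        err[:, k] = chan_sd[k] * e
    perturbed = template.samples + err

    # monotone time warp: exponentiated smooth noise as increments
    strength = (cfg.warp_strength * np.exp(-cfg.warp_rate * practice)
                + cfg.warp_floor)
    incr = np.exp(3.0 * strength * _smooth_noise(rng, n - 1,
                                                 cfg.noise_correlation))
    pos = np.concatenate(([0.0], np.cumsum(incr)))
    pos *= (n - 1) / pos[-1]
    warped = np.column_stack([
        np.interp(pos, np.arange(n), perturbed[:, k])
        for k in range(template.n_channels)])
    return MovementSeries(warped, template.channel_names,
                          participant_id=f"P{participant + 1:02d}",
                          session_id=session + 1, trial_id=trial,
                          sample_rate=cfg.sample_rate)


# ---------------------------------------------------------------------------
# rated pairs
# ---------------------------------------------------------------------------

def sample_pairs(cfg: SimConfig, rng) -> list[tuple[str, MovementKey, MovementKey]]:
    """Within-participant, cross-session pair sample (the rating design)."""
    if cfg.n_sessions < 2:
        raise ValueError("need >= 2 sessions to sample cross-session pairs")
    pairs = []
    for i in range(cfg.n_pairs):
        p = int(rng.integers(cfg.n_participants))
        pid = f"P{p + 1:02d}"
        sa, sb = rng.choice(cfg.n_sessions, size=2, replace=False)
        ta = int(rng.integers(cfg.trials_per_session))
        tb = int(rng.integers(cfg.trials_per_session))
        pairs.append((f"pair{i:04d}",
                      (pid, int(sa) + 1, ta), (pid, int(sb) + 1, tb)))
    return pairs


def latent_scores(template: MovementSeries,
                  movements: dict[MovementKey, MovementSeries],
                  pairs, cfg: SimConfig, radius: int = 10) -> np.ndarray:
    """Ground-truth weighted-DTW differences for the sampled pairs."""
    needed = sorted({k for _, ka, kb in pairs for k in (ka, kb)})
    scores = {}
    for key in needed:
        _, path = dtw(template, movements[key], radius=radius)
        if cfg.rating_basis == "feature":
            e = per_channel_errors(template, movements[key], path)
            scores[key] = float(e @ cfg.true_feature_weights)
        else:
            s = per_segment_errors(template, movements[key], path,
                                   cfg.segment_granularity)
            scores[key] = float(s @ cfg.true_segment_weights)
    return np.array([scores[ka] - scores[kb] for _, ka, kb in pairs])


def make_ratings(template: MovementSeries,
                 movements: dict[MovementKey, MovementSeries],
                 cfg: SimConfig, radius: int = 10):
    """Simulated rater judgements of sampled pairs.

    The latent score of a pair is the ground-truth weighted-DTW difference,
    mapped into [-1, 1] by a clipped linear gain set from the 99th
    percentile of |score| (so the assumed linear rating-delta relation
    holds in-range); each rater adds i.i.d. Gaussian noise and clips.

    Returns ``(records, pair mapping, SimTruth)``.
    """
    rng = np.random.default_rng([cfg.seed, 23])
    pairs = sample_pairs(cfg, rng)
    deltas = latent_scores(template, movements, pairs, cfg, radius=radius)
    scale = np.percentile(np.abs(deltas), 99)
    gain = 1.0 / scale if scale > 0 else 1.0
    true_ratings = np.clip(gain * deltas, -1.0, 1.0)

    records = []
    for r in range(cfg.n_raters):
        noise = rng.normal(0.0, cfg.rater_noise, size=len(pairs))
        noisy = np.clip(true_ratings + noise, -1.0, 1.0)
        for (pair_id, ka, kb), val in zip(pairs, noisy):
            records.append(RatingRecord(
                pair_id=pair_id, participant_id=ka[0], session_a=ka[1],
                session_b=kb[1], rater_id=f"R{r + 1}", rating=float(val)))
    truth = SimTruth(
        feature_weights=list(cfg.true_feature_weights),
        segment_weights=list(cfg.true_segment_weights),
        salient_segments=list(cfg.true_segment_saliency),
        segment_granularity=cfg.segment_granularity,
        learning_rates=list(cfg.learning_rates),
        rating_gain=float(gain), rating_basis=cfg.rating_basis,
        seed=cfg.seed)
    pair_map = {pid: (ka, kb) for pid, ka, kb in pairs}
    return records, pair_map, truth


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

def make_dataset(cfg: SimConfig, radius: int = 10,
                 standardised: bool = True):
    """Generate a complete rated dataset; returns ``(dataset, truth)``.

    With ``standardised=True`` (the analysis convention) all series are
    z-scored with statistics pooled over template and performances, and the
    rater model operates on the same standardised channels the analysis
    sees.
    """
    template = make_template(cfg)
    movements: dict[MovementKey, MovementSeries] = {}
    for p in range(cfg.n_participants):
        for s in range(cfg.n_sessions):
            for tr in range(cfg.trials_per_session):
                m = make_performance(template, p, s, tr, cfg)
                movements[m.key()] = m
    if standardised:
        group, _ = standardise([template] + list(movements.values()))
        template = group[0]
        movements = {m.key(): m for m in group[1:]}
    records, pair_map, truth = make_ratings(template, movements, cfg,
                                            radius=radius)
    dataset = MovementDataset(template=template, movements=movements,
                              ratings=records, pairs=pair_map)
    return dataset, truth


def save_dataset(cfg: SimConfig, out_dir, radius: int = 10) -> Path:
    """Emit the on-disk layout: movement CSVs, ratings, pairs and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = make_dataset(cfg, radius=radius, standardised=False)
    mov_dir = out / "movements"
    mov_dir.mkdir(exist_ok=True)
    write_movement(dataset.template, mov_dir / "template_0_0.csv")
    for (pid, ses, tr), m in dataset.movements.items():
        write_movement(m, mov_dir / f"{pid}_{ses}_{tr}.csv")
    write_ratings(dataset.ratings, out / "ratings.csv")
    rows = ["pair_id,participant_id,session_a,trial_a,session_b,trial_b"]
    for pid, (ka, kb) in dataset.pairs.items():
        rows.append(f"{pid},{ka[0]},{ka[1]},{ka[2]},{kb[1]},{kb[2]}")
    (out / "pairs.csv").write_text("\n".join(rows) + "\n")
    truth.to_json(out / "truth.json")
    return out


def load_dataset(path, standardise_channels: bool = True) -> MovementDataset:
    """Load a dataset directory written by :func:`save_dataset`.

    Velocity/acceleration channels are derived with the Savitzky-Golay
    filter when a movement file carries only the raw sensor channels; all
    series are then pooled-standardised (template included) unless
    ``standardise_channels`` is False.
    """
    import csv

    from .io import derive_kinematics, read_movement, read_ratings

    root = Path(path)
    movements: dict[MovementKey, MovementSeries] = {}
    template = None
    for f in sorted((root / "movements").glob("*.csv")):
        pid, ses, tr = f.stem.rsplit("_", 2)
        m = read_movement(f, participant_id=pid, session_id=int(ses),
                          trial_id=int(tr))
        if "p1_x" not in m.channel_names:
            m = derive_kinematics(m)
        if pid == "template":
            template = m
        else:
            movements[m.key()] = m
    if template is None:
        raise FileNotFoundError(f"{root}: no template recording found")
    ratings = read_ratings(root / "ratings.csv")
    pairs = {}
    with open(root / "pairs.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pairs[row["pair_id"]] = (
                (row["participant_id"], int(row["session_a"]),
                 int(row["trial_a"])),
                (row["participant_id"], int(row["session_b"]),
                 int(row["trial_b"])))
    if standardise_channels:
        group, _ = standardise([template] + list(movements.values()))
        template = group[0]
        movements = {m.key(): m for m in group[1:]}
    return MovementDataset(template=template, movements=movements,
                           ratings=ratings, pairs=pairs)
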