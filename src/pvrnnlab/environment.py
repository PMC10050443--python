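"""Hierarchical stochastic reaching-task environment.

Observable signals are 2-D trajectories mimicking reaching movements,
generated by a three-level hidden process:

1. *Transition bias* b in (0, 1) — the highest-order context; the
   probability that a reach departing HOME targets LEFT.
2. *Target state* — per reach, LEFT with probability b, else RIGHT
   (Bernoulli draw).
3. *Signal noise* sigma — goal positions are drawn from an isotropic
   Gaussian centred on the target state's coordinate, and i.i.d.
   Gaussian observation noise of the same scale perturbs every sample.

Each reach moves HOME -> goal -> HOME by linear interpolation with a
short dwell at the goal and at HOME.  A training corpus is a set of
fixed-bias sequences spanning a range of biases; a test sequence
switches bias once at its midpoint so that an agent's flexibility
(behavioural and cognitive) can be probed.

Time is 0-based internally; a 1-based step t in derived write-ups maps
to array index t - 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StateLabel",
    "EnvConfig",
    "GroundTruth",
    "TrajectorySequence",
    "sample_target_states",
    "render_trajectory",
    "build_training_set",
    "build_test_sequence",
    "classify_state",
    "classify_trajectory",
    "write_sequences",
]

#: the nine transition biases of the default training corpus
DEFAULT_BIASES: tuple[float, ...] = (0.98, 0.87, 0.76, 0.65, 0.54, 0.43, 0.32, 0.21, 0.10)


class StateLabel(IntEnum):
    """Discrete task state; ordering fixes the classification tie-break."""

    HOME = 0
    LEFT = 1
    RIGHT = 2


@dataclass(frozen=True)
class EnvConfig:
    """Static configuration of the reaching environment.

    Parameters
    ----------
    centers
        Noiseless coordinate of each state, inside [-1, 1]^2.
    sigma_stable, sigma_noisy
        Gaussian s.d. of goal draws and per-step observation noise in
        the stable / noisy condition.  Must satisfy
        ``sigma_noisy > sigma_stable > 0``.
    steps_per_segment
        Time steps of the linear HOME->goal (and goal->HOME) movement.
    dwell_steps
        Resting steps at the goal and again at HOME after the return.
    seq_len
        Length of every generated sequence.
    biases
        Transition biases of the training corpus (values in (0, 1)).
    n_sets
        How many sequences are generated per bias.
    """

    centers: dict[StateLabel, tuple[float, float]] = field(
        default_factory=lambda: {
            StateLabel.HOME: (0.0, -0.6),
            StateLabel.LEFT: (-0.6, 0.6),
            StateLabel.RIGHT: (0.6, 0.6),
        }
    )
    sigma_stable: float = 0.05
    sigma_noisy: float = 0.25
    # one reach cycle = 2*steps_per_segment + 2*dwell_steps = 16 steps,
    # which divides the half-sequence lengths (128, 256): concatenated
    # test halves therefore stay phase-coherent, keeping the reach
    # rhythm continuous across the mid-sequence bias switch
    steps_per_segment: int = 6
    dwell_steps: int = 2
    seq_len: int = 512
    biases: tuple[float, ...] = DEFAULT_BIASES
    n_sets: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma_noisy > self.sigma_stable > 0):
            raise ValueError("require sigma_noisy > sigma_stable > 0")
        if self.steps_per_segment < 1 or self.seq_len < self.steps_per_segment:
            raise ValueError("require seq_len >= steps_per_segment >= 1")
        if self.dwell_steps < 0:
            raise ValueError("dwell_steps must be nonnegative")
        pts = [tuple(v) for v in self.centers.values()]
        if len(set(pts)) != len(pts):
            raise ValueError("state centers must be pairwise distinct")
        if len(self.centers) != 3:
            raise ValueError("need a center for each of HOME, LEFT, RIGHT")

    def sigma(self, noise_condition: str) -> float:
        if noise_condition == "stable":
            return self.sigma_stable
        if noise_condition == "noisy":
            return self.sigma_noisy
        raise ValueError(f"unknown noise condition {noise_condition!r}")

    def center_array(self) -> np.ndarray:
        """(3, 2) array of centers indexed by StateLabel value."""
        return np.array([self.centers[s] for s in StateLabel], dtype=float)


@dataclass
class GroundTruth:
    """Per-step hidden variables aligned with the observed trajectory."""

    bias_t: np.ndarray  # (T,) piecewise-constant transition bias
    target_t: np.ndarray  # (T,) StateLabel values; HOME during return/home dwell
    state_t: np.ndarray  # (T,) noiseless nearest-state labels

    def __post_init__(self) -> None:
        if not (len(self.bias_t) == len(self.target_t) == len(self.state_t)):
            raise ValueError("ground-truth channels must have equal length")


@dataclass
class TrajectorySequence:
    """Observed 2-D signal plus the hidden process that generated it."""

    x: np.ndarray  # (T, 2) observed signal, clipped to [-1, 1]^2
    truth: GroundTruth
    bias: float | tuple[float, float]
    noise_condition: str
    seed: int | None = None

    def __len__(self) -> int:
        return self.x.shape[0]


def sample_target_states(
    bias: float,
    n: int,
    rng: np.random.Generator,
    *,
    allow_degenerate: bool = False,
) -> np.ndarray:
    """Draw ``n`` reach targets: LEFT with probability ``bias``, else RIGHT.

    Degenerate biases 0 and 1 are refused unless ``allow_degenerate`` is
    set (used only to exercise boundary behaviour in tests).
    """
    lo, hi = (0.0, 1.0) if allow_degenerate else (np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    if not (lo <= bias <= hi):
        raise ValueError(f"transition bias must lie in (0, 1); got {bias}")
    if n < 1:
        raise ValueError("n must be positive")
    draws = rng.random(n) < bias
    return np.where(draws, StateLabel.LEFT.value, StateLabel.RIGHT.value).astype(np.int64)


def _reach_profile(cfg: EnvConfig) -> tuple[np.ndarray, np.ndarray]:
    """Interpolation weights and phase flags of one HOME->goal->HOME cycle.

    Returns ``(alpha, outbound)`` where ``alpha[k]`` in [0, 1] is the
    fractional position between HOME (0) and the goal (1) at step k of
    the cycle and ``outbound[k]`` marks steps that belong to the
    outbound movement or the dwell at the goal (the steps whose target
    label is the reach target rather than HOME).
    """
    s, dw = cfg.steps_per_segment, cfg.dwell_steps
    go = np.arange(1, s + 1) / s  # leaves HOME on the first step
    stay = np.ones(dw)
    back = np.arange(s - 1, -1, -1) / s  # reaches HOME exactly on the last step
    home = np.zeros(dw)
    alpha = np.concatenate([go, stay, back, home])
    outbound = np.concatenate(
        [np.ones(s + dw, dtype=bool), np.zeros(s + dw, dtype=bool)]
    )
    return alpha, outbound


def render_trajectory(
    targets: Sequence[int],
    bias: float,
    cfg: EnvConfig,
    noise_condition: str,
    rng: np.random.Generator,
) -> TrajectorySequence:
    """Render reach targets into an observed sequence of ``cfg.seq_len`` steps.

    For each target a goal is drawn from Normal(center(target), sigma^2 I);
    the point moves HOME -> goal -> HOME by linear interpolation, dwelling
    at the goal and at HOME.  If the targets run out before ``seq_len``
    steps, further targets are drawn from ``bias``; the sequence is then
    truncated to exactly ``seq_len``.  Observation noise of the same
    sigma is added to every sample and the result is clipped to
    [-1, 1]^2.
    """
    targets = list(int(t) for t in targets)
    if not targets:
        raise ValueError("targets must be nonempty")
    sigma = cfg.sigma(noise_condition)
    centers = cfg.center_array()
    home = centers[StateLabel.HOME.value]
    alpha, outbound = _reach_profile(cfg)
    cycle = len(alpha)

    clean_parts, target_parts = [], []
    total = 0
    i = 0
    while total < cfg.seq_len:
        if i >= len(targets):
            targets.append(int(sample_target_states(bias, 1, rng)[0]))
        tgt = targets[i]
        goal = centers[tgt] + sigma * rng.standard_normal(2)
        seg = home[None, :] + alpha[:, None] * (goal - home)[None, :]
        clean_parts.append(seg)
        labels = np.where(outbound, tgt, StateLabel.HOME.value)
        target_parts.append(labels)
        total += cycle
        i += 1

    clean = np.concatenate(clean_parts)[: cfg.seq_len]
    target_t = np.concatenate(target_parts)[: cfg.seq_len]

    # noiseless reference path (goals at the exact centers) for state_t
    ref_parts = []
    for tgt in targets[:i]:
        seg = home[None, :] + alpha[:, None] * (centers[tgt] - home)[None, :]
        ref_parts.append(seg)
    ref = np.concatenate(ref_parts)[: cfg.seq_len]
    state_t = classify_trajectory(ref, cfg)

    x = clean + sigma * rng.standard_normal(clean.shape)
    np.clip(x, -1.0, 1.0, out=x)
    truth = GroundTruth(
        bias_t=np.full(cfg.seq_len, bias, dtype=float),
        target_t=target_t.astype(np.int64),
        state_t=state_t,
    )
    return TrajectorySequence(x=x, truth=truth, bias=bias, noise_condition=noise_condition)


def build_training_set(
    cfg: EnvConfig,
    noise_condition: str,
    rng: np.random.Generator,
) -> list[TrajectorySequence]:
    """The developmental-learning corpus: ``n_sets`` sequences per bias.

    The default configuration yields 18 sequences of 512 steps covering
    nine biases from 0.98 (strongly LEFT) to 0.10 (strongly RIGHT),
    each appearing twice.
    """
    corpus = []
    for _ in range(cfg.n_sets):
        for bias in cfg.biases:
            n_reaches = -(-cfg.seq_len // len(_reach_profile(cfg)[0]))
            targets = sample_target_states(bias, n_reaches, rng)
            corpus.append(render_trajectory(targets, bias, cfg, noise_condition, rng))
    return corpus


def build_test_sequence(
    cfg: EnvConfig,
    noise_condition: str,
    rng: np.random.Generator,
) -> TrajectorySequence:
    """A context-switching probe sequence.

    Two halves of ``seq_len / 2`` steps are rendered independently and
    concatenated.  The first half's bias is drawn from ``cfg.biases``;
    the second half's bias is drawn uniformly from the configured biases
    on the *opposite* side of 0.5, so the hidden context flips exactly
    once, at step ``seq_len // 2`` (0-based index of the first
    second-half step).
    """
    left_side = [b for b in cfg.biases if b > 0.5]
    right_side = [b for b in cfg.biases if b < 0.5]
    if not left_side or not right_side:
        raise ValueError("cfg.biases must contain values on both sides of 0.5")
    first = float(rng.choice(np.asarray(cfg.biases, dtype=float)))
    pool = right_side if first > 0.5 else left_side
    second = float(rng.choice(np.asarray(pool, dtype=float)))

    half_cfg = replace(cfg, seq_len=cfg.seq_len // 2)
    n_reaches = -(-half_cfg.seq_len // len(_reach_profile(cfg)[0]))
    halves = []
    for b in (first, second):
        targets = sample_target_states(b, n_reaches, rng)
        halves.append(render_trajectory(targets, b, half_cfg, noise_condition, rng))

    x = np.concatenate([h.x for h in halves])
    truth = GroundTruth(
        bias_t=np.concatenate([h.truth.bias_t for h in halves]),
        target_t=np.concatenate([h.truth.target_t for h in halves]),
        state_t=np.concatenate([h.truth.state_t for h in halves]),
    )
    return TrajectorySequence(
        x=x, truth=truth, bias=(first, second), noise_condition=noise_condition
    )


def classify_state(point: np.ndarray, cfg: EnvConfig) -> StateLabel:
    """Nearest-center state of a single 2-D point (ties -> lowest label)."""
    point = np.asarray(point, dtype=float)
    if point.shape != (2,) or not np.all(np.isfinite(point)):
        raise ValueError("point must be a finite 2-vector")
    d2 = np.sum((cfg.center_array() - point) ** 2, axis=1)
    return StateLabel(int(np.argmin(d2)))


def classify_trajectory(points: np.ndarray, cfg: EnvConfig) -> np.ndarray:
    """Vectorised nearest-center labels for a (T, 2) trajectory."""
    points = np.asarray(points, dtype=float)
    d2 = np.sum((points[:, None, :] - cfg.center_array()[None, :, :]) ** 2, axis=2)
    return np.argmin(d2, axis=1).astype(np.int64)


def write_sequences(
    sequences: Sequence[TrajectorySequence],
    out_dir: str | Path,
    cfg: EnvConfig,
    *,
    prefix: str = "seq",
) -> Path:
    """Write sequences as CSV files plus a JSON manifest; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, seq in enumerate(sequences):
        name = f"{prefix}_{i:03d}.csv"
        names.append(name)
        t = np.arange(len(seq))
        header = "t,x0,x1,bias,target,state"
        cols = np.column_stack(
            [t, seq.x[:, 0], seq.x[:, 1], seq.truth.bias_t, seq.truth.target_t, seq.truth.state_t]
        )
        np.savetxt(out / name, cols, delimiter=",", header=header, comments="",
                   fmt=["%d", "%.6f", "%.6f", "%.4f", "%d", "%d"])
    manifest = {
        "files": names,
        "noise_condition": sequences[0].noise_condition if sequences else None,
        "config": {
            "centers": {s.name: list(cfg.centers[s]) for s in StateLabel},
            "sigma_stable": cfg.sigma_stable,
            "sigma_noisy": cfg.sigma_noisy,
            "steps_per_segment": cfg.steps_per_segment,
            "dwell_steps": cfg.dwell_steps,
            "seq_len": cfg.seq_len,
            "biases": list(cfg.biases),
            "n_sets": cfg.n_sets,
            "seed": cfg.seed,
        },
        "biases": [s.bias for s in sequences],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
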