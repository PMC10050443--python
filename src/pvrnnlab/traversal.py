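"""Latent-space traversal (LST) and the generative-hierarchy score.

Traversal probes what a single latent unit *causally* controls in
top-down generation: one long closed-loop sequence is generated per
fixed clamp value of the unit (mean channel: the sampled z entry is
pinned; variance channel: the prior sigma is pinned to exp(value)),
sweeping the value over a grid spanning [-1, 1].  Each grid point gets
its own fixed prior-noise stream, so a unit registers an effect only
where its causal influence on behaviour exceeds the generation noise.

Each generated sequence is summarised by behavioural properties — per
state: steps spent there, entries into it, coordinate variance of its
samples.  A unit's *efficacy* is the maximum over properties of the
absolute Pearson correlation between clamp values and the property;
the *generative hierarchy* of a layer is the mean efficacy of its
units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Architecture, Clamp, PVRNNParams, generate
from .environment import EnvConfig, StateLabel, classify_trajectory
from .metrics import safe_pearson

__all__ = [
    "SequenceProperties",
    "TraversalResult",
    "sequence_properties",
    "traverse_unit",
    "unit_efficacy",
    "generative_hierarchy",
    "DEFAULT_GRID",
    "DEFAULT_TRAVERSAL_STEPS",
]

#: 21 evenly spaced clamp values spanning [-1, 1]
DEFAULT_GRID: np.ndarray = np.linspace(-1.0, 1.0, 21)
DEFAULT_TRAVERSAL_STEPS: int = 1024


@dataclass
class SequenceProperties:
    """Behavioural summary of one generated sequence."""

    stay_steps: dict[StateLabel, int]
    transitions: dict[StateLabel, int]
    variance: dict[StateLabel, float]

    def as_vector(self) -> np.ndarray:
        """Fixed-order property vector (9 channels) for correlations."""
        return np.array(
            [self.stay_steps[s] for s in StateLabel]
            + [self.transitions[s] for s in StateLabel]
            + [self.variance[s] for s in StateLabel],
            dtype=float,
        )


@dataclass
class TraversalResult:
    """Per-grid-point sequence properties of one clamped unit."""

    unit: int
    channel: str
    grid: np.ndarray
    properties: list[SequenceProperties]
    efficacy: float = float("nan")


def sequence_properties(x: np.ndarray, env: EnvConfig) -> SequenceProperties:
    """Classify a (T, 2) sequence and summarise per-state behaviour."""
    labels = classify_trajectory(np.asarray(x, dtype=float), env)
    stay, trans, var = {}, {}, {}
    entered = np.concatenate([[True], labels[1:] != labels[:-1]])
    for s in StateLabel:
        mask = labels == s.value
        stay[s] = int(mask.sum())
        trans[s] = int(np.sum(entered & mask)) - (1 if labels[0] == s.value else 0)
        pts = x[mask]
        var[s] = float(pts.var(axis=0).mean()) if len(pts) >= 2 else 0.0
    return SequenceProperties(stay_steps=stay, transitions=trans, variance=var)


def traverse_unit(
    params: PVRNNParams,
    arch: Architecture,
    unit: int,
    grid: np.ndarray,
    env: EnvConfig,
    rng: np.random.Generator,
    *,
    channel: str = "mean",
    T: int = DEFAULT_TRAVERSAL_STEPS,
) -> TraversalResult:
    """Clamp one z unit across ``grid`` and generate T steps per value.

    All grid values run as one batched rollout; the prior noise for
    every grid point is drawn independently from ``rng``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("traversal grid must be nonempty")
    clamp = Clamp(unit=unit, channel=channel, value=grid)
    trace = generate(
        params, arch, T, mode="prior_sample", clamp=clamp, rng=rng, batch=grid.size
    )
    props = [sequence_properties(trace.x_hat[i], env) for i in range(grid.size)]
    result = TraversalResult(unit=unit, channel=channel, grid=grid, properties=props)
    if grid.size >= 3:
        result.efficacy = unit_efficacy(result)
    return result


def unit_efficacy(result: TraversalResult) -> float:
    """Max |Pearson r(clamp value, property)| over all property channels."""
    if result.grid.size < 3:
        raise ValueError("need at least 3 grid points for an efficacy")
    pm = np.stack([p.as_vector() for p in result.properties])  # (G, 9)
    rs = [abs(safe_pearson(result.grid, pm[:, j])) for j in range(pm.shape[1])]
    return float(max(rs))


def generative_hierarchy(
    params: PVRNNParams,
    arch: Architecture,
    layer: int,
    env: EnvConfig,
    rng: np.random.Generator,
    *,
    channel: str = "mean",
    grid: np.ndarray = DEFAULT_GRID,
    T: int = DEFAULT_TRAVERSAL_STEPS,
) -> float:
    """Mean efficacy of one layer's latent units for the given channel."""
    sl = arch.z_slices[layer]
    effs = [
        traverse_unit(
            params, arch, u, grid, env, rng, channel=channel, T=T
        ).efficacy
        for u in range(sl.start, sl.stop)
    ]
    return float(np.mean(effs)) if effs else 0.0
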