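"""Behavioural and cognitive flexibility measures.

*Behavioural flexibility* — how well one-step-ahead predictions track
the observable state transitions of a context-switching test sequence:
the percentage of steps on which the discrete state (HOME/LEFT/RIGHT,
by nearest-center classification) of the prediction agrees with that of
the observation.

*Cognitive flexibility* — how well the highest layer's inferred latents
track the hidden context: the maximum over the top layer's posterior
mean units of the absolute Pearson correlation with the true
piecewise-constant transition-bias signal.
"""

from __future__ import annotations

import numpy as np

from .core import Architecture, LatentTrace
from .environment import EnvConfig, GroundTruth, classify_trajectory

__all__ = ["behavioral_flexibility", "cognitive_flexibility", "safe_pearson"]


def behavioral_flexibility(
    pred: np.ndarray, obs: np.ndarray, env: EnvConfig
) -> float:
    """Percent agreement of nearest-center states of pred vs obs."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    sp = classify_trajectory(pred, env)
    so = classify_trajectory(obs, env)
    return 100.0 * float(np.mean(sp == so))


def safe_pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r with the convention r = 0 when either input is constant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.ptp(u) == 0.0 or np.ptp(v) == 0.0:
        return 0.0
    su, sv = u.std(), v.std()
    return float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))


def cognitive_flexibility(
    trace: LatentTrace,
    truth: GroundTruth,
    arch: Architecture,
    *,
    layer: int = -1,
    aggregate: str = "max",
) -> tuple[float, dict[int, float]]:
    """Correlation of top-layer posterior means with the hidden bias.

    Returns (score, per-unit correlations keyed by global z-unit
    index).  ``aggregate`` is 'max' (default) or 'mean' over |r|.
    """
    if trace.mu_q is None:
        raise ValueError("cognitive flexibility needs a posterior trace")
    bias = np.asarray(truth.bias_t, dtype=float)
    sl = arch.z_slices[layer]
    mu = trace.mu_q[0]  # (T, n_z)
    if mu.shape[0] != bias.shape[0]:
        raise ValueError("trace does not cover the full test sequence")
    corrs = {
        sl.start + i: safe_pearson(mu[:, sl.start + i], bias)
        for i in range(sl.stop - sl.start)
    }
    mags = np.abs(np.array(list(corrs.values())))
    if aggregate == "max":
        score = float(mags.max()) if mags.size else 0.0
    elif aggregate == "mean":
        score = float(mags.mean()) if mags.size else 0.0
    else:
        raise ValueError("aggregate must be 'max' or 'mean'")
    return score, corrs
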