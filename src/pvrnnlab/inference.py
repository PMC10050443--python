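"""Test-phase online inference by error regression.

With synaptic weights frozen, the network adapts to an unseen sequence
by optimising only the adaptive variables a_t inside a sliding window:
at each step t the windowed free energy (reconstruction of the observed
x within the window plus the test-phase meta-prior-weighted KL) is
minimised over the window's a entries for a fixed number of iterations,
and the network is then rolled one step past the window with the prior
mean to emit the one-step-ahead prediction xhat_{t+1}.

The test-phase meta-prior w_test controls how strongly the prior grips
the posterior during this online inference; by default it equals the
learning-phase meta-prior of the network's condition.

The optimisation uses the posterior mean (no reparameterisation noise)
and prior-mean prediction, so the reported predictions are
deterministic given the trained network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AdaptiveVariables,
    Architecture,
    LatentTrace,
    PVRNNParams,
    backward,
    forward,
    free_energy,
    mtrnn_step,
    output,
    prior_params,
)
from .optim import Adam

__all__ = ["RegressionConfig", "RegressionResult", "error_regression"]


@dataclass(frozen=True)
class RegressionConfig:
    """Sliding-window error-regression hyper-parameters."""

    window: int = 16
    iters: int = 30
    learning_rate: float = 0.05
    w_test: tuple[float, ...] | None = None  # None -> learning-phase w
    warm_start: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.iters < 1 or self.learning_rate <= 0:
            raise ValueError("invalid regression configuration")


@dataclass
class RegressionResult:
    """Predictions and the inferred posterior of one test sequence."""

    predictions: np.ndarray  # (T, n_out); predictions[t] forecasts x_t
    trace: LatentTrace  # full-sequence posterior pass with the final a
    a: AdaptiveVariables
    windowed_losses: np.ndarray  # (T, iters) free energy per inner iteration


def _predict_next(params, arch, h, d):
    """One closed-loop prior-mean step from state (h, d) -> xhat."""
    mu_p, _ = prior_params(d, params.w_pmu, params.b_pmu, params.w_psig, params.b_psig)
    h1, d1 = mtrnn_step(h, d, mu_p, params, arch)
    return output(d1, params)


def error_regression(
    params: PVRNNParams,
    arch: Architecture,
    x: np.ndarray,
    cfg: RegressionConfig,
    *,
    w: tuple[float, ...] | None = None,
    a_init: AdaptiveVariables | None = None,
) -> RegressionResult:
    """Online posterior inference over a test sequence (weights frozen).

    Parameters
    ----------
    x
        Observed (T, n_out) sequence.
    w
        Learning-phase meta-prior of the network; used when
        ``cfg.w_test`` is None.
    a_init
        Optional initial adaptive variables (e.g. the trained a of a
        training sequence); defaults to zeros.

    Returns predictions aligned so that ``predictions[t]`` is issued
    before x_t is observed (predictions[0] comes from the untrained
    zero state).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != arch.n_out:
        raise ValueError(f"x must be (T, {arch.n_out})")
    T = x.shape[0]
    w_test = cfg.w_test
    if w_test is None:
        if w is None:
            raise ValueError("need w_test or the network's learning-phase w")
        w_test = tuple(w)

    if a_init is None:
        a = AdaptiveVariables.zeros(1, T, arch.n_z)
    else:
        a = AdaptiveVariables(a_init.a_mu.copy(), a_init.a_sig.copy())
        if a.a_mu.shape != (1, T, arch.n_z):
            raise ValueError("a_init shape mismatch")

    predictions = np.empty((T, arch.n_out))
    losses = np.empty((T, cfg.iters))
    # frozen state just before the current window
    h_base = np.zeros((1, arch.n_d))
    d_base = np.zeros((1, arch.n_d))
    base = 0  # first step inside the window

    predictions[0] = _predict_next(params, arch, h_base, d_base)[0]

    for t in range(T):
        start = max(0, t - cfg.window + 1)
        # steps that left the window are frozen; advance the base state
        while base < start:
            mu_q = np.tanh(a.a_mu[:, base])
            h_base, d_base = mtrnn_step(h_base, d_base, mu_q, params, arch)
            base += 1
        if cfg.warm_start and t > 0:
            a.a_mu[:, t] = a.a_mu[:, t - 1]
            a.a_sig[:, t] = a.a_sig[:, t - 1]

        win = slice(start, t + 1)
        a_win = AdaptiveVariables(a.a_mu[:, win], a.a_sig[:, win])
        opt = Adam(
            {"a_mu": a_win.a_mu, "a_sig": a_win.a_sig}, lr=cfg.learning_rate
        )
        x_win = x[None, win]
        n_win = t + 1 - start
        trace = None
        for it in range(cfg.iters):
            trace = forward(
                params, arch, n_win, mode="posterior", a=a_win,
                h0=h_base, d0=d_base,
            )
            loss, _, _ = free_energy(x_win, trace, w_test, arch)
            losses[t, it] = loss
            _, a_grads = backward(
                params, arch, trace, x_win, w_test,
                need_weight_grads=False, d0=d_base,
            )
            opt.step({"a_mu": a_grads.a_mu, "a_sig": a_grads.a_sig})

        # state at the window end under the optimised posterior
        trace = forward(
            params, arch, n_win, mode="posterior", a=a_win, h0=h_base, d0=d_base
        )
        if t + 1 < T:
            predictions[t + 1] = _predict_next(
                params, arch, trace.h[:, -1], trace.d[:, -1]
            )[0]

    full_trace = forward(params, arch, T, mode="posterior", a=a)
    return RegressionResult(
        predictions=predictions, trace=full_trace, a=a, windowed_losses=losses
    )
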