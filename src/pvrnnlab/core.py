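"""PV-RNN: predictive-coding-inspired variational recurrent neural network.

The model couples deterministic multiple-timescale recurrent units ``d``
with Gaussian stochastic latents ``z``, one pair per layer of a small
hierarchy.  Per step and layer

    prior       p(z_t^l | d_{t-1}^l):   mu^p = tanh(W_mu d_{t-1}^l + b),
                                        sigma^p = exp(W_s d_{t-1}^l + c)
    posterior   q(z_t^l | a_t^l):       mu^q = tanh(a^mu_t),
                                        sigma^q = exp(a^sigma_t)
    dynamics    h_t^l = (1 - 1/tau_l) h_{t-1}^l
                        + (1/tau_l)(sum_m W_{m->l} d_{t-1}^m + W_z z_t^l + b)
                d_t^l = tanh(h_t^l)
    output      xhat_t = tanh(W_out d_t^1 + b_out)

with layer-restricted connectivity: layer l receives d from layers
l-1, l, l+1 only; z and the prior map never cross layers.  Higher
layers carry larger time constants tau, giving slow contextual dynamics
on top of fast motor-like dynamics.

Learning minimises the variational free energy

    L = sum_t 1/2 ||x_t - xhat_t||^2
        + sum_t sum_l w^l KL[ q(z_t^l) || p(z_t^l) ]

where the per-layer KL weight ``w^l`` — the *meta-prior* — controls how
strongly the posterior is pulled toward the learned prior, i.e. the
stochasticity of the acquired neural dynamics.

Implementation note: all layers are stacked into single ``d`` (sum n_d)
and ``z`` (sum n_z) vectors; the connectivity restriction is a binary
block mask multiplied into the weight matrices (and their gradients).
This is algebraically identical to the per-layer formulation and much
faster in NumPy.  Gradients are exact analytic backpropagation through
time over the full sequence; they are validated against finite
differences in the test suite.

All time indices are 0-based; the initial states h_0, d_0 are zero, so
the first-step prior is ``prior_params(0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

try:  # JIT for the two sequential carry loops; NumPy fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "LayerSpec",
    "Architecture",
    "PVRNNParams",
    "AdaptiveVariables",
    "MetaPriorConfig",
    "LatentTrace",
    "Clamp",
    "init_params",
    "prior_params",
    "posterior_params",
    "reparameterize",
    "mtrnn_step",
    "output",
    "kl_gaussians",
    "forward",
    "free_energy",
    "backward",
    "generate",
    "DEFAULT_ARCH",
]


@dataclass(frozen=True)
class LayerSpec:
    """Size and timescale of one layer."""

    n_d: int
    n_z: int
    tau: float

    def __post_init__(self) -> None:
        if self.n_d < 1 or self.n_z < 0 or self.tau < 1:
            raise ValueError("require n_d >= 1, n_z >= 0, tau >= 1")


#: 3-layer default: fast/large lower layer to slow/small higher layer
DEFAULT_ARCH: tuple[LayerSpec, ...] = (
    LayerSpec(20, 2, 2.0),
    LayerSpec(10, 2, 8.0),
    LayerSpec(10, 2, 32.0),
)


class Architecture:
    """Stacked-layer bookkeeping: slices, time constants, connectivity masks."""

    def __init__(self, layers: Sequence[LayerSpec] = DEFAULT_ARCH, n_out: int = 2):
        self.layers = tuple(layers)
        self.n_out = n_out
        self.L = len(self.layers)
        d_off = np.cumsum([0] + [l.n_d for l in self.layers])
        z_off = np.cumsum([0] + [l.n_z for l in self.layers])
        self.n_d = int(d_off[-1])
        self.n_z = int(z_off[-1])
        self.d_slices = [slice(int(d_off[i]), int(d_off[i + 1])) for i in range(self.L)]
        self.z_slices = [slice(int(z_off[i]), int(z_off[i + 1])) for i in range(self.L)]
        self.tau_d = np.concatenate(
            [np.full(l.n_d, l.tau, dtype=float) for l in self.layers]
        )
        # per-z-unit layer index, for per-layer KL weighting/aggregation
        self.z_layer = np.concatenate(
            [np.full(l.n_z, i, dtype=np.int64) for i, l in enumerate(self.layers)]
        )
        self.mask_dd = np.zeros((self.n_d, self.n_d))
        for lo in range(self.L):
            for li in range(self.L):
                if abs(lo - li) <= 1:
                    self.mask_dd[self.d_slices[lo], self.d_slices[li]] = 1.0
        self.mask_zd = np.zeros((self.n_d, self.n_z))
        self.mask_p = np.zeros((self.n_z, self.n_d))
        for l in range(self.L):
            self.mask_zd[self.d_slices[l], self.z_slices[l]] = 1.0
            self.mask_p[self.z_slices[l], self.d_slices[l]] = 1.0
        self.mask_out = np.zeros((n_out, self.n_d))
        self.mask_out[:, self.d_slices[0]] = 1.0

    def w_units(self, w: Sequence[float]) -> np.ndarray:
        """Per-z-unit KL weight vector from a per-layer weight list."""
        w = np.asarray(w, dtype=float)
        if w.shape != (self.L,):
            raise ValueError(f"need one meta-prior per layer ({self.L})")
        if np.any(w < 0):
            raise ValueError("meta-priors must be nonnegative")
        return w[self.z_layer]

    def unit_index(self, layer: int, unit: int) -> int:
        """Global z-unit index of `unit` within `layer` (both 0-based)."""
        sl = self.z_slices[layer]
        if not 0 <= unit < sl.stop - sl.start:
            raise IndexError(f"layer {layer} has no z unit {unit}")
        return sl.start + unit


@dataclass(frozen=True)
class MetaPriorConfig:
    """Per-layer KL weights for the learning and test phases."""

    w: tuple[float, ...]
    w_test: tuple[float, ...] | None = None

    def resolved_test(self) -> tuple[float, ...]:
        return self.w if self.w_test is None else self.w_test

    @classmethod
    def preset(cls, name: str, L: int = 3) -> "MetaPriorConfig":
        """'weak'/'normal'/'strong' set the lowest layer's w to 0.1/1/10."""
        lower = {"weak": 0.1, "normal": 1.0, "strong": 10.0}[name]
        return cls(w=tuple([lower] + [1.0] * (L - 1)))


@dataclass
class PVRNNParams:
    """All synaptic weights, as masked stacked matrices."""

    w_dd: np.ndarray  # (n_d, n_d) d_{t-1} -> h_t, block-tridiagonal by layer
    w_zd: np.ndarray  # (n_d, n_z) z_t -> h_t, block-diagonal
    b_d: np.ndarray  # (n_d,)
    w_pmu: np.ndarray  # (n_z, n_d) prior mean map, block-diagonal
    b_pmu: np.ndarray  # (n_z,)
    w_psig: np.ndarray  # (n_z, n_d) prior log-sigma map, block-diagonal
    b_psig: np.ndarray  # (n_z,)
    w_out: np.ndarray  # (n_out, n_d), reads the lowest layer only
    b_out: np.ndarray  # (n_out,)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def copy(self) -> "PVRNNParams":
        return PVRNNParams(**{k: v.copy() for k, v in self.as_dict().items()})

    def mask_dict(self, arch: Architecture) -> dict[str, np.ndarray | None]:
        return {
            "w_dd": arch.mask_dd,
            "w_zd": arch.mask_zd,
            "b_d": None,
            "w_pmu": arch.mask_p,
            "b_pmu": None,
            "w_psig": arch.mask_p,
            "b_psig": None,
            "w_out": arch.mask_out,
            "b_out": None,
        }


@dataclass
class AdaptiveVariables:
    """Per-sequence, per-step posterior parameters a_t (one pair per z unit).

    ``a_mu`` and ``a_sig`` have shape (n_seq, T, n_z); the posterior is
    mu^q = tanh(a_mu), sigma^q = exp(a_sig), so zero initialisation
    gives a squashed unit Gaussian.
    """

    a_mu: np.ndarray
    a_sig: np.ndarray

    @classmethod
    def zeros(cls, n_seq: int, T: int, n_z: int) -> "AdaptiveVariables":
        return cls(np.zeros((n_seq, T, n_z)), np.zeros((n_seq, T, n_z)))


@dataclass
class LatentTrace:
    """Per-step record of one (possibly batched) forward pass.

    All arrays have leading dims (B, T, ...); B indexes sequences (or
    traversal grid points), T time steps.
    """

    h: np.ndarray  # (B, T, n_d)
    d: np.ndarray  # (B, T, n_d)
    mu_p: np.ndarray  # (B, T, n_z)
    sig_p: np.ndarray  # (B, T, n_z)
    mu_q: np.ndarray | None  # posterior-mode only
    sig_q: np.ndarray | None
    z: np.ndarray  # (B, T, n_z)
    x_hat: np.ndarray  # (B, T, n_out)
    eps: np.ndarray | None = None
    mode: str = "posterior"
    clamp: "Clamp | None" = None


@dataclass(frozen=True)
class Clamp:
    """Fix one latent unit during generation.

    channel 'mean': the sampled z entry is replaced by ``value``;
    channel 'variance': sigma^p of the unit is replaced by exp(value).
    ``value`` may be a scalar or a (B,) vector (one value per batch row,
    used to traverse a whole grid in one batched rollout).
    """

    unit: int
    channel: str
    value: float | np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in ("mean", "variance"):
            raise ValueError("clamp channel must be 'mean' or 'variance'")


# ---------------------------------------------------------------------------
# elementary operations (single-step, used directly in tests and docs)
# ---------------------------------------------------------------------------

def prior_params(
    d_prev: np.ndarray, w_mu: np.ndarray, b_mu: np.ndarray,
    w_sig: np.ndarray, b_sig: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian prior of z_t from the previous deterministic state."""
    mu = np.tanh(d_prev @ w_mu.T + b_mu)
    sig = np.exp(d_prev @ w_sig.T + b_sig)
    return mu, sig


def posterior_params(a_mu: np.ndarray, a_sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Approximate posterior of z_t from the adaptive variables."""
    return np.tanh(a_mu), np.exp(a_sig)


def reparameterize(mu: np.ndarray, sig: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps (pathwise sampling)."""
    return mu + sig * eps


def mtrnn_step(
    h_prev: np.ndarray,
    d_prev: np.ndarray,
    z_t: np.ndarray,
    params: PVRNNParams,
    arch: Architecture,
) -> tuple[np.ndarray, np.ndarray]:
    """One leaky-integrator update of all layers.

    h_t = (1 - 1/tau) h_{t-1} + (1/tau)(W_dd d_{t-1} + W_zd z_t + b);
    d_t = tanh(h_t).  The block masks in the weights realise the
    neighbour-restricted hierarchy.
    """
    inp = d_prev @ params.w_dd.T + z_t @ params.w_zd.T + params.b_d
    h_t = (1.0 - 1.0 / arch.tau_d) * h_prev + inp / arch.tau_d
    return h_t, np.tanh(h_t)


def output(d_t: np.ndarray, params: PVRNNParams) -> np.ndarray:
    """Predicted observation from the lowest layer: tanh(W_out d^1 + b)."""
    return np.tanh(d_t @ params.w_out.T + params.b_out)


def kl_gaussians(
    mu_q: np.ndarray, sig_q: np.ndarray, mu_p: np.ndarray, sig_p: np.ndarray,
) -> float:
    """KL[q || p] for diagonal Gaussians, summed over all dimensions."""
    mu_q, sig_q, mu_p, sig_p = map(np.asarray, (mu_q, sig_q, mu_p, sig_p))
    if np.any(sig_q <= 0) or np.any(sig_p <= 0):
        raise ValueError("standard deviations must be positive")
    return float(np.sum(_kl_elem(mu_q, sig_q, mu_p, sig_p)))


def _kl_elem(mu_q, sig_q, mu_p, sig_p):
    return (
        np.log(sig_p / sig_q)
        + (sig_q**2 + (mu_q - mu_p) ** 2) / (2.0 * sig_p**2)
        - 0.5
    )


# ---------------------------------------------------------------------------
# sequential carry kernels (the only per-step loops in training/inference)
# ---------------------------------------------------------------------------

def _fwd_carry_np(h, d, z_in, w_dd, leak, inv_tau, tr_h, tr_d):
    T = z_in.shape[1]
    for t in range(T):
        h = leak * h + inv_tau * (d @ w_dd.T + z_in[:, t])
        d = np.tanh(h)
        tr_h[:, t] = h
        tr_d[:, t] = d


def _bwd_carry_np(g_d_local, g_dprev_prior, one_minus_d2, w_dd, inv_tau, leak, g_inp):
    B, T, nd = g_d_local.shape
    g_h_next = np.zeros((B, nd))
    g_d_next = np.zeros((B, nd))
    for t in range(T - 1, -1, -1):
        g_h = (g_d_local[:, t] + g_d_next) * one_minus_d2[:, t] + g_h_next
        g_inp_t = g_h * inv_tau
        g_inp[:, t] = g_inp_t
        g_d_next = g_inp_t @ w_dd + g_dprev_prior[:, t]
        g_h_next = g_h * leak


if _njit is not None:

    @_njit(cache=True)
    def _fwd_carry(h, d, z_in, w_dd, leak, inv_tau, tr_h, tr_d):  # pragma: no cover
        B, T, nd = z_in.shape
        for t in range(T):
            for b in range(B):
                for i in range(nd):
                    acc = 0.0
                    for j in range(nd):
                        acc += w_dd[i, j] * d[b, j]
                    h[b, i] = leak[i] * h[b, i] + inv_tau[i] * (acc + z_in[b, t, i])
            for b in range(B):
                for i in range(nd):
                    d[b, i] = np.tanh(h[b, i])
                    tr_h[b, t, i] = h[b, i]
                    tr_d[b, t, i] = d[b, i]

    @_njit(cache=True)
    def _bwd_carry(
        g_d_local, g_dprev_prior, one_minus_d2, w_dd, inv_tau, leak, g_inp
    ):  # pragma: no cover
        B, T, nd = g_d_local.shape
        g_h_next = np.zeros((B, nd))
        g_d_next = np.zeros((B, nd))
        for t in range(T - 1, -1, -1):
            for b in range(B):
                for i in range(nd):
                    gh = (
                        (g_d_local[b, t, i] + g_d_next[b, i]) * one_minus_d2[b, t, i]
                        + g_h_next[b, i]
                    )
                    g_inp[b, t, i] = gh * inv_tau[i]
                    g_h_next[b, i] = gh * leak[i]
            for b in range(B):
                for i in range(nd):
                    acc = 0.0
                    for j in range(nd):
                        acc += g_inp[b, t, j] * w_dd[j, i]
                    g_d_next[b, i] = acc + g_dprev_prior[b, t, i]

else:  # pragma: no cover
    _fwd_carry = _fwd_carry_np
    _bwd_carry = _bwd_carry_np


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def init_params(arch: Architecture, rng: np.random.Generator) -> PVRNNParams:
    """Normal(0, 1/fan_in) weights on the unmasked support; zero biases."""

    def _w(mask: np.ndarray) -> np.ndarray:
        fan_in = mask.sum(axis=1, keepdims=True)
        std = np.where(fan_in > 0, 1.0 / np.sqrt(np.maximum(fan_in, 1.0)), 0.0)
        return rng.standard_normal(mask.shape) * std * mask

    return PVRNNParams(
        w_dd=_w(arch.mask_dd),
        w_zd=_w(arch.mask_zd),
        b_d=np.zeros(arch.n_d),
        w_pmu=_w(arch.mask_p),
        b_pmu=np.zeros(arch.n_z),
        w_psig=_w(arch.mask_p),
        b_psig=np.zeros(arch.n_z),
        w_out=_w(arch.mask_out),
        b_out=np.zeros(arch.n_out),
    )


# ---------------------------------------------------------------------------
# sequence-level forward / loss / backward
# ---------------------------------------------------------------------------

def forward(
    params: PVRNNParams,
    arch: Architecture,
    T: int,
    *,
    mode: str = "posterior",
    a: AdaptiveVariables | None = None,
    eps: np.ndarray | None = None,
    clamp: Clamp | None = None,
    h0: np.ndarray | None = None,
    d0: np.ndarray | None = None,
    batch: int | None = None,
) -> LatentTrace:
    """Run the network for T steps.

    mode 'posterior'     z ~ q (requires ``a``; ``eps`` of shape
                         (B, T, n_z), or None for the posterior mean)
    mode 'prior_sample'  z ~ p (closed-loop generation; ``eps`` or a
                         zero stream if None)
    mode 'prior_mean'    z = mu^p (deterministic generation)
    """
    if mode not in ("posterior", "prior_sample", "prior_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "posterior":
        if a is None:
            raise ValueError("posterior mode requires adaptive variables")
        B = a.a_mu.shape[0]
        if a.a_mu.shape[1] < T:
            raise ValueError("adaptive variables shorter than T")
    else:
        B = batch if batch is not None else (eps.shape[0] if eps is not None else 1)
    if eps is None and mode != "prior_mean":
        eps = np.zeros((B, T, arch.n_z))

    nd, nz = arch.n_d, arch.n_z
    h = np.zeros((B, nd)) if h0 is None else np.broadcast_to(h0, (B, nd)).copy()
    d = np.zeros((B, nd)) if d0 is None else np.broadcast_to(d0, (B, nd)).copy()
    d_init = d.copy()

    clamp_val = None
    if clamp is not None:
        clamp_val = np.broadcast_to(np.asarray(clamp.value, dtype=float), (B,))

    tr_h = np.empty((B, T, nd))
    tr_d = np.empty((B, T, nd))
    leak = 1.0 - 1.0 / arch.tau_d
    inv_tau = 1.0 / arch.tau_d

    if mode == "posterior":
        # In posterior mode the prior never feeds the dynamics, and the
        # posterior never reads d, so everything except the recurrent
        # carry vectorises over time.
        tr_mq = np.tanh(a.a_mu[:, :T])
        tr_sq = np.exp(a.a_sig[:, :T])
        tr_z = tr_mq + tr_sq * eps[:, :T]
        if clamp is not None and clamp.channel == "mean":
            tr_z[:, :, clamp.unit] = clamp_val[:, None]
        z_in = tr_z @ params.w_zd.T + params.b_d  # (B, T, nd)
        _fwd_carry(h, d, z_in, params.w_dd, leak, inv_tau, tr_h, tr_d)
        d_prev = np.concatenate([d_init[:, None], tr_d[:, :-1]], axis=1)
        tr_mp = np.tanh(d_prev @ params.w_pmu.T + params.b_pmu)
        tr_sp = np.exp(d_prev @ params.w_psig.T + params.b_psig)
        if clamp is not None and clamp.channel == "variance":
            tr_sp[:, :, clamp.unit] = np.exp(clamp_val)[:, None]
    else:
        tr_mq = tr_sq = None
        tr_mp = np.empty((B, T, nz))
        tr_sp = np.empty((B, T, nz))
        tr_z = np.empty((B, T, nz))
        for t in range(T):
            mu_p, sig_p = prior_params(
                d, params.w_pmu, params.b_pmu, params.w_psig, params.b_psig
            )
            if clamp is not None and clamp.channel == "variance":
                sig_p[:, clamp.unit] = np.exp(clamp_val)
            z = reparameterize(mu_p, sig_p, eps[:, t]) if mode == "prior_sample" else mu_p.copy()
            if clamp is not None and clamp.channel == "mean":
                z[:, clamp.unit] = clamp_val
            h, d = mtrnn_step(h, d, z, params, arch)
            tr_mp[:, t], tr_sp[:, t] = mu_p, sig_p
            tr_z[:, t], tr_h[:, t], tr_d[:, t] = z, h, d

    tr_x = np.tanh(tr_d @ params.w_out.T + params.b_out)
    return LatentTrace(
        h=tr_h, d=tr_d, mu_p=tr_mp, sig_p=tr_sp, mu_q=tr_mq, sig_q=tr_sq,
        z=tr_z, x_hat=tr_x, eps=eps, mode=mode, clamp=clamp,
    )


def free_energy(
    x: np.ndarray,
    trace: LatentTrace,
    w: Sequence[float],
    arch: Architecture,
) -> tuple[float, float, np.ndarray]:
    """Meta-prior-weighted variational free energy of a posterior trace.

    Returns (loss, reconstruction term, per-layer KL sums).  The
    reconstruction term is the Gaussian negative log likelihood with
    fixed unit output variance, i.e. sum_t ||x_t - xhat_t||^2 / 2,
    summed over batch; KL sums are over batch and time, per layer.
    """
    if trace.mode != "posterior":
        raise ValueError("free energy requires a posterior-driven trace")
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.shape != trace.x_hat.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs x_hat {trace.x_hat.shape}")
    recon = 0.5 * float(np.sum((x - trace.x_hat) ** 2))
    kl_unit = _kl_elem(trace.mu_q, trace.sig_q, trace.mu_p, trace.sig_p)
    kl_layers = np.array(
        [float(np.sum(kl_unit[:, :, sl])) for sl in arch.z_slices]
    )
    w = np.asarray(w, dtype=float)
    loss = recon + float(np.sum(w * kl_layers))
    return loss, recon, kl_layers


def backward(
    params: PVRNNParams,
    arch: Architecture,
    trace: LatentTrace,
    x: np.ndarray,
    w: Sequence[float],
    *,
    need_weight_grads: bool = True,
    d0: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray] | None, AdaptiveVariables]:
    """Exact gradients of the free energy via BPTT.

    Returns (weight gradients summed over the batch, per-sequence
    gradients w.r.t. the adaptive variables).  ``trace`` must come from
    a posterior-mode forward pass on ``x``; if that pass started from a
    nonzero deterministic state, pass the same ``d0``.
    """
    if trace.mode != "posterior":
        raise ValueError("backward requires a posterior-driven trace")
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    B, T, _ = trace.x_hat.shape
    w_unit = arch.w_units(w)
    inv_tau = 1.0 / arch.tau_d
    leak = 1.0 - inv_tau
    d_init = (
        np.zeros((B, arch.n_d)) if d0 is None
        else np.broadcast_to(d0, (B, arch.n_d))
    )
    eps = trace.eps
    mu_p, sig_p = trace.mu_p, trace.sig_p
    mu_q, sig_q = trace.mu_q, trace.sig_q

    # ---- time-local gradient sources, vectorised over (B, T) ----
    g_opre = (trace.x_hat - x) * (1.0 - trace.x_hat**2)
    g_d_local = g_opre @ params.w_out  # output head -> d_t

    inv_sp2 = 1.0 / sig_p**2
    diff = mu_q - mu_p
    g_muq_kl = w_unit * diff * inv_sp2
    g_sigq_kl = w_unit * (-1.0 / sig_q + sig_q * inv_sp2)
    g_sigp = w_unit * (1.0 / sig_p - (sig_q**2 + diff**2) / sig_p**3)
    g_pmu_pre = -g_muq_kl * (1.0 - mu_p**2)
    g_psig_pre = g_sigp * sig_p
    # prior maps read d_{t-1}: their pull on d_t arrives at step t+1
    g_dprev_prior = g_pmu_pre @ params.w_pmu + g_psig_pre @ params.w_psig

    # ---- reverse recurrent carry (the only sequential part) ----
    g_inp = np.empty((B, T, arch.n_d))
    one_minus_d2 = 1.0 - trace.d**2
    _bwd_carry(
        np.ascontiguousarray(g_d_local), np.ascontiguousarray(g_dprev_prior),
        one_minus_d2, params.w_dd, inv_tau, leak, g_inp,
    )

    # ---- adaptive-variable gradients ----
    g_z = g_inp @ params.w_zd
    g_muq = g_muq_kl + g_z
    g_sigq = g_sigq_kl + (g_z * eps[:, :T] if eps is not None else 0.0)
    a_grads = AdaptiveVariables(
        a_mu=g_muq * (1.0 - mu_q**2), a_sig=g_sigq * sig_q
    )
    if not need_weight_grads:
        return None, a_grads

    # ---- weight gradients as flat (B*T) matmuls ----
    nd = arch.n_d
    d_flat = trace.d.reshape(B * T, nd)
    d_prev = np.concatenate([d_init[:, None], trace.d[:, :-1]], axis=1)
    d_prev_flat = d_prev.reshape(B * T, nd)
    g_inp_flat = g_inp.reshape(B * T, nd)
    g = {
        "w_out": g_opre.reshape(B * T, -1).T @ d_flat,
        "b_out": g_opre.sum(axis=(0, 1)),
        "w_dd": g_inp_flat.T @ d_prev_flat,
        "w_zd": g_inp_flat.T @ trace.z.reshape(B * T, -1),
        "b_d": g_inp.sum(axis=(0, 1)),
        "w_pmu": g_pmu_pre.reshape(B * T, -1).T @ d_prev_flat,
        "b_pmu": g_pmu_pre.sum(axis=(0, 1)),
        "w_psig": g_psig_pre.reshape(B * T, -1).T @ d_prev_flat,
        "b_psig": g_psig_pre.sum(axis=(0, 1)),
    }
    for k, m in params.mask_dict(arch).items():
        if m is not None:
            g[k] *= m
    return g, a_grads


def generate(
    params: PVRNNParams,
    arch: Architecture,
    T: int,
    *,
    mode: str = "prior_sample",
    clamp: Clamp | None = None,
    rng: np.random.Generator | None = None,
    batch: int = 1,
    h0: np.ndarray | None = None,
    d0: np.ndarray | None = None,
) -> LatentTrace:
    """Closed-loop top-down rollout of T steps from the prior.

    ``prior_sample`` draws z from the learned prior (needs ``rng``);
    ``prior_mean`` uses z = mu^p deterministically.  An optional
    ``clamp`` fixes one latent unit for the whole rollout (latent-space
    traversal); with a batched clamp value, a whole traversal grid runs
    as one batch, each row with its own noise stream from ``rng``.
    """
    if T < 1:
        raise ValueError("T must be positive")
    if clamp is not None and not 0 <= clamp.unit < arch.n_z:
        raise IndexError(f"clamp unit {clamp.unit} out of range")
    eps = None
    if mode == "prior_sample":
        if rng is None:
            raise ValueError("prior_sample mode requires an rng")
        # independent noise per batch row (each traversal grid point gets
        # its own fixed stream): a clamped unit only earns a high
        # grid-property correlation if its causal effect exceeds the
        # generation noise
        eps = rng.standard_normal((batch, T, arch.n_z))
    return forward(
        params, arch, T, mode=mode, eps=eps, clamp=clamp, batch=batch, h0=h0, d0=d0
    )
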