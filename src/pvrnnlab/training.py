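"""Developmental learning: joint optimisation of weights and adaptive variables.

The learning phase minimises the meta-prior-weighted free energy over
the whole training corpus by full-sequence backpropagation through time
(no truncation), updating synaptic weights and the per-sequence
adaptive variables a_t with Adam.  By default one optimizer step is
taken per sequence, in an epoch-wise shuffled order: the gradient noise
of per-sequence stepping reliably breaks the mean-trajectory plateau
that full-batch gradients sit on with these small corpora (a batch mode
remains available via ``batch_gradient=True``).

Two presets are provided: the full-scale corpus (18 sequences of 512
steps, 5e4 epochs) and a scaled-down preset (6 sequences of 256 steps,
1.5e3 epochs) whose per-network cost suits repeated multi-condition
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    AdaptiveVariables,
    Architecture,
    MetaPriorConfig,
    PVRNNParams,
    backward,
    forward,
    free_energy,
    init_params,
)
from .environment import TrajectorySequence
from .optim import Adam

__all__ = [
    "TrainConfig", "TrainedNetwork", "train_network", "train_condition",
    "save_checkpoint", "load_checkpoint", "SCALED_BIASES",
]

#: six-bias corpus of the scaled-down preset (three per side of 0.5)
SCALED_BIASES: tuple[float, ...] = (0.98, 0.76, 0.65, 0.43, 0.32, 0.10)


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the developmental learning phase."""

    epochs: int = 50_000
    learning_rate: float = 1e-3
    learning_rate_a: float | None = None  # None -> 10 x learning_rate
    batch_gradient: bool = False  # True: one summed step per epoch
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    meta_prior: MetaPriorConfig = field(default_factory=lambda: MetaPriorConfig.preset("normal"))
    seed: int = 0
    n_networks: int = 20

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.learning_rate <= 0 or self.n_networks < 1:
            raise ValueError("invalid training configuration")

    @property
    def lr_a(self) -> float:
        # adaptive variables are per-step sequence memory: they tolerate
        # (and need) a much faster rate than the shared synaptic weights
        return 10.0 * self.learning_rate if self.learning_rate_a is None else self.learning_rate_a

    @classmethod
    def scaled(cls, **kw) -> "TrainConfig":
        """Reduced-cost preset for repeated condition-grid runs."""
        kw.setdefault("epochs", 1_500)
        kw.setdefault("learning_rate", 2e-3)
        return cls(**kw)


@dataclass
class TrainedNetwork:
    """A trained PV-RNN plus its learning history and provenance."""

    params: PVRNNParams
    a: AdaptiveVariables
    arch: Architecture
    meta_prior: MetaPriorConfig
    seed: int
    history: np.ndarray  # (epochs, 2 + L): loss, recon, KL per layer
    condition: dict = field(default_factory=dict)


def train_network(
    corpus: list[TrajectorySequence],
    arch: Architecture,
    cfg: TrainConfig,
) -> TrainedNetwork:
    """Train one network on a corpus of equal-length sequences.

    Fresh reparameterisation noise is drawn every epoch from a seeded
    generator, so identical (corpus, cfg) runs are bit-reproducible.
    Raises ``FloatingPointError`` with the epoch index if the loss goes
    non-finite.
    """
    if not corpus:
        raise ValueError("corpus must be nonempty")
    T = len(corpus[0])
    if any(len(s) != T for s in corpus):
        raise ValueError("all corpus sequences must have equal length")
    B = len(corpus)
    x = np.stack([s.x for s in corpus])

    rng = np.random.default_rng(cfg.seed)
    params = init_params(arch, rng)
    a = AdaptiveVariables.zeros(B, T, arch.n_z)
    w = cfg.meta_prior.w

    opt_w = Adam(params.as_dict(), lr=cfg.learning_rate, beta1=cfg.beta1,
                 beta2=cfg.beta2, eps=cfg.adam_eps)
    if cfg.batch_gradient:
        opt_a = Adam({"a_mu": a.a_mu, "a_sig": a.a_sig}, lr=cfg.lr_a,
                     beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.adam_eps)
    else:
        opt_a_seq = [
            Adam({"a_mu": a.a_mu[b : b + 1], "a_sig": a.a_sig[b : b + 1]},
                 lr=cfg.lr_a, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.adam_eps)
            for b in range(B)
        ]

    history = np.empty((cfg.epochs, 2 + arch.L))
    for epoch in range(cfg.epochs):
        if cfg.batch_gradient:
            eps = rng.standard_normal((B, T, arch.n_z))
            trace = forward(params, arch, T, mode="posterior", a=a, eps=eps)
            loss, recon, kl_layers = free_energy(x, trace, w, arch)
            history[epoch, 0], history[epoch, 1] = loss, recon
            history[epoch, 2:] = kl_layers
            grads, a_grads = backward(params, arch, trace, x, w)
            opt_w.step(grads)
            opt_a.step({"a_mu": a_grads.a_mu, "a_sig": a_grads.a_sig})
        else:
            ep = np.zeros(2 + arch.L)
            for b in rng.permutation(B):
                eps = rng.standard_normal((1, T, arch.n_z))
                ab = AdaptiveVariables(a.a_mu[b : b + 1], a.a_sig[b : b + 1])
                trace = forward(params, arch, T, mode="posterior", a=ab, eps=eps)
                loss, recon, kl_layers = free_energy(x[b : b + 1], trace, w, arch)
                ep += np.concatenate([[loss, recon], kl_layers])
                grads, a_grads = backward(params, arch, trace, x[b : b + 1], w)
                opt_w.step(grads)
                opt_a_seq[b].step({"a_mu": a_grads.a_mu, "a_sig": a_grads.a_sig})
            history[epoch] = ep
        if not np.isfinite(history[epoch, 0]):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: "
                f"recon={history[epoch, 1]}, kl={history[epoch, 2:]}"
            )

    return TrainedNetwork(
        params=params, a=a, arch=arch, meta_prior=cfg.meta_prior,
        seed=cfg.seed, history=history,
    )


def train_condition(
    corpus: list[TrajectorySequence],
    arch: Architecture,
    cfg: TrainConfig,
    *,
    condition: dict | None = None,
) -> list[TrainedNetwork]:
    """Train ``cfg.n_networks`` independent networks (seeds seed+i)."""
    nets = []
    for i in range(cfg.n_networks):
        net = train_network(corpus, arch, replace(cfg, seed=cfg.seed + i))
        net.condition = dict(condition or {})
        nets.append(net)
    return nets


def save_checkpoint(net: TrainedNetwork, path) -> None:
    """Write a trained network as a ``.npz`` archive.

    Schema: ``layers`` (L x 3 array of n_d, n_z, tau), ``meta_prior_w``,
    ``meta_prior_w_test`` (empty when unset), ``seed``, the named weight
    arrays of ``PVRNNParams``, and the adaptive variables ``a_mu``,
    ``a_sig`` (n_seq x T x n_z).
    """
    blobs: dict[str, np.ndarray] = {
        "layers": np.array(
            [(l.n_d, l.n_z, l.tau) for l in net.arch.layers], dtype=float
        ),
        "meta_prior_w": np.asarray(net.meta_prior.w, dtype=float),
        "meta_prior_w_test": np.asarray(
            net.meta_prior.w_test if net.meta_prior.w_test is not None else [],
            dtype=float,
        ),
        "seed": np.array([net.seed]),
        "a_mu": net.a.a_mu,
        "a_sig": net.a.a_sig,
    }
    blobs.update(net.params.as_dict())
    np.savez(path, **blobs)


def load_checkpoint(path) -> TrainedNetwork:
    """Rebuild a :class:`TrainedNetwork` saved by :func:`save_checkpoint`."""
    from .core import Architecture, LayerSpec, MetaPriorConfig, PVRNNParams

    with np.load(path) as z:
        arch = Architecture(
            tuple(LayerSpec(int(nd), int(nz), float(tau)) for nd, nz, tau in z["layers"])
        )
        w_test = tuple(float(v) for v in z["meta_prior_w_test"]) or None
        params = PVRNNParams(
            **{k: z[k] for k in PVRNNParams.__dataclass_fields__}
        )
        return TrainedNetwork(
            params=params,
            a=AdaptiveVariables(z["a_mu"], z["a_sig"]),
            arch=arch,
            meta_prior=MetaPriorConfig(w=tuple(float(v) for v in z["meta_prior_w"]), w_test=w_test),
            seed=int(z["seed"][0]),
            history=np.empty((0, 2 + arch.L)),
        )
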