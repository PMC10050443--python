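"""Condition-grid orchestration and statistical analysis.

The experimental design crosses three meta-prior conditions (weak /
normal / strong, i.e. lower-layer KL weight 0.1 / 1.0 / 10) with two
environments (stable / noisy signal noise).  For each condition a
corpus is generated, n independent networks are trained, each network
runs error regression on a freshly generated context-switching test
sequence, and behavioural flexibility, cognitive flexibility and the
per-layer generative hierarchy are recorded — one tidy row per network.

Analysis helpers reproduce the summary pipeline: per-condition 1.5 x
IQR outlier removal, between-subject one-way and two-way ANOVA (Type
III sums of squares, since cells can be unbalanced after outlier
removal), simple effects against the pooled error term, and Shaffer's
modified sequentially rejective Bonferroni post-hoc for three groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Architecture, MetaPriorConfig
from .environment import EnvConfig, build_test_sequence, build_training_set
from .inference import RegressionConfig, error_regression
from .metrics import behavioral_flexibility, cognitive_flexibility
from .training import SCALED_BIASES, TrainConfig, train_network
from .traversal import DEFAULT_GRID, generative_hierarchy

__all__ = [
    "AnovaResult",
    "GridConfig",
    "run_grid",
    "iqr_filter",
    "anova_oneway",
    "anova_twoway",
    "simple_effects",
    "pairwise_pooled_t",
    "shaffer_posthoc",
    "META_PRIOR_LEVELS",
    "ENVIRONMENTS",
]

META_PRIOR_LEVELS = ("weak", "normal", "strong")
ENVIRONMENTS = ("stable", "noisy")


@dataclass(frozen=True)
class AnovaResult:
    """One F test: effect name, F, (df between, df within), p."""

    effect: str
    F: float
    df: tuple[int, int]
    p: float


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def iqr_filter(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier split: keep Q1 - k*IQR <= v <= Q3 + k*IQR.

    Quartiles use the linear-interpolation convention of
    ``numpy.percentile``.  Fewer than 4 values: nothing is removed and
    a warning is issued.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; IQR filter skipped", stacklevel=2)
        return values, np.array([])
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Between-subject one-way ANOVA from group sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df1, df2 = len(groups) - 1, N - len(groups)
    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else float("inf")
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(F, df1, df2))
    return AnovaResult("group", float(F), (df1, df2), p)


def _two_way_cells(df: pd.DataFrame, value: str, a: str, b: str):
    levels_a = list(pd.unique(df[a]))
    levels_b = list(pd.unique(df[b]))
    cells = {}
    for la in levels_a:
        for lb in levels_b:
            v = df.loc[(df[a] == la) & (df[b] == lb), value].to_numpy(dtype=float)
            if v.size == 0:
                raise ValueError(f"empty cell ({la}, {lb})")
            cells[(la, lb)] = v
    return levels_a, levels_b, cells


def anova_twoway(
    df: pd.DataFrame,
    value: str = "value",
    a: str = "meta_prior",
    b: str = "environment",
) -> list[AnovaResult]:
    """Between-subject two-way ANOVA with Type-III sums of squares.

    Fits the full cell-means model by OLS with sum-to-zero effect
    coding and tests each term by model comparison against the full
    model (marginal, order-independent — appropriate for the unbalanced
    cells left by outlier filtering).
    """
    levels_a, levels_b, cells = _two_way_cells(df, value, a, b)
    y = df[value].to_numpy(dtype=float)
    n = len(y)

    def _effect_cols(codes, levels):
        # sum-to-zero coding: one column per non-reference level
        cols = []
        for lev in levels[:-1]:
            c = np.where(codes == lev, 1.0, 0.0) - np.where(codes == levels[-1], 1.0, 0.0)
            cols.append(c)
        return cols

    ca = df[a].to_numpy()
    cb = df[b].to_numpy()
    cols_a = _effect_cols(ca, levels_a)
    cols_b = _effect_cols(cb, levels_b)
    cols_ab = [x * z for x in cols_a for z in cols_b]
    intercept = [np.ones(n)]

    def _rss(cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full_cols = intercept + cols_a + cols_b + cols_ab
    rss_full = _rss(full_cols)
    df_err = n - len(full_cols)
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_err

    out = []
    for name, drop, df1 in (
        (a, cols_a, len(levels_a) - 1),
        (b, cols_b, len(levels_b) - 1),
        (f"{a}:{b}", cols_ab, (len(levels_a) - 1) * (len(levels_b) - 1)),
    ):
        reduced = [c for c in full_cols if not any(c is dcol for dcol in drop)]
        ss = _rss(reduced) - rss_full
        if mse == 0.0:
            F = 0.0 if ss <= 1e-12 else float("inf")
            p = 1.0 if ss <= 1e-12 else 0.0
        else:
            F = (ss / df1) / mse
            p = float(sps.f.sf(F, df1, df_err))
        out.append(AnovaResult(name, float(F), (df1, df_err), p))
    return out


def simple_effects(
    df: pd.DataFrame,
    value: str = "value",
    a: str = "meta_prior",
    b: str = "environment",
) -> dict[str, AnovaResult]:
    """Simple effect of ``b`` at each level of ``a``, pooled error term.

    The error term (MSE and its df) comes from the full two-way model;
    ``b`` must have exactly two levels.
    """
    levels_a, levels_b, cells = _two_way_cells(df, value, a, b)
    if len(levels_b) != 2:
        raise ValueError("simple effects implemented for a two-level factor")
    # pooled within-cell error of the full model
    rss = sum(float(np.sum((v - v.mean()) ** 2)) for v in cells.values())
    df_err = len(df) - len(cells)
    mse = rss / df_err
    out = {}
    for la in levels_a:
        v1, v2 = cells[(la, levels_b[0])], cells[(la, levels_b[1])]
        ss = (v1.mean() - v2.mean()) ** 2 / (1.0 / len(v1) + 1.0 / len(v2))
        if mse == 0.0:
            F = 0.0 if ss <= 1e-12 else float("inf")
            p = 1.0 if ss <= 1e-12 else 0.0
        else:
            F = ss / mse
            p = float(sps.f.sf(F, 1, df_err))
        out[str(la)] = AnovaResult(f"{b} | {a}={la}", float(F), (1, df_err), p)
    return out


def pairwise_pooled_t(
    groups: dict[str, np.ndarray]
) -> dict[tuple[str, str], tuple[float, int, float]]:
    """Pairwise t tests using the pooled within-group error of all groups.

    Returns pair -> (t, df, two-sided p) with df = N - g (the ANOVA
    error df), as conventional for post-hoc comparisons.
    """
    names = list(groups)
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    N = sum(len(v) for v in arrs.values())
    g = len(arrs)
    rss = sum(float(np.sum((v - v.mean()) ** 2)) for v in arrs.values())
    df = N - g
    mse = rss / df
    out = {}
    for i in range(g):
        for j in range(i + 1, g):
            vi, vj = arrs[names[i]], arrs[names[j]]
            se = np.sqrt(mse * (1.0 / len(vi) + 1.0 / len(vj)))
            t = float((vi.mean() - vj.mean()) / se) if se > 0 else 0.0
            p = float(2.0 * sps.t.sf(abs(t), df)) if se > 0 else 1.0
            out[(names[i], names[j])] = (t, df, p)
    return out


def shaffer_posthoc(
    pvalues: dict[tuple[str, str], float], alpha: float = 0.05
) -> dict[tuple[str, str], bool]:
    """Shaffer's modified sequentially rejective Bonferroni, 3 groups.

    For three groups (three pairwise hypotheses), once any hypothesis
    is rejected at alpha/3 at most one of the remaining pairs can still
    be true, so the subsequent thresholds are alpha/1: the sorted
    p-values are tested against alpha/3, alpha, alpha, stopping at the
    first retention.
    """
    if len(pvalues) != 3:
        raise ValueError("this Shaffer schedule covers exactly 3 pairwise tests")
    order = sorted(pvalues, key=pvalues.__getitem__)
    divisors = (3, 1, 1)
    decisions = {}
    stopped = False
    for pair, div in zip(order, divisors):
        if not stopped and pvalues[pair] <= alpha / div:
            decisions[pair] = True
        else:
            stopped = True
            decisions[pair] = False
    return decisions


# ---------------------------------------------------------------------------
# grid orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridConfig:
    """Settings of one 3 x 2 condition-grid run."""

    n_networks: int = 20
    seed: int = 0
    scaled: bool = True
    epochs: int | None = None  # None -> preset default
    regression: RegressionConfig = RegressionConfig(iters=15)
    traversal_steps: int = 1024
    meta_priors: tuple[str, ...] = META_PRIOR_LEVELS
    environments: tuple[str, ...] = ENVIRONMENTS

    def env_config(self) -> EnvConfig:
        if self.scaled:
            return EnvConfig(seq_len=256, biases=SCALED_BIASES, n_sets=1, seed=self.seed)
        return EnvConfig(seed=self.seed)

    def train_config(self, meta_prior: str, seed: int) -> TrainConfig:
        mp = MetaPriorConfig.preset(meta_prior)
        if self.scaled:
            cfg = TrainConfig.scaled(meta_prior=mp, seed=seed, n_networks=self.n_networks)
        else:
            cfg = TrainConfig(meta_prior=mp, seed=seed, n_networks=self.n_networks)
        if self.epochs is not None:
            cfg = replace(cfg, epochs=self.epochs)
        return cfg


def run_grid(grid: GridConfig, arch: Architecture | None = None) -> pd.DataFrame:
    """Run the full meta-prior x environment grid; one row per network.

    Per condition: one corpus (shared by the condition's networks),
    ``n_networks`` training runs with consecutive seeds, a fresh test
    sequence per network for error regression, flexibility metrics and
    the per-layer generative hierarchy from latent-space traversal.
    Failures of individual networks are recorded (row with NaNs and the
    error message) and the run continues.
    """
    arch = arch or Architecture()
    env_cfg = grid.env_config()
    rows = []
    for ci, mp_name in enumerate(grid.meta_priors):
        for ei, env_name in enumerate(grid.environments):
            # corpora depend on the environment but are shared across
            # meta-prior conditions and networks, like a fixed stimulus set
            corpus_rng = np.random.default_rng((grid.seed * 7919 + ei) % 2**31)
            corpus = build_training_set(env_cfg, env_name, corpus_rng)
            base_seed = grid.seed + 10_000 * (ci * len(grid.environments) + ei)
            for k in range(grid.n_networks):
                row = {
                    "meta_prior": mp_name,
                    "environment": env_name,
                    "network_seed": base_seed + k,
                }
                try:
                    row.update(
                        _evaluate_network(
                            corpus, arch, env_cfg, env_name, mp_name,
                            grid, base_seed + k,
                        )
                    )
                except Exception as exc:  # noqa: BLE001 - keep the grid running
                    row.update(
                        behavioral=np.nan, cognitive=np.nan,
                        gh_lower=np.nan, gh_middle=np.nan, gh_higher=np.nan,
                        gh_variance=np.nan, error=str(exc),
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _evaluate_network(corpus, arch, env_cfg, env_name, mp_name, grid, seed):
    tcfg = grid.train_config(mp_name, seed)
    net = train_network(corpus, arch, tcfg)

    test_rng = np.random.default_rng(seed + 1)
    test = build_test_sequence(env_cfg, env_name, test_rng)
    res = error_regression(
        net.params, arch, test.x, grid.regression, w=net.meta_prior.w
    )
    behavioral = behavioral_flexibility(res.predictions[1:], test.x[1:], env_cfg)
    cognitive, _ = cognitive_flexibility(res.trace, test.truth, arch)

    trav_rng = np.random.default_rng(seed + 2)
    gh = [
        generative_hierarchy(
            net.params, arch, layer, env_cfg, trav_rng,
            grid=DEFAULT_GRID, T=grid.traversal_steps,
        )
        for layer in range(arch.L)
    ]
    gh_var = float(np.mean([
        generative_hierarchy(
            net.params, arch, layer, env_cfg, trav_rng,
            channel="variance", grid=DEFAULT_GRID, T=grid.traversal_steps,
        )
        for layer in range(arch.L)
    ]))
    return {
        "behavioral": behavioral,
        "cognitive": cognitive,
        "gh_lower": gh[0],
        "gh_middle": gh[1],
        "gh_higher": gh[2],
        "gh_variance": gh_var,
        "final_loss": float(net.history[-1, 0]),
        "error": "",
    }
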