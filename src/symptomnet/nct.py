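"""Permutation-based comparison of two group networks.

Both groups' networks are estimated with one shared configuration; the
observed statistics are absolute between-group differences in global
strength, in each edge weight (with the maximum edge difference summarizing
overall structure), and in each node's strength and bridge strength. Null
distributions come from re-estimating both networks after shuffling the
group labels over the pooled respondents (group sizes preserved).

P-values follow the counting rule P = K / n_perm, where K is the number of
permutations whose absolute statistic is at least as large as the observed
one (a two-tailed test on absolute differences). The literal count can reach
zero; a (K+1)/(n_perm+1) variant is available behind a flag. Edge p-values
are adjusted by the Benjamini–Hochberg false-discovery-rate procedure;
centrality p-values are reported unadjusted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .centrality import cross_cluster_mask, global_strength
from .ggm import (GgmConfig, ZeroVarianceError, estimate_network,
                  select_weights, spearman_from_array)
from .stability import ResampleError
from .survey import CLUSTER_OF, ITEMS

logger = logging.getLogger(__name__)


def permutation_p(observed: float, null_draws: np.ndarray,
                  plus_one: bool = False) -> float:
    """Two-tailed permutation p-value by direct counting.

    ``P = K / n_perm`` with ``K = #{ |null| >= |observed| }``. With
    ``plus_one=True`` the positively biased but never-zero estimator
    ``(K+1)/(n_perm+1)`` is returned instead.
    """
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("null_draws must be nonempty")
    k = int((np.abs(null_draws) >= abs(observed)).sum())
    if plus_one:
        return (k + 1) / (null_draws.size + 1)
    if k == 0:
        warnings.warn("permutation p-value of exactly 0; consider the "
                      "(K+1)/(n_perm+1) estimator (plus_one=True)",
                      stacklevel=2)
    return k / null_draws.size


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class NctConfig:
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0
    plus_one: bool = False
    fdr_edges: bool = True
    redraw_cap: int = 50


@dataclass
class NctResult:
    node_labels: tuple[str, ...]
    edge_labels: list[tuple[str, str]]
    global_strengths: tuple[float, float]     # (group A, group B)
    observed_global_diff: float
    observed_max_edge_diff: float
    p_global: float
    p_structure: float
    edge_diff: np.ndarray
    edge_p: np.ndarray
    edge_p_fdr: np.ndarray
    nodal_diff: np.ndarray
    nodal_p: np.ndarray
    bridge_diff: np.ndarray
    bridge_p: np.ndarray
    n_perm: int
    seed: int
    alpha: float

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_i": [a for a, _ in self.edge_labels],
            "node_j": [b for _, b in self.edge_labels],
            "abs_diff": self.edge_diff,
            "p": self.edge_p,
            "p_fdr": self.edge_p_fdr,
        })

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": list(self.node_labels),
            "strength_abs_diff": self.nodal_diff,
            "strength_p": self.nodal_p,
            "bridge_abs_diff": self.bridge_diff,
            "bridge_p": self.bridge_p,
        })

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        self.edge_table().to_csv(f"{stem}_edges.csv", index=False)
        self.node_table().to_csv(f"{stem}_nodes.csv", index=False)
        meta = {
            "global_strength_a": self.global_strengths[0],
            "global_strength_b": self.global_strengths[1],
            "observed_global_diff": self.observed_global_diff,
            "observed_max_edge_diff": self.observed_max_edge_diff,
            "p_global": self.p_global,
            "p_structure": self.p_structure,
            "n_perm": self.n_perm, "seed": self.seed, "alpha": self.alpha,
            "centrality_p_adjustment": "none (per-test alpha)",
        }
        Path(f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))


def permutation_null(a: pd.DataFrame, b: pd.DataFrame,
                     stat_fn: Callable[[pd.DataFrame, pd.DataFrame], np.ndarray],
                     n_perm: int, seed: int = 0,
                     redraw_cap: int = 50) -> np.ndarray:
    """Generic label-shuffling null distribution of an arbitrary statistic.

    ``stat_fn`` maps two tables to a scalar or 1-d statistic vector. Each
    iteration shuffles group membership over the pooled rows, preserving
    group sizes; iterations on which ``stat_fn`` raises :class:`ResampleError`
    (degenerate permuted sample) are redrawn up to ``redraw_cap`` times.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    pooled = pd.concat([a, b], ignore_index=True)
    n1, n = len(a), len(pooled)
    draws = []
    for _ in range(n_perm):
        for attempt in range(redraw_cap):
            perm = rng.permutation(n)
            try:
                stat = stat_fn(pooled.iloc[perm[:n1]], pooled.iloc[perm[n1:]])
                break
            except ResampleError:
                continue
        else:
            raise ResampleError(f"degenerate permutation persisted over {redraw_cap} redraws")
        draws.append(np.atleast_1d(np.asarray(stat, dtype=float)))
    return np.vstack(draws)


def _array_network_stats(ggm_config: GgmConfig, cross: np.ndarray):
    """Statistic vector from two item arrays:
    [|global diff|, per-edge |diff|..., per-node strength..., bridge...]."""

    def stat_fn(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        try:
            Sa, na, *_ = spearman_from_array(xa, ggm_config)
            Sb, nb, *_ = spearman_from_array(xb, ggm_config)
        except ZeroVarianceError as exc:
            raise ResampleError(str(exc)) from exc
        wa, _ = select_weights(Sa, na, ggm_config)
        wb, _ = select_weights(Sb, nb, ggm_config)
        aa, ab = np.abs(wa), np.abs(wb)
        iu = np.triu_indices(wa.shape[0], 1)
        return np.concatenate([
            [abs(aa[iu].sum() - ab[iu].sum())],
            np.abs(wa[iu] - wb[iu]),
            np.abs(aa.sum(axis=1) - ab.sum(axis=1)),
            np.abs((aa * cross).sum(axis=1) - (ab * cross).sum(axis=1)),
        ])

    return stat_fn


def compare_networks(school: pd.DataFrame, vacation: pd.DataFrame,
                     ggm_config: GgmConfig = GgmConfig(),
                     config: NctConfig = NctConfig()) -> NctResult:
    """Permutation network-comparison test between two groups."""
    if len(school) == 0 or len(vacation) == 0:
        raise ValueError("both group tables must be nonempty")
    cross = cross_cluster_mask(ITEMS, CLUSTER_OF)
    stat_fn = _array_network_stats(ggm_config, cross)
    xa = school[list(ITEMS)].to_numpy(dtype="float64", na_value=np.nan)
    xb = vacation[list(ITEMS)].to_numpy(dtype="float64", na_value=np.nan)

    net_a = estimate_network(school, ggm_config)
    net_b = estimate_network(vacation, ggm_config)
    observed = stat_fn(xa, xb)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    pooled = np.vstack([xa, xb])
    n1, n = len(xa), len(pooled)
    draws = np.empty((config.n_perm, observed.size))
    for it in range(config.n_perm):
        for _attempt in range(config.redraw_cap):
            perm = rng.permutation(n)
            try:
                draws[it] = stat_fn(pooled[perm[:n1]], pooled[perm[n1:]])
                break
            except ResampleError:
                continue
        else:
            raise ResampleError(
                f"degenerate permutation persisted over {config.redraw_cap} redraws")
    null = draws

    p = net_a.p
    iu = np.triu_indices(p, 1)
    n_edges = len(iu[0])
    sl_global = 0
    sl_edges = slice(1, 1 + n_edges)
    sl_nodal = slice(1 + n_edges, 1 + n_edges + p)
    sl_bridge = slice(1 + n_edges + p, 1 + n_edges + 2 * p)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-count warnings summarized below
        p_global = permutation_p(observed[sl_global], null[:, sl_global], config.plus_one)
        max_edge_obs = float(observed[sl_edges].max())
        p_structure = permutation_p(max_edge_obs, null[:, sl_edges].max(axis=1),
                                    config.plus_one)
        edge_p = np.array([permutation_p(observed[sl_edges][e], null[:, sl_edges][:, e],
                                         config.plus_one) for e in range(n_edges)])
        nodal_p = np.array([permutation_p(observed[sl_nodal][i], null[:, sl_nodal][:, i],
                                          config.plus_one) for i in range(p)])
        bridge_p = np.array([permutation_p(observed[sl_bridge][i], null[:, sl_bridge][:, i],
                                           config.plus_one) for i in range(p)])
    if not config.plus_one:
        n_zero = int((edge_p == 0).sum() + (nodal_p == 0).sum() + (bridge_p == 0).sum()
                     + (p_global == 0) + (p_structure == 0))
        if n_zero:
            logger.warning("%d permutation p-values hit the literal floor of 0 "
                           "(granularity 1/%d); the (K+1)/(n_perm+1) estimator is "
                           "available via plus_one=True", n_zero, config.n_perm)

    edge_p_fdr = fdr_adjust(edge_p) if config.fdr_edges else edge_p.copy()
    return NctResult(
        node_labels=net_a.labels,
        edge_labels=[(net_a.labels[i], net_a.labels[j]) for i, j in zip(*iu)],
        global_strengths=(global_strength(net_a), global_strength(net_b)),
        observed_global_diff=float(observed[sl_global]),
        observed_max_edge_diff=max_edge_obs,
        p_global=p_global, p_structure=p_structure,
        edge_diff=observed[sl_edges], edge_p=edge_p, edge_p_fdr=edge_p_fdr,
        nodal_diff=observed[sl_nodal], nodal_p=nodal_p,
        bridge_diff=observed[sl_bridge], bridge_p=bridge_p,
        n_perm=config.n_perm, seed=config.seed, alpha=config.alpha,
    )
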