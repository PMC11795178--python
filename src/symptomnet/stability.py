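"""Bootstrap accuracy and stability of estimated symptom networks.

Three procedures, all re-running the full Spearman -> glasso -> EBIC chain
per replicate:

* nonparametric bootstrap of edge weights (percentile confidence intervals);
* case-dropping subsampling for centrality stability, summarized by the
  correlation-stability (CS) coefficient — the largest drop proportion at
  which at least 95% of subsample centralities still correlate >= 0.7 with
  the full-sample values;
* bootstrap difference tests between pairs of edges and pairs of node
  strengths (significant when the 95% bootstrap interval of the difference
  excludes zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import cross_cluster_mask, nodal_strength
from .ggm import (GgmConfig, ZeroVarianceError, estimate_network,
                  select_weights, spearman_from_array)
from .survey import CLUSTER_OF, ITEMS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootConfig:
    n_boot: int = 1000
    n_boot_drop: int = 500
    drop_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    ci: tuple[float, float] = (2.5, 97.5)
    cs_correlation: float = 0.7
    cs_coverage: float = 0.95
    redraw_cap: int = 50
    seed: int = 0


class ResampleError(RuntimeError):
    """A degenerate (zero-variance) resample kept recurring past the redraw cap."""


def _resample_ok(items: np.ndarray) -> bool:
    return bool((items.std(axis=0) > 0).all())


def _draw_indices(rng: np.random.Generator, n: int, size: int, replace: bool,
                  items: np.ndarray, cap: int) -> np.ndarray:
    for _ in range(cap):
        idx = rng.choice(n, size=size, replace=replace)
        if _resample_ok(items[idx]):
            return idx
    raise ResampleError(f"zero-variance item persisted over {cap} redraws")


def _estimate_weights(items: np.ndarray, ggm_config: GgmConfig) -> np.ndarray:
    """Array-path re-estimation used inside resampling loops."""
    try:
        S, n_eff, *_ = spearman_from_array(items, ggm_config)
    except ZeroVarianceError as exc:
        raise ResampleError(str(exc)) from exc
    return select_weights(S, n_eff, ggm_config)[0]


@dataclass
class BootstrapDraws:
    """Edge weights and centralities across bootstrap re-estimations."""

    edge_labels: list[tuple[str, str]]
    node_labels: tuple[str, ...]
    observed_weights: np.ndarray     # (E,)
    observed_strength: np.ndarray    # (p,)
    weights: np.ndarray              # (n_boot, E)
    strengths: np.ndarray            # (n_boot, p)


def bootstrap_networks(table: pd.DataFrame,
                       ggm_config: GgmConfig = GgmConfig(),
                       boot: BootConfig = BootConfig()) -> BootstrapDraws:
    """Row-resampling bootstrap with full network re-estimation per draw."""
    n = len(table)
    if n < 50:
        raise ValueError("bootstrap requires at least 50 rows")
    rng = np.random.default_rng(np.random.SeedSequence([boot.seed, 11]))
    items = table[list(ITEMS)].to_numpy(dtype="float64", na_value=np.nan)

    net0 = estimate_network(table, ggm_config)
    p = net0.p
    iu = np.triu_indices(p, 1)
    edge_labels = [(net0.labels[i], net0.labels[j]) for i, j in zip(*iu)]

    W = np.empty((boot.n_boot, len(edge_labels)))
    S = np.empty((boot.n_boot, p))
    for b in range(boot.n_boot):
        idx = _draw_indices(rng, n, n, True, items, boot.redraw_cap)
        w = _estimate_weights(items[idx], ggm_config)
        W[b] = w[iu]
        S[b] = np.abs(w).sum(axis=1)
    return BootstrapDraws(edge_labels=edge_labels, node_labels=net0.labels,
                          observed_weights=net0.weights[iu],
                          observed_strength=nodal_strength(net0),
                          weights=W, strengths=S)


def edge_accuracy(table: pd.DataFrame,
                  ggm_config: GgmConfig = GgmConfig(),
                  boot: BootConfig = BootConfig(),
                  draws: BootstrapDraws | None = None) -> pd.DataFrame:
    """Percentile bootstrap confidence interval for every edge weight."""
    d = draws or bootstrap_networks(table, ggm_config, boot)
    lo, hi = np.percentile(d.weights, boot.ci, axis=0)
    return pd.DataFrame({
        "node_i": [a for a, _ in d.edge_labels],
        "node_j": [b for _, b in d.edge_labels],
        "observed": d.observed_weights,
        "boot_mean": d.weights.mean(axis=0),
        "lower": lo,
        "upper": hi,
    })


@dataclass
class CaseDroppingResult:
    index: str
    drop_grid: tuple[float, ...]
    correlations: dict[float, np.ndarray]   # per drop proportion
    proportion_ok: dict[float, float]
    n_skipped: dict[float, int]
    cs_coefficient: float


def case_dropping_stability(table: pd.DataFrame, index: str = "nodal_strength",
                            ggm_config: GgmConfig = GgmConfig(),
                            boot: BootConfig = BootConfig()) -> CaseDroppingResult:
    """CS-coefficient of a centrality index under case-dropping subsampling.

    For each drop proportion, subsamples without replacement, re-estimates the
    network, and correlates (Pearson) the subsample index with the full-sample
    index. Subsamples with a constant index vector are skipped and logged.
    """
    if index not in ("nodal_strength", "bridge_strength"):
        raise ValueError(f"unknown centrality index {index!r}")
    n = len(table)
    if n < 100:
        raise ValueError("case-dropping stability requires at least 100 rows")
    rng = np.random.default_rng(np.random.SeedSequence([boot.seed, 13]))
    items = table[list(ITEMS)].to_numpy(dtype="float64", na_value=np.nan)
    cross = cross_cluster_mask(ITEMS, CLUSTER_OF)

    def idx_of(w: np.ndarray) -> np.ndarray:
        a = np.abs(w)
        return a.sum(axis=1) if index == "nodal_strength" else (a * cross).sum(axis=1)

    full = idx_of(_estimate_weights(items, ggm_config))
    full_sd = full.std()

    correlations: dict[float, np.ndarray] = {}
    proportion_ok: dict[float, float] = {}
    n_skipped: dict[float, int] = {}
    for drop in boot.drop_grid:
        size = int(round(n * (1.0 - drop)))
        cors, skipped = [], 0
        for _ in range(boot.n_boot_drop):
            sub = _draw_indices(rng, n, size, False, items, boot.redraw_cap)
            vec = idx_of(_estimate_weights(items[sub], ggm_config))
            if full_sd == 0 or vec.std() == 0:
                skipped += 1
                continue
            cors.append(float(np.corrcoef(full, vec)[0, 1]))
        cors = np.asarray(cors)
        correlations[drop] = cors
        n_skipped[drop] = skipped
        if skipped:
            logger.info("drop %.1f: skipped %d constant-index subsamples", drop, skipped)
        ok = (cors >= boot.cs_correlation).sum() if cors.size else 0
        proportion_ok[drop] = ok / boot.n_boot_drop
    passing = [d for d in boot.drop_grid if proportion_ok[d] >= boot.cs_coverage]
    cs = max(passing) if passing else 0.0
    return CaseDroppingResult(index=index, drop_grid=boot.drop_grid,
                              correlations=correlations,
                              proportion_ok=proportion_ok,
                              n_skipped=n_skipped, cs_coefficient=cs)


def bootstrap_difference_tests(table: pd.DataFrame,
                               ggm_config: GgmConfig = GgmConfig(),
                               boot: BootConfig = BootConfig(),
                               draws: BootstrapDraws | None = None
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise bootstrap difference tests for edges and node strengths.

    Returns two symmetric 0/1 DataFrames: ``edge_diff`` (edge pair flagged
    when the 95% bootstrap interval of their weight difference excludes 0)
    and ``strength_diff`` (likewise for nodal strengths). An element is never
    flagged against itself.
    """
    d = draws or bootstrap_networks(table, ggm_config, boot)

    def pairwise(mat: np.ndarray) -> np.ndarray:
        m = mat.shape[1]
        sig = np.zeros((m, m), dtype=int)
        for i in range(m - 1):
            diff = mat[:, i:i + 1] - mat[:, i + 1:]
            lo, hi = np.percentile(diff, boot.ci, axis=0)
            flag = (lo > 0) | (hi < 0)
            sig[i, i + 1:] = flag
            sig[i + 1:, i] = flag
        return sig

    edge_names = [f"{a}--{b}" for a, b in d.edge_labels]
    edge_diff = pd.DataFrame(pairwise(d.weights), index=edge_names, columns=edge_names)
    strength_diff = pd.DataFrame(pairwise(d.strengths),
                                 index=list(d.node_labels), columns=list(d.node_labels))
    return edge_diff, strength_diff
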