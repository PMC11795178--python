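"""Regularized partial-correlation network estimation.

The estimation chain follows standard network-psychometrics practice for
ordinal symptom data: Spearman rank correlations (the items are skewed
4-category Likert responses), the graphical lasso over a logarithmic penalty
grid, and model selection by the extended Bayesian information criterion
(EBIC). Edge weights are the regularized partial correlations obtained from
the selected precision matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glasso import glasso_kernel
from .survey import CLUSTER_OF, ITEMS

logger = logging.getLogger(__name__)

#: |weight| below this is treated as exactly zero when counting edges.
ZERO_TOL = 1e-8


@dataclass(frozen=True)
class GgmConfig:
    """Estimator settings: EBIC gamma, penalty grid, solver tolerances."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-6          # relative to mean |off-diagonal S|
    max_sweeps: int = 10_000
    psd_floor: float = 1e-6    # eigenvalue floor for correlation repair


@dataclass
class CorrelationMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    n_effective: int
    repaired: bool = False
    min_eig_before: float | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")


@dataclass
class SymptomNetwork:
    """A labelled symptom network with regularized partial-correlation weights."""

    labels: tuple[str, ...]
    cluster_of: dict[str, str]
    weights: np.ndarray
    lambda_selected: float
    ebic_gamma: float
    n: int

    def __post_init__(self) -> None:
        w = self.weights
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(w)).max() > 1e-12:
            raise ValueError("weight matrix must have zero diagonal")

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int((np.abs(self.weights[iu]) > ZERO_TOL).sum())

    @property
    def density_percent(self) -> float:
        from .survey import round_half_up
        return round_half_up(100.0 * self.edge_count / self.n_possible_edges)

    def item_subnetwork(self, labels: Sequence[str] = ITEMS) -> "SymptomNetwork":
        """Restrict to the given (symptom) nodes, e.g. dropping covariates."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise ValueError(f"labels not in network: {missing}")
        pos = [self.labels.index(l) for l in labels]
        return SymptomNetwork(
            labels=tuple(labels),
            cluster_of={l: self.cluster_of[l] for l in labels},
            weights=self.weights[np.ix_(pos, pos)].copy(),
            lambda_selected=self.lambda_selected,
            ebic_gamma=self.ebic_gamma, n=self.n,
        )

    def to_edgelist(self) -> pd.DataFrame:
        iu = np.triu_indices(self.p, 1)
        return pd.DataFrame({
            "node_i": [self.labels[i] for i in iu[0]],
            "node_j": [self.labels[j] for j in iu[1]],
            "weight": self.weights[iu],
        })

    def save(self, stem: str | Path) -> None:
        """Write ``<stem>_weights.csv``, ``<stem>_edges.csv``, ``<stem>_meta.json``."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.weights, index=list(self.labels),
                     columns=list(self.labels)).to_csv(f"{stem}_weights.csv")
        self.to_edgelist().to_csv(f"{stem}_edges.csv", index=False)
        meta = {
            "lambda_selected": self.lambda_selected, "ebic_gamma": self.ebic_gamma,
            "n": self.n, "edge_count": self.edge_count,
            "n_possible_edges": self.n_possible_edges,
            "density_percent": self.density_percent,
            "cluster_of": self.cluster_of,
        }
        Path(f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))


class ZeroVarianceError(ValueError):
    """An item had no variance on the (listwise-complete) rows in use."""


def spearman_from_array(data: np.ndarray,
                        config: GgmConfig = GgmConfig()) -> tuple[np.ndarray, int, bool, float]:
    """Spearman correlation core on a float array (NaN marks missing).

    Returns ``(corr, n_complete, repaired, min_eig_before)``; raises
    :class:`ZeroVarianceError` naming offending column indices.
    """
    if np.isnan(data).any():
        data = data[~np.isnan(data).any(axis=1)]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    if data.shape[1] < 2:
        raise ValueError("need at least 2 items")
    sds = data.std(axis=0)
    if (sds == 0).any():
        raise ZeroVarianceError(
            f"zero-variance item(s) at columns {np.flatnonzero(sds == 0).tolist()}")
    ranks = stats.rankdata(data, axis=0, method="average")
    corr = np.corrcoef(ranks, rowvar=False)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)

    eigmin = float(np.linalg.eigvalsh(corr)[0])
    repaired = False
    if eigmin < -1e-10:  # genuinely indefinite; exact singularity is fine
        vals, vecs = np.linalg.eigh(corr)
        vals = np.clip(vals, config.psd_floor, None)
        corr = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        corr = 0.5 * (corr + corr.T)
        np.fill_diagonal(corr, 1.0)
        repaired = True
        logger.warning("Spearman matrix repaired to PSD (min eigenvalue %.3e)", eigmin)
    return corr, int(data.shape[0]), repaired, eigmin


def spearman_matrix(table: pd.DataFrame,
                    columns: Sequence[str] = ITEMS,
                    config: GgmConfig = GgmConfig()) -> CorrelationMatrix:
    """Pairwise Spearman correlations on listwise-complete rows.

    Ties get average ranks. A non-positive-semidefinite result is repaired to
    the nearest correlation matrix by eigenvalue clipping and unit-diagonal
    rescaling; the repair is logged with the pre-repair minimum eigenvalue.
    """
    data = table[list(columns)].to_numpy(dtype="float64", na_value=np.nan)
    try:
        corr, n_eff, repaired, eigmin = spearman_from_array(data, config)
    except ZeroVarianceError as exc:
        sds = data[~np.isnan(data).any(axis=1)].std(axis=0)
        bad = [columns[i] for i in np.flatnonzero(sds == 0)]
        raise ZeroVarianceError(f"zero-variance item(s): {bad}") from exc
    return CorrelationMatrix(labels=tuple(columns), values=corr,
                             n_effective=n_eff,
                             repaired=repaired, min_eig_before=eigmin)


class GlassoConvergenceError(RuntimeError):
    pass


def _thresh(S: np.ndarray, tol: float) -> float:
    p = S.shape[0]
    mean_off = (np.abs(S).sum() - np.trace(np.abs(S))) / max(p * (p - 1), 1)
    return tol * max(mean_off, 1e-12)


def glasso_fit(corr: CorrelationMatrix | np.ndarray, lam: float,
               config: GgmConfig = GgmConfig()) -> np.ndarray:
    """Sparse precision estimate at one penalty value.

    At ``lam = 0`` on a full-rank input the solution is the plain inverse
    correlation matrix, computed directly. Convergence is declared when the
    largest working-covariance change in a sweep drops below
    ``tol * mean |off-diagonal S|``.
    """
    S = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        return np.linalg.inv(S)
    p = S.shape[0]
    W = S.copy()
    Theta = np.zeros((p, p))
    B = np.zeros((p, p))
    ok, sweeps, delta = glasso_kernel(S, lam, _thresh(S, config.tol),
                                      config.max_sweeps, W, Theta, B)
    if not ok:
        raise GlassoConvergenceError(
            f"glasso did not converge at lambda={lam:.6g} "
            f"(last change {delta:.3e} after {sweeps} sweeps)")
    return Theta


def precision_to_partials(precision: np.ndarray) -> np.ndarray:
    """Partial correlations: w_ij = -theta_ij / sqrt(theta_ii * theta_jj)."""
    d = np.diag(precision)
    if (d <= 0).any():
        raise ValueError("precision matrix has a nonpositive diagonal entry")
    w = -precision / np.sqrt(np.outer(d, d))
    np.fill_diagonal(w, 0.0)
    return 0.5 * (w + w.T)


def ebic_score(precision: np.ndarray, corr: CorrelationMatrix | np.ndarray,
               n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fitted precision matrix.

    ``-n*(log det Theta - tr(S Theta)) + E*log n + 4*E*gamma*log p`` with E
    the number of nonzero upper-triangle off-diagonals.
    """
    S = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    iu = np.triu_indices(p, 1)
    E = int((np.abs(precision[iu]) > ZERO_TOL).sum())
    loglik = logdet - float(np.sum(S * precision))
    return -n * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def lambda_grid(corr: CorrelationMatrix | np.ndarray,
                config: GgmConfig = GgmConfig()) -> np.ndarray:
    """Logarithmic penalty grid from lambda_max down to ratio*lambda_max."""
    S = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    offdiag = S - np.diag(np.diag(S))
    lam_max = float(np.abs(offdiag).max())
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda)


def select_network(corr: CorrelationMatrix, n: int | None = None,
                   config: GgmConfig = GgmConfig(),
                   cluster_of: Mapping[str, str] | None = None) -> SymptomNetwork:
    """EBIC model selection over the glasso path.

    The path is solved from the sparsest (largest lambda) end with warm
    starts; ties in EBIC go to the larger lambda. Weights with magnitude
    below 1e-8 are snapped to exact zero.
    """
    n = corr.n_effective if n is None else n
    weights, lam_sel = select_weights(corr.values, n, config)
    return SymptomNetwork(
        labels=corr.labels, cluster_of=_clusters(corr.labels, cluster_of),
        weights=weights, lambda_selected=lam_sel, ebic_gamma=config.gamma, n=n)


def select_weights(S: np.ndarray, n: int,
                   config: GgmConfig = GgmConfig()) -> tuple[np.ndarray, float]:
    """Path-selection core: returns ``(weights, lambda_selected)``.

    This is the resampling hot path (bootstrap, permutation), so it works on
    a bare correlation array and skips the labelled container. The path is
    solved from the sparsest (largest lambda) end with warm starts.
    """
    p = S.shape[0]
    offdiag = S - np.diag(np.diag(S))
    lam_max = float(np.abs(offdiag).max())
    if lam_max <= 0:
        # no off-diagonal signal at all: the empty network
        return np.zeros((p, p)), 0.0
    grid = np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda)
    thresh = _thresh(S, config.tol)
    W = S.copy()
    Theta = np.zeros((p, p))
    B = np.zeros((p, p))
    logn, logp = np.log(n), np.log(p)
    iu = np.triu_indices(p, 1)
    best_score, best_theta, best_lam = np.inf, None, 0.0
    failures = []
    for lam in grid:
        ok, _, delta = glasso_kernel(S, float(lam), thresh, config.max_sweeps, W, Theta, B)
        if not ok:
            failures.append((float(lam), float(delta)))
            continue
        sign, logdet = np.linalg.slogdet(Theta)
        if sign <= 0:
            failures.append((float(lam), np.nan))
            continue
        E = int((np.abs(Theta[iu]) > ZERO_TOL).sum())
        score = -n * (logdet - float(np.sum(S * Theta))) \
            + E * logn + 4.0 * E * config.gamma * logp
        # strict < keeps the earlier (larger-lambda, sparser) model on ties
        if score < best_score - 1e-12:
            best_score, best_theta, best_lam = score, Theta.copy(), float(lam)
    if best_theta is None:
        raise GlassoConvergenceError(
            f"all {len(grid)} path fits failed; per-lambda diagnostics: {failures}")
    weights = precision_to_partials(best_theta)
    weights[np.abs(weights) < ZERO_TOL] = 0.0
    return weights, best_lam


def _clusters(labels: Sequence[str], cluster_of: Mapping[str, str] | None) -> dict[str, str]:
    if cluster_of is not None:
        return {l: cluster_of[l] for l in labels}
    return {l: CLUSTER_OF.get(l, "covariate") for l in labels}


def estimate_network(table: pd.DataFrame,
                     config: GgmConfig = GgmConfig()) -> SymptomNetwork:
    """Spearman -> glasso -> EBIC on the sixteen symptom items of a table."""
    corr = spearman_matrix(table, ITEMS, config)
    return select_network(corr, config=config)


def covariate_network(table: pd.DataFrame, covariates: Sequence[str],
                      config: GgmConfig = GgmConfig()) -> SymptomNetwork:
    """Re-estimate the network with demographic covariates as extra nodes.

    Covariate columns join the sixteen items in one Spearman matrix and are
    labelled with cluster ``"covariate"``. An empty covariate list reduces to
    the plain item network.
    """
    for cov in covariates:
        if cov not in table.columns:
            raise ValueError(f"covariate {cov!r} not in table")
        col = table[cov].dropna()
        if col.nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    cols = list(ITEMS) + list(covariates)
    corr = spearman_matrix(table, cols, config)
    return select_network(corr, config=config)


@dataclass(frozen=True)
class DeltaNetwork:
    """Entrywise |edge difference| between two networks on shared item nodes."""

    labels: tuple[str, ...]
    delta: np.ndarray
    max_delta: float


def delta_network(a: SymptomNetwork, b: SymptomNetwork,
                  labels: Sequence[str] = ITEMS) -> DeltaNetwork:
    """Absolute edge-weight differences on the common (symptom) block.

    Used as the control analysis: comparing the plain network with the
    item-item block of its covariate-adjusted counterpart shows how much the
    covariates alter the symptom network.
    """
    for net in (a, b):
        missing = [l for l in labels if l not in net.labels]
        if missing:
            raise ValueError(f"network lacks shared labels: {missing}")
    wa = a.item_subnetwork(labels).weights
    wb = b.item_subnetwork(labels).weights
    d = np.abs(wa - wb)
    return DeltaNetwork(labels=tuple(labels), delta=d, max_delta=float(d.max()))
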