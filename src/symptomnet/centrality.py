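"""Strength-based centrality of symptom networks.

Three quantities: global strength (sum of |edge weights| over all edges),
nodal strength (sum of |weights| incident to a node) and bridge strength
(sum of |weights| from a node to nodes of the other symptom cluster).
Absolute values are used throughout; a signed "expected influence" variant
is available behind a flag for exploration but is not the default path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ggm import SymptomNetwork

#: Cluster label treated as non-symptom; such nodes are excluded from the
#: centrality profile (and hence from both sides of bridge strength).
COVARIATE_CLUSTER = "covariate"


@dataclass(frozen=True)
class CentralityProfile:
    labels: tuple[str, ...]
    cluster_of: dict[str, str]
    nodal_strength: np.ndarray
    bridge_strength: np.ndarray
    global_strength: float
    standardized_strength: np.ndarray
    standardized_bridge: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": list(self.labels),
            "cluster": [self.cluster_of[l] for l in self.labels],
            "nodal_strength": self.nodal_strength,
            "bridge_strength": self.bridge_strength,
            "standardized_strength": self.standardized_strength,
            "standardized_bridge": self.standardized_bridge,
        })

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def _weights(net: SymptomNetwork, signed: bool) -> np.ndarray:
    return net.weights if signed else np.abs(net.weights)


def nodal_strength(net: SymptomNetwork, signed: bool = False) -> np.ndarray:
    """Per-node sum of |edge weights| (row sums of the |weight| matrix)."""
    return _weights(net, signed).sum(axis=1)


def global_strength(net: SymptomNetwork, signed: bool = False) -> float:
    """Sum of |edge weights| over unordered pairs; half the nodal-strength sum."""
    w = _weights(net, signed)
    iu = np.triu_indices(net.p, 1)
    return float(w[iu].sum())


def bridge_strength(net: SymptomNetwork,
                    clusters: Mapping[str, str] | None = None,
                    signed: bool = False) -> np.ndarray:
    """Per-node sum of |edge weights| to nodes of *other* symptom clusters.

    Covariate-cluster nodes contribute zero and receive zero.
    """
    clusters = dict(clusters) if clusters is not None else net.cluster_of
    missing = [l for l in net.labels if l not in clusters]
    if missing:
        raise ValueError(f"nodes without a cluster assignment: {missing}")
    labs = net.labels
    cl = np.array([clusters[l] for l in labs])
    w = _weights(net, signed)
    out = np.zeros(net.p)
    symptom = cl != COVARIATE_CLUSTER
    for i in range(net.p):
        if not symptom[i]:
            continue
        mask = symptom & (cl != cl[i])
        out[i] = w[i, mask].sum()
    return out


def cross_cluster_mask(labels, clusters: Mapping[str, str]) -> np.ndarray:
    """Boolean (p, p) mask of symptom-node pairs in different clusters.

    Used by resampling hot paths to compute bridge strength as a masked row
    sum; covariate nodes are excluded on both axes.
    """
    cl = np.array([clusters[l] for l in labels])
    symptom = cl != COVARIATE_CLUSTER
    diff = cl[:, None] != cl[None, :]
    return diff & symptom[:, None] & symptom[None, :]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population convention across the network's nodes
    if sd == 0 or len(x) < 2:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_profile(net: SymptomNetwork, signed: bool = False) -> CentralityProfile:
    """Full profile on the symptom nodes; covariate nodes are dropped first."""
    symptom_labels = tuple(l for l in net.labels
                           if net.cluster_of[l] != COVARIATE_CLUSTER)
    sub = net.item_subnetwork(symptom_labels) if symptom_labels != net.labels else net
    ns = nodal_strength(sub, signed)
    bs = bridge_strength(sub, signed=signed)
    return CentralityProfile(
        labels=sub.labels, cluster_of=dict(sub.cluster_of),
        nodal_strength=ns, bridge_strength=bs,
        global_strength=global_strength(sub, signed),
        standardized_strength=_zscore(ns),
        standardized_bridge=_zscore(bs),
    )
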