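"""Weighted-graph metrics used to validate the eccentricity interpretation.

Node strength, within-module degree z-score, and participation coefficient
are computed on the row-thresholded template connectivity matrix. Eccentric
(segregated) regions should show high strength and low participation; regions
near the manifold centroid integrate across networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError


@dataclass
class WeightedGraph:
    """Nonnegative symmetric weighted graph with a module partition.

    Construction symmetrizes by elementwise max(w, w^T), zeroes negative
    weights (strength-based metrics assume nonnegative weights) and zeroes
    the diagonal.
    """

    weights: np.ndarray
    module_labels: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, float)
        n = W.shape[0]
        if W.shape != (n, n):
            raise ValidationError("weight matrix must be square")
        labels = np.asarray(self.module_labels)
        if labels.shape != (n,):
            raise ValidationError("module_labels must cover all regions")
        W = np.maximum(W, W.T)
        W = np.where(W > 0, W, 0.0)
        np.fill_diagonal(W, 0.0)
        self.weights = W
        self.module_labels = labels

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def node_strength(g: WeightedGraph) -> np.ndarray:
    """Sum of each region's connection weights."""
    return g.weights.sum(axis=1)


def within_module_degree_z(g: WeightedGraph) -> np.ndarray:
    """Within-module strength, z-scored against the region's own module.

    Modules whose members all share the same within-module strength (zero SD)
    yield 0 for every member; singleton modules are rejected.
    """
    labels = g.module_labels
    z = np.zeros(g.n_nodes)
    for mod in np.unique(labels):
        members = np.flatnonzero(labels == mod)
        if members.size < 2:
            raise ValidationError(f"module {mod!r} has a single member")
        within = g.weights[np.ix_(members, members)].sum(axis=1)
        sd = within.std()
        if sd > 0:
            z[members] = (within - within.mean()) / sd
    return z


def participation_coefficient(g: WeightedGraph) -> np.ndarray:
    """Diversity of a region's connections across modules: 1 - sum_m (k_im/k_i)^2.

    A region connected only within its own module scores 0; equal strength to
    each of M modules gives 1 - 1/M. Zero-strength regions score 0.
    """
    labels = g.module_labels
    k = g.weights.sum(axis=1)
    pc = np.zeros(g.n_nodes)
    nz = k > 0
    acc = np.zeros(g.n_nodes)
    for mod in np.unique(labels):
        members = labels == mod
        k_im = g.weights[:, members].sum(axis=1)
        acc[nz] += (k_im[nz] / k[nz]) ** 2
    pc[nz] = 1.0 - acc[nz]
    return pc
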