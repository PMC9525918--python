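"""Differential Spearman correlation networks and block-model clustering.

Per replicate and condition, edges between protein pairs carry the Spearman
correlation of the two temporal profiles.  For each pair this yields N
vehicle and N treated edge values; a two-sided pooled-variance t-test
contrasts the two groups, and pairs with -log10 p above the retention
threshold (default 2, i.e. p < 1%) form the difference network.  Nodes of
that network are clustered with a non-degree-corrected Bernoulli stochastic
block model scored by a profile log-likelihood with an MDL-like penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import AbundanceCube


# ---------------------------------------------------------------------------
# Edges
# ---------------------------------------------------------------------------

def spearman_edges(cube: AbundanceCube, condition: str = "",
                   min_overlap: int = 3) -> pd.DataFrame:
    """Per-replicate Spearman correlations over temporal profiles.

    Returns a long table (u, v, condition, replicate, rho) with u < v.
    Pairs use pairwise-complete time points; samples with fewer than
    ``min_overlap`` shared points are omitted.
    """
    if len(cube.entity_ids) < 2:
        raise ValueError("need >= 2 proteins")
    rows = []
    for r, rep in enumerate(cube.replicates):
        profile = cube.values[:, :, :, r].reshape(len(cube.entity_ids), -1)
        complete = ~np.isnan(profile)
        if profile.shape[1] < min_overlap:
            raise ValueError("need >= 3 time points per replicate")
        # rank-transform rows with full data in bulk, fall back pairwise else
        full = complete.all(axis=1)
        ranks = np.full_like(profile, np.nan)
        if full.any():
            ranks[full] = stats.rankdata(profile[full], axis=1)
        rho_full = None
        if full.any():
            rk = ranks[full]
            rk = rk - rk.mean(axis=1, keepdims=True)
            denom = np.sqrt((rk**2).sum(axis=1))
            denom[denom == 0] = np.nan
            rho_full = (rk @ rk.T) / np.outer(denom, denom)
        full_ix = np.flatnonzero(full)
        pos_of = {int(i): j for j, i in enumerate(full_ix)}
        n = len(cube.entity_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if full[i] and full[j]:
                    rho = rho_full[pos_of[i], pos_of[j]]
                else:
                    shared = complete[i] & complete[j]
                    if shared.sum() < min_overlap:
                        continue
                    rho = stats.spearmanr(profile[i, shared], profile[j, shared]).statistic
                if np.isnan(rho):
                    continue
                rows.append((cube.entity_ids[i], cube.entity_ids[j],
                             condition, rep, float(rho)))
    return pd.DataFrame(rows, columns=["u", "v", "condition", "replicate", "rho"])


@dataclass
class EdgeChange:
    """Result of the two-condition edge t-test for one protein pair."""

    u: str
    v: str
    t_stat: float
    p: float
    neg_log10_p: float
    retained: bool


def edge_ttest(vehicle_rho: np.ndarray, treated_rho: np.ndarray,
               u: str = "", v: str = "", retain_threshold: float = 2.0,
               fisher_z: bool = False, welch: bool = False) -> EdgeChange:
    """Two-sided two-sample t-test between the conditions' edge values.

    Pooled-variance (Student) by default; Fisher z-transform of the
    correlations optional.
    """
    a = np.asarray(vehicle_rho, dtype=float)
    b = np.asarray(treated_rho, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per condition")
    if fisher_z:
        a = np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12))
        b = np.arctanh(np.clip(b, -1 + 1e-12, 1 - 1e-12))
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t_stat = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t_stat):
        t_stat, p = 0.0, 1.0
    nlp = -np.log10(p) if p > 0 else np.inf
    return EdgeChange(u=u, v=v, t_stat=t_stat, p=p, neg_log10_p=float(nlp),
                      retained=bool(nlp > retain_threshold))


def differential_edges(vehicle: pd.DataFrame, treated: pd.DataFrame,
                       retain_threshold: float = 2.0, fisher_z: bool = False,
                       welch: bool = False) -> list[EdgeChange]:
    """Run the edge t-test for every pair present in both conditions."""
    changes = []
    skipped = 0
    veh = vehicle.groupby(["u", "v"])["rho"].apply(np.asarray)
    tre = treated.groupby(["u", "v"])["rho"].apply(np.asarray)
    for key in veh.index.intersection(tre.index):
        a, b = veh[key], tre[key]
        if len(a) < 2 or len(b) < 2:
            skipped += 1
            continue
        changes.append(edge_ttest(a, b, u=key[0], v=key[1],
                                  retain_threshold=retain_threshold,
                                  fisher_z=fisher_z, welch=welch))
    if skipped:
        import logging
        logging.getLogger(__name__).info("differential_edges: skipped %d pairs "
                                         "with <2 samples", skipped)
    return changes


def changes_frame(changes: list[EdgeChange]) -> pd.DataFrame:
    return pd.DataFrame([{"u": c.u, "v": c.v, "t_stat": c.t_stat, "p": c.p,
                          "neg_log10_p": c.neg_log10_p, "retained": c.retained}
                         for c in changes])


def build_difference_network(changes: list[EdgeChange],
                             drop_isolated: bool = True) -> nx.Graph:
    """Simple undirected graph of retained edges."""
    graph = nx.Graph()
    if not drop_isolated:
        graph.add_nodes_from({c.u for c in changes} | {c.v for c in changes})
    for c in changes:
        if c.retained:
            graph.add_edge(c.u, c.v, neg_log10_p=c.neg_log10_p)
    return graph


# ---------------------------------------------------------------------------
# Stochastic block model
# ---------------------------------------------------------------------------

def sbm_log_likelihood(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Profile log-likelihood (1/2) sum_rs m_rs * log(m_rs / (n_r * n_s))
    with m_rs the directed block edge counts and 0*log 0 = 0; the half
    counts each undirected edge once."""
    blocks = np.unique(labels)
    n_r = np.array([(labels == r).sum() for r in blocks], dtype=float)
    ll = 0.0
    for a, r in enumerate(blocks):
        for b, s in enumerate(blocks):
            m = float(adjacency[np.ix_(labels == r, labels == s)].sum())
            if m > 0:
                ll += m * np.log(m / (n_r[a] * n_r[b]))
    return 0.5 * ll


def sbm_penalized_score(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Likelihood minus the (B(B+1)/2) * log E model-complexity penalty."""
    B = len(np.unique(labels))
    E = adjacency.sum() / 2.0
    penalty = (B * (B + 1) / 2.0) * (np.log(E) if E > 0 else 0.0)
    return sbm_log_likelihood(adjacency, labels) - penalty


class StochasticBlockModel(BaseEstimator):
    """Non-degree-corrected Bernoulli SBM fit by greedy agglomeration plus
    single-node move refinement, selected over a range of block counts by a
    penalized profile likelihood.

    Attributes: ``labels_`` (node -> block), ``n_blocks_``,
    ``log_likelihood_``, ``score_``.
    """

    def __init__(self, b_min=1, b_max=4, n_restarts=5, random_state=0):
        self.b_min = b_min
        self.b_max = b_max
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValueError("empty graph")
        nodes = sorted(graph.nodes())
        adjacency = nx.to_numpy_array(graph, nodelist=nodes)
        n = len(nodes)
        rng = np.random.default_rng(self.random_state)
        best = None
        for B in range(self.b_min, min(self.b_max, n) + 1):
            for _ in range(self.n_restarts):
                labels = self._agglomerate(adjacency, B, rng)
                labels = self._refine(adjacency, labels, B, rng)
                score = sbm_penalized_score(adjacency, labels)
                if best is None or score > best[1]:
                    best = (labels, score)
        labels, score = best
        # renumber blocks consecutively
        _, labels = np.unique(labels, return_inverse=True)
        self.nodes_ = nodes
        self.labels_ = {node: int(lbl) for node, lbl in zip(nodes, labels)}
        self.n_blocks_ = int(labels.max()) + 1
        self.log_likelihood_ = sbm_log_likelihood(adjacency, labels)
        self.score_ = float(score)
        return self

    def _agglomerate(self, adjacency, B, rng):
        n = len(adjacency)
        labels = rng.permutation(n) % max(n, 1)  # start: one block per node
        labels = np.arange(n)
        current = n
        while current > B:
            blocks = np.unique(labels)
            best_merge, best_score = None, -np.inf
            # sample candidate merges to keep this O(B^2) bounded
            pairs = [(r, s) for i, r in enumerate(blocks) for s in blocks[i + 1:]]
            if len(pairs) > 200:
                pairs = [pairs[i] for i in rng.choice(len(pairs), 200, replace=False)]
            for r, s in pairs:
                trial = labels.copy()
                trial[trial == s] = r
                score = sbm_log_likelihood(adjacency, trial)
                if score > best_score:
                    best_score, best_merge = score, (r, s)
            r, s = best_merge
            labels[labels == s] = r
            current -= 1
        _, labels = np.unique(labels, return_inverse=True)
        return labels

    def _refine(self, adjacency, labels, B, rng, max_sweeps=10):
        n = len(adjacency)
        labels = labels.copy()
        for _ in range(max_sweeps):
            improved = False
            for i in rng.permutation(n):
                current = sbm_log_likelihood(adjacency, labels)
                best_lbl, best_score = labels[i], current
                for lbl in range(B):
                    if lbl == labels[i]:
                        continue
                    trial = labels.copy()
                    trial[i] = lbl
                    if len(np.unique(trial)) < len(np.unique(labels)):
                        continue  # keep blocks non-empty
                    score = sbm_log_likelihood(adjacency, trial)
                    if score > best_score + 1e-12:
                        best_score, best_lbl = score, lbl
                if best_lbl != labels[i]:
                    labels[i] = best_lbl
                    improved = True
            if not improved:
                break
        return labels


def fit_sbm(graph: nx.Graph, b_range: tuple[int, int] = (1, 4),
            n_restarts: int = 5, seed: int = 0) -> StochasticBlockModel:
    """Functional wrapper over :class:`StochasticBlockModel`."""
    model = StochasticBlockModel(b_min=b_range[0], b_max=b_range[1],
                                 n_restarts=n_restarts, random_state=seed)
    return model.fit(graph)
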