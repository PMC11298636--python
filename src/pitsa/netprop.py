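"""Random-walk-with-restart propagation on protein-interaction networks.

Scores how closely every protein in an interaction network (BioPlex-style
undirected graph) associates with a target protein set: seed proteins get
unit weight, the weight diffuses by a restart random walk, and the real
network's node weights are calibrated against degree-preserving randomized
networks to yield per-node z-scores. High-z nodes plus the seeds form the
display subgraph, pruned of peripheral unquantified degree-1 proteins.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.5
DEFAULT_STEPS = 40
DEFAULT_N_RANDOM = 100
DEFAULT_Z_THRESHOLD = 10.0


def load_network(edges: pd.DataFrame, quantified: dict | None = None) -> nx.Graph:
    """Build an undirected PPI graph from a two-column edge list.

    Self-loops are removed (counted); duplicate edges collapse naturally.
    ``quantified`` maps node id -> bool and is stored as a node attribute.
    """
    g = nx.Graph()
    g.add_edges_from(edges.iloc[:, :2].itertuples(index=False, name=None))
    loops = list(nx.selfloop_edges(g))
    if loops:
        g.remove_edges_from(loops)
        logger.info("removed %d self-loops at network load", len(loops))
    if quantified is not None:
        nx.set_node_attributes(g, {n: bool(quantified.get(n, False)) for n in g}, "quantified")
    return g


def map_orthologs(ids, homology: dict) -> tuple[list, list]:
    """Map gene ids through a many-to-one homology table (e.g. mouse ->
    human Entrez). Returns (mapped ids in input order, unmapped ids)."""
    mapped, unmapped = [], []
    for i in ids:
        if i in homology:
            mapped.append(homology[i])
        else:
            unmapped.append(i)
    if unmapped:
        logger.info("ortholog mapping dropped %d of %d ids", len(unmapped), len(ids))
    return mapped, unmapped


def _walk_matrix(g: nx.Graph, nodelist: list) -> sp.csr_array:
    """Row-stochastic degree-normalized adjacency; isolated nodes
    self-transition so total walk weight is conserved."""
    a = nx.to_scipy_sparse_array(g, nodelist=nodelist, format="csr", dtype=float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    isolated = deg == 0
    inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, deg))
    w = sp.diags_array(inv) @ a
    if isolated.any():
        w = (w + sp.diags_array(isolated.astype(float))).tocsr()
    return w


def _seed_vector(g: nx.Graph, seeds, nodelist: list) -> np.ndarray:
    present = [s for s in seeds if s in g]
    dropped = len(set(seeds)) - len(set(present))
    if dropped:
        logger.info("dropped %d seed proteins absent from the network", dropped)
    if not present:
        raise ValueError("empty seed set after restricting to network nodes")
    idx = {n: i for i, n in enumerate(nodelist)}
    w0 = np.zeros(len(nodelist))
    for s in set(present):
        w0[idx[s]] = 1.0
    return w0


def propagate(
    g: nx.Graph,
    seeds,
    restart: float = DEFAULT_RESTART,
    steps: int = DEFAULT_STEPS,
) -> pd.DataFrame:
    """Restart random walk from unit seed weights.

    Each seed starts at weight 1.0; for ``steps`` iterations the weight
    vector updates as ``w <- (1 - restart) * W' w + restart * w0`` with W the
    row-stochastic walk matrix. The total weight equals the number of seeds
    at every step. Returns a DataFrame (node, weight, seed).
    """
    if not 0.0 < restart <= 1.0:
        raise ValueError("restart probability must lie in (0, 1]")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    nodelist = list(g)
    w0 = _seed_vector(g, seeds, nodelist)
    wt = _walk_matrix(g, nodelist).T.tocsr()
    w = w0.copy()
    for _ in range(steps):
        w = (1.0 - restart) * (wt @ w) + restart * w0
    return pd.DataFrame({"node": nodelist, "weight": w, "seed": w0 > 0})


def randomize_network(g: nx.Graph, rng: np.random.Generator | int) -> nx.Graph:
    """Degree-preserving edge scramble by double-edge swaps.

    Attempts 10 x |edges| swaps; each picks two edges (a, b), (c, d) and
    rewires to (a, d), (c, b) when that creates no self-loop or duplicate.
    Every node keeps its exact interaction count. If no legal swap exists
    (e.g. a star), the input topology is returned unchanged with a warning.
    """
    rng = np.random.default_rng(rng)
    edges = [tuple(e) for e in g.edges()]
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to randomize")
    edge_set = {frozenset(e) for e in edges}
    n_swapped = 0
    for _ in range(10 * m):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:  # swap orientation uniformly
            c, d = d, c
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.update((new1, new2))
        edges[i] = (a, d)
        edges[j] = (c, b)
        n_swapped += 1
    if n_swapped == 0:
        logger.warning("no legal degree-preserving swap found; returning network unchanged")
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    out.add_edges_from(edges)
    return out


def propagation_zscores(
    g: nx.Graph,
    seeds,
    n_random: int = DEFAULT_N_RANDOM,
    rng_seed: int = 0,
    restart: float = DEFAULT_RESTART,
    steps: int = DEFAULT_STEPS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Propagation weights calibrated against randomized networks.

    The real network's walk is repeated on ``n_random`` degree-preserving
    randomizations (same seeds, restart and step count); per node,
    ``z = (w_real - mean_rand) / sd_rand`` with the sample (n-1) standard
    deviation. Nodes whose randomized weights have zero spread get an
    undefined z (never selected). ``selected`` flags z strictly above
    ``z_threshold``. Randomization seeds derive from ``rng_seed`` and are
    recorded in ``DataFrame.attrs['randomization_seeds']``.
    """
    if n_random < 2:
        raise ValueError("need n_random >= 2 randomized networks")
    real = propagate(g, seeds, restart=restart, steps=steps)
    children = np.random.SeedSequence(rng_seed).spawn(n_random)
    rand_w = np.empty((n_random, len(real)))
    for k, child in enumerate(children):
        gr = randomize_network(g, np.random.default_rng(child))
        rand_w[k] = propagate(gr, seeds, restart=restart, steps=steps)["weight"].to_numpy()
    mean = rand_w.mean(axis=0)
    sd = rand_w.std(axis=0, ddof=1)
    defined = sd > 0
    z = np.full(len(real), np.nan)
    z[defined] = (real["weight"].to_numpy()[defined] - mean[defined]) / sd[defined]
    out = real.assign(z=z, z_defined=defined, selected=defined & (z > z_threshold))
    out.attrs["randomization_seeds"] = [int(c.generate_state(1)[0]) for c in children]
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("z undefined (zero randomized spread) for %d nodes", n_undef)
    return out


def extract_subgraph(
    result: pd.DataFrame,
    g: nx.Graph,
    seeds,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> nx.Graph:
    """Display subgraph: nodes with z strictly above the threshold plus all
    seed proteins, induced on the network, then iteratively pruned of
    peripheral proteins that were not quantified (node attribute
    ``quantified``) and hang by a single interaction. Seed nodes are never
    pruned."""
    seeds = {s for s in seeds if s in g}
    z = dict(zip(result["node"], result["z"]))
    keep = {n for n in g if np.isfinite(z.get(n, np.nan)) and z[n] > z_threshold} | seeds
    if not keep:
        logger.warning("empty selection at z > %g; returning empty graph", z_threshold)
        return nx.Graph()
    sub = g.subgraph(keep).copy()
    while True:
        prunable = [
            n
            for n in sub
            if n not in seeds and sub.degree(n) == 1 and not sub.nodes[n].get("quantified", False)
        ]
        if not prunable:
            break
        sub.remove_nodes_from(prunable)
    return sub
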