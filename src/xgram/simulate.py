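"""Synthetic association networks and expression data with known truth.

The generators stand in for the two external data sources the method
consumes: a modular protein-association network (emulated by a planted
partition / stochastic block model, whose clusters play the role of
functional modules) and replicated, pre-normalised expression data
following the additive three-component model

    E = s_ik + b_bio + xi_tech,

with ``s`` the condition signal (piecewise constant over clusters by
default), ``b`` a per-(gene, biological replicate) deviation of SD
sigma_b whose within-cluster correlation ``rho_bio`` interpolates
between independent genes (rho = 0) and a whole cluster moving
coherently (rho = 1), and ``xi`` iid technical noise of SD sigma_xi
per measurement.  Every generator is seeded and returns a truth record
so tests can assert parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GeneOrdering, InteractionNetwork

__all__ = [
    "PlantedNetworkSpec",
    "SyntheticExpressionSpec",
    "make_planted_network",
    "make_signal",
    "make_expression",
    "true_ordering",
]


@dataclass
class PlantedNetworkSpec:
    """Planted-partition network: m clusters of c nodes.

    Within-cluster pairs are edges with probability ``p_in``,
    between-cluster pairs with ``p_out``.  ``p_in > p_out`` is what
    makes the clusters recoverable by seriation.
    """

    n_clusters: int = 10
    cluster_size: int = 30
    p_in: float = 0.5
    p_out: float = 0.005
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.n_clusters * self.cluster_size


@dataclass
class SyntheticExpressionSpec:
    """Parameters of the three-component expression model.

    Defaults mirror a small microarray study: log2-scale baseline ~8,
    biological SD 0.3, technical SD 0.5, five biological x four
    technical replicates per condition.
    """

    sigma_b: float = 0.3
    sigma_xi: float = 0.5
    rho_bio: float = 0.0
    n_b: int = 5
    n_a: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.sigma_b < 0 or self.sigma_xi < 0:
            raise ValueError("SDs must be >= 0")
        if not 0.0 <= self.rho_bio <= 1.0:
            raise ValueError("rho_bio must lie in [0, 1]")


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def make_planted_network(
    spec: PlantedNetworkSpec,
) -> tuple[InteractionNetwork, dict[str, int]]:
    """Sample a planted-partition network; returns (network, labels).

    Nodes isolated by the sampling are rewired to one random partner
    in their own cluster, since the ordering is defined only for genes
    with at least one association.
    """
    n = spec.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(spec.seed)
    names = _gene_names(n)
    labels = {names[i]: i // spec.cluster_size for i in range(n)}
    lab = np.repeat(np.arange(spec.n_clusters), spec.cluster_size)
    iu, iv = np.triu_indices(n, k=1)
    same = lab[iu] == lab[iv]
    p = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(p.size) < p
    edges = [(names[a], names[b]) for a, b in zip(iu[keep], iv[keep])]
    # rewire isolated nodes to a within-cluster partner
    degree = np.zeros(n, dtype=int)
    for a, b in zip(iu[keep], iv[keep]):
        degree[a] += 1
        degree[b] += 1
    for i in np.nonzero(degree == 0)[0]:
        cluster = lab[i]
        candidates = np.nonzero((lab == cluster) & (np.arange(n) != i))[0]
        j = int(rng.choice(candidates))
        edges.append((names[i], names[j]))
        degree[i] += 1
        degree[j] += 1
    network = InteractionNetwork.from_edges(edges)
    return network, labels


def true_ordering(labels: dict[str, int]) -> GeneOrdering:
    """The planted ordering: nodes sorted by (cluster, name)."""
    order = sorted(labels, key=lambda g: (labels[g], g))
    return GeneOrdering(order)


def count_recovered_clusters(
    network: InteractionNetwork,
    ordering: GeneOrdering,
    labels: dict[str, int],
    r: int,
) -> int:
    """Planted clusters showing up as window-modularity local maxima.

    Finds local maxima of M_i(r) (peaks at least r apart), assigns each
    peak the majority truth label of its window, and counts the
    distinct clusters claimed.
    """
    from scipy.signal import find_peaks

    from .network import window_modularity

    m = window_modularity(network, ordering, r).values
    peaks, _ = find_peaks(np.nan_to_num(m, nan=0.0), distance=max(r, 1))
    found = set()
    for p in peaks:
        window = ordering.order[max(0, p - r) : p + r + 1]
        labs = [labels[g] for g in window if g in labels]
        if labs:
            found.add(max(set(labs), key=labs.count))
    return len(found)


def make_signal(
    labels: dict[str, int],
    conditions=("A", "B"),
    base: float = 8.0,
    shifted_clusters=None,
    delta: float = 0.5,
    seed: int = 0,
) -> dict[str, pd.Series]:
    """Piecewise-constant condition signals over clusters.

    The first condition sits at ``base`` everywhere; each later
    condition shifts ``shifted_clusters`` (default: ceil(m/5) randomly
    chosen clusters) by ``delta`` -- localized differential peaks.
    """
    genes = sorted(labels, key=lambda g: (labels[g], g))
    lab = np.array([labels[g] for g in genes])
    m = int(lab.max()) + 1
    rng = np.random.default_rng(seed)
    if shifted_clusters is None:
        k = max(1, int(np.ceil(m / 5)))
        shifted_clusters = sorted(rng.choice(m, size=k, replace=False).tolist())
    shifted_clusters = list(shifted_clusters)
    signals = {}
    for idx, cond in enumerate(conditions):
        s = np.full(len(genes), base, dtype=float)
        if idx > 0:
            s[np.isin(lab, shifted_clusters)] += delta
        signals[cond] = pd.Series(s, index=genes)
    return signals


def make_expression(
    labels: dict[str, int],
    expr_spec: SyntheticExpressionSpec,
    signals: dict[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Replicated expression data from the additive model.

    Returns (expression genes x samples, design table, truth record).
    The truth record keeps the signals, every biological draw and the
    generating parameters.  Correlated biological draws are realised
    as b = sigma_b (sqrt(rho) z_cluster + sqrt(1-rho) z_gene), which
    preserves the marginal SD for any rho.
    """
    if signals is None:
        signals = make_signal(labels, seed=expr_spec.seed)
    genes = list(next(iter(signals.values())).index)
    lab = np.array([labels[g] for g in genes])
    n_genes = len(genes)
    rng = np.random.default_rng(expr_spec.seed)
    sb, sx, rho = expr_spec.sigma_b, expr_spec.sigma_xi, expr_spec.rho_bio
    n_clusters = int(lab.max()) + 1

    columns = {}
    design_rows = []
    bio_draws = {}
    for cond, s in signals.items():
        sv = s.loc[genes].to_numpy()
        for b in range(1, expr_spec.n_b + 1):
            z_cluster = rng.standard_normal(n_clusters)
            z_gene = rng.standard_normal(n_genes)
            bio = sb * (np.sqrt(rho) * z_cluster[lab] + np.sqrt(1.0 - rho) * z_gene)
            bio_draws[(cond, b)] = bio.copy()
            for a in range(1, expr_spec.n_a + 1):
                noise = sx * rng.standard_normal(n_genes)
                name = f"{cond}_b{b}_t{a}"
                columns[name] = sv + bio + noise
                design_rows.append(
                    {"sample": name, "condition": cond, "bio_rep": b, "tech_rep": a}
                )
    expression = pd.DataFrame(columns, index=genes)
    design = pd.DataFrame(design_rows)
    truth = {
        "signals": {k: v.loc[genes] for k, v in signals.items()},
        "bio_draws": bio_draws,
        "sigma_b": sb,
        "sigma_xi": sx,
        "rho_bio": rho,
        "n_b": expr_spec.n_b,
        "n_a": expr_spec.n_a,
        "seed": expr_spec.seed,
        "labels": dict(labels),
    }
    return expression, design, truth
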