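"""Protein-protein interaction network statistics for age-annotated proteins.

Loads STRING-style edge lists (combined scores on the 0-1000 scale) over
proteins labelled with an age class -- B (younger, e.g. bilaterian-specific)
or M (older, e.g. metazoan-specific) -- and computes per-protein degrees,
the fraction of B partners, median +/- MAD summaries, a chi-square test of
B-B / B-M / M-M interaction-class mixing against random pairing, rank tests
between groups, and seed-anchored subnetwork extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation_enrichment import StatResult
from .synthetic_data import substream

MAD_SCALE = 1.4826  # consistency constant vs the normal sd


@dataclass
class PpiNetwork:
    node_class: dict[str, str]                 # protein -> "B" | "M"
    edges: dict[frozenset, int]                # unordered pair -> combined score

    def nodes(self) -> list[str]:
        return sorted(self.node_class)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for pair in self.edges:
            if node in pair:
                out |= pair - {node}
        return out


def load_ppi_edges(
    rows: Iterable[tuple[str, str, int]] | str,
    node_classes: Mapping[str, str],
    min_score: int = 400,
) -> PpiNetwork:
    """Build a network from (protein1, protein2, combined_score) rows.

    ``rows`` may be a TSV path with a header line.  Edges below ``min_score``
    are dropped; duplicates collapse keeping the maximum score; self-edges
    are rejected; every endpoint must carry an age class.
    """
    if isinstance(rows, str):
        parsed = []
        with open(rows) as fh:
            header = fh.readline()
            if not header.lower().startswith("protein"):
                fh.seek(0)
            for line in fh:
                a, b, s = line.split()[:3]
                parsed.append((a, b, int(float(s))))
        rows = parsed
    edges: dict[frozenset, int] = {}
    used_nodes: set[str] = set()
    for a, b, score in rows:
        if a == b:
            continue
        for p in (a, b):
            if p not in node_classes:
                raise KeyError(f"protein {p!r} has no age class")
        if score < min_score:
            continue
        key = frozenset((a, b))
        edges[key] = max(edges.get(key, 0), score)
        used_nodes |= {a, b}
    node_class = {p: node_classes[p] for p in node_classes}
    return PpiNetwork(node_class=node_class, edges=edges)


# -- connectivity -----------------------------------------------------------


def median_mad(values: Sequence[float]) -> tuple[float, float]:
    """(median, MAD scaled by 1.4826)."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med))) * MAD_SCALE
    return med, mad


@dataclass
class ConnectivityStats:
    degree: dict[str, int]
    b_fraction: dict[str, float | None]        # None at degree 0
    class_summary: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)


def connectivity_stats(net: PpiNetwork) -> ConnectivityStats:
    """Degrees, per-node B-partner fractions, per-class median +/- MAD."""
    degree = {p: 0 for p in net.node_class}
    b_partners = {p: 0 for p in net.node_class}
    for pair in net.edges:
        a, b = sorted(pair)
        degree[a] += 1
        degree[b] += 1
        if net.node_class[b] == "B":
            b_partners[a] += 1
        if net.node_class[a] == "B":
            b_partners[b] += 1
    b_fraction = {
        p: (b_partners[p] / degree[p]) if degree[p] else None for p in degree
    }
    summary: dict[str, dict[str, tuple[float, float]]] = {}
    for cls in sorted(set(net.node_class.values())):
        members = [p for p in net.node_class if net.node_class[p] == cls]
        degs = [degree[p] for p in members]
        fracs = [b_fraction[p] for p in members if b_fraction[p] is not None]
        summary[cls] = {
            "degree": median_mad(degs) if degs else (float("nan"), float("nan")),
            "b_fraction": median_mad(fracs) if fracs else (float("nan"), float("nan")),
        }
    return ConnectivityStats(degree=degree, b_fraction=b_fraction, class_summary=summary)


# -- interaction-class mixing test ------------------------------------------


@dataclass
class InteractionClassCounts:
    observed: dict[str, float]
    expected: dict[str, float]


def _observed_class_counts(net: PpiNetwork) -> dict[str, int]:
    counts = {"BB": 0, "BM": 0, "MM": 0}
    for pair in net.edges:
        classes = sorted(net.node_class[p] for p in pair)
        counts["".join(classes)] += 1
    return counts


def interaction_class_test(
    net: PpiNetwork,
    null: str = "proportional",
    permutation_reps: int = 100,
    n_swaps: int = 1000,
    seed: int = 0,
) -> tuple[StatResult, InteractionClassCounts]:
    """Chi-square of observed B-B/B-M/M-M counts against a mixing null.

    ``proportional``: expected proportions from random endpoint pairing given
    the class sizes nB, nM (BB : BM : MM = nB(nB-1)/2 : nB nM : nM(nM-1)/2),
    scaled to the edge total; df = 2.  ``permutation``: expectations from
    degree-preserving double edge swaps averaged over replicates.
    """
    if len(set(net.node_class.values())) < 2:
        raise ValueError("both age classes must be present in the network")
    if not net.edges:
        raise ValueError("network has no edges")
    observed = _observed_class_counts(net)
    total = sum(observed.values())

    if null == "proportional":
        nB = sum(1 for c in net.node_class.values() if c == "B")
        nM = len(net.node_class) - nB
        w = {"BB": nB * (nB - 1) / 2, "BM": nB * nM, "MM": nM * (nM - 1) / 2}
        wsum = sum(w.values())
        expected = {k: total * v / wsum for k, v in w.items()}
    elif null == "permutation":
        import networkx as nx

        rng = substream(seed, "ppi-null")
        G = nx.Graph()
        G.add_edges_from(tuple(sorted(p)) for p in net.edges)
        acc = {"BB": 0.0, "BM": 0.0, "MM": 0.0}
        for _ in range(permutation_reps):
            H = G.copy()
            try:
                nx.double_edge_swap(H, nswap=n_swaps, max_tries=n_swaps * 20,
                                    seed=int(rng.integers(2**31)))
            except nx.NetworkXError:
                pass
            for a, b in H.edges():
                key = "".join(sorted((net.node_class[a], net.node_class[b])))
                acc[key] += 1
        expected = {k: v / permutation_reps for k, v in acc.items()}
    else:
        raise ValueError(f"unknown null model {null!r}")

    keys = [k for k in ("BB", "BM", "MM") if expected[k] > 0]
    stat = sum((observed[k] - expected[k]) ** 2 / expected[k] for k in keys)
    df = len(keys) - 1
    p = float(stats.chi2.sf(stat, df=df))
    return (
        StatResult("chisq_classes", statistic=float(stat), p_value=p, details={"df": df}),
        InteractionClassCounts(observed={k: float(observed[k]) for k in observed},
                               expected=expected),
    )


# -- rank tests -------------------------------------------------------------


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U (exact when feasible, else tie-corrected
    normal approximation with continuity correction)."""
    if not len(x) or not len(y):
        raise ValueError("groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return StatResult("mann_whitney", statistic=float(res.statistic),
                      p_value=float(res.pvalue), details={"U": float(res.statistic)})


def kruskal_wallis(*groups: Sequence[float]) -> StatResult:
    """Kruskal-Wallis H with tie correction, chi-square approximation."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        # all values identical: H is 0 by definition (scipy yields nan here)
        stat_v, p = 0.0, 1.0
    else:
        res = stats.kruskal(*groups)
        stat_v, p = float(res.statistic), float(res.pvalue)
    return StatResult("kruskal_wallis", statistic=stat_v, p_value=p,
                      details={"df": len(groups) - 1, "H": stat_v})


def rank_tests(groups: Sequence[Sequence[float]]) -> StatResult:
    """Mann-Whitney for two groups, Kruskal-Wallis for more."""
    if len(groups) == 2:
        return mann_whitney(groups[0], groups[1])
    return kruskal_wallis(*groups)


# -- subnetworks ------------------------------------------------------------


def extract_subnetwork(net: PpiNetwork, seeds: Iterable[str]) -> PpiNetwork:
    """Induced subnetwork on the seed proteins plus their direct partners."""
    seeds = set(seeds)
    unknown = seeds - set(net.node_class)
    if unknown:
        raise KeyError(f"unknown seed protein(s): {sorted(unknown)}")
    keep = set(seeds)
    for pair in net.edges:
        if pair & seeds:
            keep |= pair
    edges = {pair: s for pair, s in net.edges.items() if pair <= keep}
    return PpiNetwork(node_class={p: net.node_class[p] for p in keep}, edges=edges)
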