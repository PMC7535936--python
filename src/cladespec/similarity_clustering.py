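"""Orthology-graph construction and Markov clustering.

All-vs-all local alignment (affine-gap Smith-Waterman, BLOSUM62,
Karlin-Altschul E-values) feeds an OrthoMCL-style weighted graph: ortholog
edges are cross-species reciprocal best hits, in-paralog edges are
same-species pairs mutually closer than either is to any other species, and
co-ortholog edges connect cross-species pairs related through a duplication.
Edge weights are averaged -log10 E-values, normalized per species pair
(orthologs/co-orthologs) or per species (in-paralogs).  The graph is then
clustered with Markov clustering (MCL): alternating expansion and entrywise
inflation of a column-stochastic matrix with self-loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

E_FLOOR = 1e-180


# -- alignment and E-values -------------------------------------------------


@dataclass
class AlignerConfig:
    """Local-alignment scoring and Karlin-Altschul statistics.

    ``lam``/``K`` are the standard gapped BLOSUM62 constants for gap open 11,
    extend 1; ``db_size`` is the effective database residue count used as n
    in E = K * m * n * exp(-lam * S).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    db_size: int | None = None

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        self._aligner = None

    def aligner(self):
        if self._aligner is None:
            from Bio.Align import PairwiseAligner, substitution_matrices

            a = PairwiseAligner()
            a.mode = "local"
            a.substitution_matrix = substitution_matrices.load(self.matrix)
            a.open_gap_score = -(self.gap_open + self.gap_extend)
            a.extend_gap_score = -float(self.gap_extend)
            self._aligner = a
        return self._aligner

    def e_value(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    score: float
    e_value: float
    percent_match: float


def _kmers(s: str, k: int = 4) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def best_evalue(record, reference: Sequence, config: AlignerConfig) -> float:
    """Best (smallest) E-value of ``record`` against a reference set."""
    aligner = config.aligner()
    n = config.db_size or sum(len(r.residues) for r in reference)
    best = math.inf
    for ref in reference:
        s = aligner.score(record.residues, ref.residues)
        e = config.e_value(s, len(record.residues), n)
        best = min(best, e)
    return best


def all_vs_all_similarity(
    records: Sequence,
    config: AlignerConfig | None = None,
    e_cutoff: float = 1e-5,
    min_shared_kmers: int = 2,
) -> list[SimilarityHit]:
    """One hit per ordered pair with local-alignment E < e_cutoff.

    A shared-k-mer prescreen (seed-and-extend spirit) skips pairs without
    ``min_shared_kmers`` common 4-mers; set it to 0 for an exhaustive sweep.
    Output is sorted by (query, subject) and contains no self-hits.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    config = config or AlignerConfig()
    aligner = config.aligner()
    n_db = config.db_size or sum(len(r.residues) for r in records)
    recs = sorted(records, key=lambda r: r.id)
    kmer_sets = [_kmers(r.residues) for r in recs]

    # bucket by k-mer to enumerate candidate pairs
    candidates: set[tuple[int, int]] = set()
    if min_shared_kmers > 0:
        buckets: dict[str, list[int]] = {}
        for i, ks in enumerate(kmer_sets):
            for km in ks:
                buckets.setdefault(km, []).append(i)
        pair_counts: dict[tuple[int, int], int] = {}
        for idxs in buckets.values():
            if len(idxs) > 1:
                for a in range(len(idxs)):
                    for b in range(a + 1, len(idxs)):
                        key = (idxs[a], idxs[b])
                        pair_counts[key] = pair_counts.get(key, 0) + 1
        candidates = {p for p, c in pair_counts.items() if c >= min_shared_kmers}
    else:
        candidates = {(i, j) for i in range(len(recs)) for j in range(i + 1, len(recs))}

    hits: list[SimilarityHit] = []
    for i, j in sorted(candidates):
        a, b = recs[i], recs[j]
        score = aligner.score(a.residues, b.residues)
        e_ab = config.e_value(score, len(a.residues), n_db)
        e_ba = config.e_value(score, len(b.residues), n_db)
        if min(e_ab, e_ba) >= e_cutoff:
            continue
        aln = aligner.align(a.residues, b.residues)[0]
        cols_a = int(sum(e - s for s, e in aln.aligned[0]))
        cols_b = int(sum(e - s for s, e in aln.aligned[1]))
        if e_ab < e_cutoff:
            hits.append(SimilarityHit(a.id, b.id, score, e_ab, cols_a / len(a.residues)))
        if e_ba < e_cutoff:
            hits.append(SimilarityHit(b.id, a.id, score, e_ba, cols_b / len(b.residues)))
    hits.sort(key=lambda h: (h.query, h.subject))
    return hits


def write_hits_tsv(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\te_value\tpercent_match\n")
        for h in hits:
            fh.write(f"{h.query}\t{h.subject}\t{h.score:g}\t{h.e_value:.6g}\t{h.percent_match:.4f}\n")


# -- OrthoMCL-style graph ---------------------------------------------------


@dataclass(frozen=True)
class WeightedEdge:
    a: str
    b: str
    edge_class: str  # ortholog | inparalog | coortholog
    weight: float


def _species(seq_id: str) -> str:
    return seq_id.split("|", 1)[0]


def build_orthomcl_graph(hits: Sequence[SimilarityHit]) -> list[WeightedEdge]:
    """Classify and weight edges following the published OrthoMCL rules.

    Ortholog: cross-species reciprocal best hits (per species pair).
    In-paralog: same-species mutual pairs with E better than either member's
    best cross-species E.  Co-ortholog: cross-species pairs connected through
    an ortholog edge plus in-paralog edges that also share a hit.  Weights
    are the mean of -log10(E) over the available directions (E floored), then
    normalized: ortholog/co-ortholog weights by the mean ortholog weight of
    their species pair, in-paralog weights by the mean weight of in-paralog
    edges (within the species) whose nodes have a cross-species ortholog.
    """
    evalue: dict[tuple[str, str], float] = {}
    score: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for h in hits:
        if h.query == h.subject:
            continue
        key = (h.query, h.subject)
        if key not in evalue or (h.e_value, -h.score) < (evalue[key], -score[key]):
            evalue[key] = h.e_value
            score[key] = h.score
        nodes.add(h.query)
        nodes.add(h.subject)

    def better(q_s: tuple[str, str], than: tuple[str, str]) -> bool:
        # smaller E, then larger raw score, then lexicographic subject id
        a = (evalue[q_s], -score[q_s], q_s[1])
        b = (evalue[than], -score[than], than[1])
        return a < b

    # best cross-species hit per (query, subject-species)
    best_by_species: dict[tuple[str, str], str] = {}
    best_cross_e: dict[str, float] = {}
    for (q, s) in evalue:
        if _species(q) == _species(s):
            continue
        key = (q, _species(s))
        cur = best_by_species.get(key)
        if cur is None or better((q, s), (q, cur)):
            best_by_species[key] = s
        best_cross_e[q] = min(best_cross_e.get(q, math.inf), evalue[(q, s)])

    def pair_weight(x: str, y: str) -> float:
        vals = []
        for key in ((x, y), (y, x)):
            if key in evalue:
                vals.append(-math.log10(max(evalue[key], E_FLOOR)))
        return sum(vals) / len(vals)

    # ortholog edges: reciprocal best hits between species
    ortholog_pairs: set[tuple[str, str]] = set()
    for (q, sp), s in best_by_species.items():
        if best_by_species.get((s, _species(q))) == q:
            ortholog_pairs.add((min(q, s), max(q, s)))

    has_ortholog = {n for pair in ortholog_pairs for n in pair}

    # in-paralog edges
    inparalog_pairs: set[tuple[str, str]] = set()
    for (q, s) in evalue:
        if q >= s or _species(q) != _species(s):
            continue
        if (s, q) not in evalue:
            continue
        e_mutual = max(evalue[(q, s)], evalue[(s, q)])
        bound = min(best_cross_e.get(q, math.inf), best_cross_e.get(s, math.inf))
        if e_mutual < bound:
            inparalog_pairs.add((q, s))

    inpar_adj: dict[str, set[str]] = {}
    for a, b in inparalog_pairs:
        inpar_adj.setdefault(a, set()).add(b)
        inpar_adj.setdefault(b, set()).add(a)

    # co-ortholog edges: (in-paralogs of a) x (in-paralogs of b) around each
    # ortholog edge (a, b), requiring a shared hit
    coortholog_pairs: set[tuple[str, str]] = set()
    for a, b in ortholog_pairs:
        side_a = {a} | inpar_adj.get(a, set())
        side_b = {b} | inpar_adj.get(b, set())
        for x in side_a:
            for y in side_b:
                if x == y or _species(x) == _species(y):
                    continue
                key = (min(x, y), max(x, y))
                if key in ortholog_pairs or key in coortholog_pairs:
                    continue
                if (x, y) in evalue or (y, x) in evalue:
                    coortholog_pairs.add(key)

    # raw weights
    edges: list[tuple[str, str, str, float]] = []
    for a, b in sorted(ortholog_pairs):
        edges.append((a, b, "ortholog", pair_weight(a, b)))
    for a, b in sorted(coortholog_pairs):
        edges.append((a, b, "coortholog", pair_weight(a, b)))
    for a, b in sorted(inparalog_pairs):
        edges.append((a, b, "inparalog", pair_weight(a, b)))

    # normalization
    sp_pair_w: dict[tuple[str, str], list[float]] = {}
    for a, b, cls, w in edges:
        if cls == "ortholog":
            key = tuple(sorted((_species(a), _species(b))))
            sp_pair_w.setdefault(key, []).append(w)
    sp_pair_mean = {k: sum(v) / len(v) for k, v in sp_pair_w.items()}

    inpar_anchor_w: dict[str, list[float]] = {}
    inpar_all_w: dict[str, list[float]] = {}
    for a, b, cls, w in edges:
        if cls == "inparalog":
            sp = _species(a)
            inpar_all_w.setdefault(sp, []).append(w)
            if a in has_ortholog or b in has_ortholog:
                inpar_anchor_w.setdefault(sp, []).append(w)
    inpar_mean = {}
    for sp, ws in inpar_all_w.items():
        anchored = inpar_anchor_w.get(sp)
        pool = anchored if anchored else ws
        inpar_mean[sp] = sum(pool) / len(pool)

    out: list[WeightedEdge] = []
    for a, b, cls, w in edges:
        if cls in ("ortholog", "coortholog"):
            key = tuple(sorted((_species(a), _species(b))))
            denom = sp_pair_mean.get(key)
            norm = w / denom if denom else w
        else:
            denom = inpar_mean.get(_species(a))
            norm = w / denom if denom else w
        out.append(WeightedEdge(a, b, cls, norm))
    return out


# -- Markov clustering ------------------------------------------------------


@dataclass
class MclConfig:
    inflation: float = 1.5
    expansion: int = 2
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-6
    max_iterations: int = 200

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: frozenset[str]

    @property
    def species(self) -> frozenset[str]:
        return frozenset(_species(m) for m in self.members)


class MclConvergenceError(RuntimeError):
    pass


def _mcl_component(nodes: list[str], weights: Mapping[tuple[str, str], float],
                   config: MclConfig) -> list[set[str]]:
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in weights.items():
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    # self-loops: node's maximum incident weight (regularization)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(config.max_iterations):
        prev = M
        M = np.linalg.matrix_power(M, config.expansion)
        M = M ** config.inflation
        M[M < config.prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < config.convergence_tol:
            break
    else:
        raise MclConvergenceError(
            f"MCL did not converge in {config.max_iterations} iterations "
            f"on component containing {nodes[0]!r} ({n} nodes)"
        )
    # attractor-based extraction: rows with mass on the diagonal define
    # clusters; overlapping attractor rows are merged
    clusters: list[set[int]] = []
    for i in range(n):
        if M[i, i] > config.prune_threshold:
            members = set(np.nonzero(M[i] > config.prune_threshold)[0])
            merged = False
            for c in clusters:
                if c & members:
                    c |= members
                    merged = True
                    break
            if not merged:
                clusters.append(members)
    # repeated merge passes in case of chained overlaps
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    return [{nodes[i] for i in c} for c in clusters]


def mcl_cluster(
    edges: Sequence[WeightedEdge],
    config: MclConfig | None = None,
    keep_singletons: bool = False,
) -> list[Orthogroup]:
    """Cluster the weighted graph; singletons dropped unless requested;
    OG ids assigned by descending size then smallest member id."""
    config = config or MclConfig()
    if not edges:
        raise ValueError("empty graph")
    import networkx as nx

    G = nx.Graph()
    for e in edges:
        w = max(e.weight, 0.0)
        if G.has_edge(e.a, e.b):
            G[e.a][e.b]["weight"] = max(G[e.a][e.b]["weight"], w)
        else:
            G.add_edge(e.a, e.b, weight=w)

    all_clusters: list[set[str]] = []
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        weights = {
            (a, b): d["weight"] for a, b, d in G.subgraph(comp).edges(data=True)
        }
        all_clusters.extend(_mcl_component(nodes, weights, config))

    if not keep_singletons:
        all_clusters = [c for c in all_clusters if len(c) >= 2]
    all_clusters.sort(key=lambda c: (-len(c), min(c)))
    return [
        Orthogroup(og_id=f"OG_{i + 1}", members=frozenset(c))
        for i, c in enumerate(all_clusters)
    ]


def select_orthogroups(groups: Iterable[Orthogroup], min_species: int = 10) -> list[Orthogroup]:
    """Groups with at least ``min_species`` distinct species."""
    return [g for g in groups if len(g.species) >= min_species]


# -- mapping external queries ----------------------------------------------


def map_external_queries(
    queries: Sequence,
    db_records: Sequence,
    groups: Sequence[Orthogroup],
    min_identity: float = 0.95,
    min_len: int = 100,
    min_species: int = 75,
    config: AlignerConfig | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Map queries onto orthogroups via high-identity local hits.

    A query maps to its best hit's orthogroup iff the alignment identity
    exceeds ``min_identity`` over at least ``min_len`` aligned residues and
    the orthogroup spans at least ``min_species`` species.  Returns
    (query id -> og id, unmapped query ids).
    """
    config = config or AlignerConfig()
    aligner = config.aligner()
    member_to_og = {m: g.og_id for g in groups for m in g.members}
    big_enough = {g.og_id for g in groups if len(g.species) >= min_species}
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    db = sorted(db_records, key=lambda r: r.id)
    for q in queries:
        best = None  # (score desc key, subject)
        for rec in db:
            s = aligner.score(q.residues, rec.residues)
            if best is None or (s, rec.id) > best[:2]:
                best = (s, rec.id, rec)
        ok = False
        if best is not None:
            aln = aligner.align(q.residues, best[2].residues)[0]
            counts = aln.counts()
            aligned_cols = int(sum(e - s for s, e in aln.aligned[0]))
            identity = counts.identities / aligned_cols if aligned_cols else 0.0
            og = member_to_og.get(best[1])
            if (identity > min_identity and aligned_cols >= min_len
                    and og is not None and og in big_enough):
                mapping[q.id] = og
                ok = True
        if not ok:
            unmapped.append(q.id)
    return mapping, unmapped


# -- groups-file dialect ----------------------------------------------------


def write_groups_file(groups: Iterable[Orthogroup], path) -> None:
    """OrthoMCL groups dialect: ``OG_17: id1 id2 ...`` (members sorted)."""
    with open(path, "w") as fh:
        for g in groups:
            fh.write(f"{g.og_id}: " + " ".join(sorted(g.members)) + "\n")


def read_groups_file(path) -> list[Orthogroup]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            og_id, members = line.split(":", 1)
            out.append(Orthogroup(og_id=og_id.strip(), members=frozenset(members.split())))
    return out
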