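"""Profile-based error correction of lineage-specific orthogroup sets.

For each orthogroup a multiple alignment is built (progressive,
identity-guided), converted to a per-column amino-acid emission profile, and
searched all-vs-all against the other profiles with a log-odds co-emission
score.  Reciprocal best hits between profiles reveal orthogroups that a
sequence-level clustering split apart; a lineage-specific candidate whose
reciprocal partner contains species outside the focal clade betrays a more
ancient origin and is removed from the final set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synthetic_data import AMINO_ACIDS, substream
from .taxonomy_filters import TaxonomyTable

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_NEG = -1e30


def _blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    B = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            B[i, j] = m[a, b]
    return B


_BLOSUM62 = None


def _blosum62() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = _blosum62_matrix()
    return _BLOSUM62


# -- affine-gap dynamic programming ----------------------------------------


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float, local: bool):
    """Gotoh alignment over a precomputed column-pair score matrix.

    Rows are vectorized; the E recurrence (gap consuming columns of the
    second axis) is resolved with a running-maximum scan.  Returns
    (score, ops) where ops is a list of ('M', i, j) / ('D', i, None) /
    ('I', None, j) steps in order.  Ties break deterministically
    (match > gap-in-2 > gap-in-1).
    """
    n1, n2 = S.shape
    H = np.full((n1 + 1, n2 + 1), _NEG)
    E = np.full((n1 + 1, n2 + 1), _NEG)  # gap consuming axis-2 columns
    F = np.full((n1 + 1, n2 + 1), _NEG)  # gap consuming axis-1 columns
    H[0, 0] = 0.0
    j_idx = np.arange(1, n2 + 1)
    if local:
        H[0, :] = 0.0
        H[:, 0] = 0.0
    else:
        H[0, 1:] = -gap_open - (j_idx - 1) * gap_extend
        E[0, 1:] = H[0, 1:]
        i_idx = np.arange(1, n1 + 1)
        H[1:, 0] = -gap_open - (i_idx - 1) * gap_extend
        F[1:, 0] = H[1:, 0]
    for i in range(1, n1 + 1):
        F[i, 1:] = np.maximum(H[i - 1, 1:] - gap_open, F[i - 1, 1:] - gap_extend)
        G = np.maximum(H[i - 1, :-1] + S[i - 1, :], F[i, 1:])
        if local:
            G = np.maximum(G, 0.0)
        # E[i, j] = max_{k<j} G'[k] - open - (j-1-k)*ext, with G'[0] = H[i, 0]
        base = np.concatenate(([H[i, 0]], G[:-1]))
        a = np.maximum.accumulate(base + gap_extend * np.arange(n2))
        E[i, 1:] = a - gap_open - gap_extend * (j_idx - 1)
        H[i, 1:] = np.maximum(G, E[i, 1:])
        if local:
            H[i, 1:] = np.maximum(H[i, 1:], 0.0)

    if local:
        flat = int(np.argmax(H))
        i, j = divmod(flat, n2 + 1)
        score = float(H[i, j])
    else:
        i, j = n1, n2
        score = float(H[n1, n2])

    ops: list[tuple] = []
    state = "H"
    tol = 1e-9
    while i > 0 or j > 0:
        if local and state == "H" and H[i, j] <= tol:
            break
        if state == "H":
            diag = H[i - 1, j - 1] + S[i - 1, j - 1] if i > 0 and j > 0 else _NEG
            if i > 0 and j > 0 and abs(H[i, j] - diag) < tol:
                ops.append(("M", i - 1, j - 1))
                i, j = i - 1, j - 1
            elif abs(H[i, j] - F[i, j]) < tol:
                state = "F"
            elif abs(H[i, j] - E[i, j]) < tol:
                state = "E"
            elif not local and j == 0:
                ops.append(("D", i - 1, None))
                i -= 1
            elif not local and i == 0:
                ops.append(("I", None, j - 1))
                j -= 1
            else:  # numerical fallback
                state = "F" if F[i, j] >= E[i, j] else "E"
        elif state == "F":
            ops.append(("D", i - 1, None))
            if abs(F[i, j] - (H[i - 1, j] - gap_open)) < tol:
                state = "H"
            i -= 1
        else:  # state == "E"
            ops.append(("I", None, j - 1))
            if abs(E[i, j] - (H[i, j - 1] - gap_open)) < tol:
                state = "H"
            j -= 1
    ops.reverse()
    return score, ops


# -- multiple alignment -----------------------------------------------------


@dataclass
class MultipleAlignment:
    og_id: str
    rows: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("unequal row lengths")


def _freq_matrix(rows: Mapping[str, str]) -> np.ndarray:
    """Per-column residue frequencies, normalized over non-gap residues."""
    ids = sorted(rows)
    L = len(rows[ids[0]])
    counts = np.zeros((L, 20))
    for rid in ids:
        for j, a in enumerate(rows[rid]):
            if a in _AA_INDEX:
                counts[j, _AA_INDEX[a]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals


def _merge_alignments(left: dict[str, str], right: dict[str, str],
                      gap_open: float = 11.0, gap_extend: float = 1.0) -> dict[str, str]:
    """Profile-to-profile global alignment of two sub-alignments."""
    Fl = _freq_matrix(left)
    Fr = _freq_matrix(right)
    S = Fl @ _blosum62() @ Fr.T
    _, ops = _affine_dp(S, gap_open, gap_extend, local=False)
    out = {rid: [] for rid in list(left) + list(right)}
    for op, i, j in ops:
        for rid, row in left.items():
            out[rid].append(row[i] if op in ("M", "D") else "-")
        for rid, row in right.items():
            out[rid].append(row[j] if op in ("M", "I") else "-")
    return {rid: "".join(chars) for rid, chars in out.items()}


def build_msa(og_id: str, sequences: Mapping[str, str]) -> MultipleAlignment:
    """Progressive alignment: identity-based single-linkage guide, profile merges.

    Deterministic: merge order breaks ties on the lexicographically smallest
    member pair.  An externally produced alignment can be wrapped in
    MultipleAlignment directly instead.
    """
    from .orf_extraction import global_identity

    ids = sorted(sequences)
    if not ids:
        raise ValueError("orthogroup has no member sequences")
    if len(ids) == 1:
        return MultipleAlignment(og_id, {ids[0]: sequences[ids[0]]})

    sim = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sim[(ids[i], ids[j])] = global_identity(sequences[ids[i]], sequences[ids[j]])

    clusters: dict[str, dict[str, str]] = {rid: {rid: sequences[rid]} for rid in ids}
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                a, b = keys[x], keys[y]
                link = max(
                    sim[(min(p, q), max(p, q))]
                    for p in clusters[a] for q in clusters[b]
                )
                cand = (-link, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        clusters[a] = _merge_alignments(clusters[a], clusters[b])
        del clusters[b]
    rows = next(iter(clusters.values()))
    msa = MultipleAlignment(og_id, rows)
    msa.validate()
    return msa


def write_aligned_fasta(msa: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(msa.rows):
            fh.write(f">{rid}\n")
            row = msa.rows[rid]
            for i in range(0, len(row), 60):
                fh.write(row[i:i + 60] + "\n")


# -- profiles ---------------------------------------------------------------


@dataclass
class ProfileModel:
    """Match-column emission profile of an orthogroup alignment."""

    og_id: str
    emissions: np.ndarray       # (L, 20), rows sum to 1
    background: np.ndarray      # (20,), sums to 1
    column_occupancy: np.ndarray  # (L,) fraction non-gap

    @property
    def L(self) -> int:
        return self.emissions.shape[0]


def build_profile(msa: MultipleAlignment, alpha: float = 1.0,
                  occupancy_threshold: float = 0.5) -> ProfileModel:
    """Columns with occupancy >= threshold become match columns.

    emission(a) = (count(a) + alpha * f(a)) / (n_nongap + alpha), with the
    background f estimated from all residues in the alignment.
    """
    msa.validate()
    ids = sorted(msa.rows)
    n_rows = len(ids)
    L_all = msa.n_columns
    counts = np.zeros((L_all, 20))
    for rid in ids:
        for j, a in enumerate(msa.rows[rid]):
            if a in _AA_INDEX:
                counts[j, _AA_INDEX[a]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no standard residues")
    background = counts.sum(axis=0) / total
    occupancy = counts.sum(axis=1) / n_rows
    match = occupancy >= occupancy_threshold
    if not match.any():
        match = occupancy == occupancy.max()
    c = counts[match]
    nongap = c.sum(axis=1, keepdims=True)
    emissions = (c + alpha * background) / (nongap + alpha)
    # renormalize to absorb rounding in the background estimate
    emissions /= emissions.sum(axis=1, keepdims=True)
    return ProfileModel(msa.og_id, emissions, background, occupancy[match])


def write_profile(profile: ProfileModel, path) -> None:
    """Plain-text profile table: one line per match column, 20 emissions."""
    with open(path, "w") as fh:
        fh.write(f"# profile {profile.og_id} columns={profile.L} alphabet={AMINO_ACIDS}\n")
        fh.write("# background\t" + "\t".join(f"{x:.6f}" for x in profile.background) + "\n")
        for i in range(profile.L):
            fh.write(f"{profile.column_occupancy[i]:.4f}\t"
                     + "\t".join(f"{x:.6f}" for x in profile.emissions[i]) + "\n")


def read_profile(path) -> ProfileModel:
    background = None
    occ, rows = [], []
    og_id = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# profile"):
                og_id = line.split()[2]
            elif line.startswith("# background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.strip():
                parts = line.split("\t")
                occ.append(float(parts[0]))
                rows.append([float(x) for x in parts[1:]])
    return ProfileModel(og_id, np.array(rows), background, np.array(occ))


# -- profile-profile search -------------------------------------------------


@dataclass(frozen=True)
class ProfileHit:
    query: str
    subject: str
    score: float        # bits
    aligned_columns: int


def profile_pair_score(
    p: ProfileModel, q: ProfileModel,
    gap_open: float = 3.0, gap_extend: float = 0.3,
) -> tuple[float, int]:
    """Local log-odds alignment of two profiles.

    Column score s(i,j) = log2(sum_a p_i(a) q_j(a) / f(a)) with f the mean of
    the two backgrounds, so the score is symmetric in its arguments.
    """
    f = (p.background + q.background) / 2.0
    f = np.maximum(f, 1e-6)
    S = np.log2(np.maximum(p.emissions @ (q.emissions / f).T, 1e-12))
    score, ops = _affine_dp(S, gap_open, gap_extend, local=True)
    cols = sum(1 for op, _, _ in ops if op == "M")
    return score, cols


def profile_search(
    query: ProfileModel,
    db: Sequence[ProfileModel],
    gap_open: float = 3.0,
    gap_extend: float = 0.3,
    min_cols: int = 20,
) -> list[ProfileHit]:
    """Ranked hits of one profile against a profile database.

    Hits shorter than ``min_cols`` aligned columns are discarded; ranking is
    by descending score with lexicographic subject id as tie-break.
    """
    if not db:
        raise ValueError("profile database is empty")
    hits = []
    for subject in db:
        score, cols = profile_pair_score(query, subject, gap_open, gap_extend)
        if cols >= min_cols:
            hits.append(ProfileHit(query.og_id, subject.og_id, score, cols))
    hits.sort(key=lambda h: (-h.score, h.subject))
    return hits


def all_vs_all_profile_search(
    profiles: Sequence[ProfileModel],
    gap_open: float = 3.0,
    gap_extend: float = 0.3,
    min_cols: int = 20,
    min_score: float | None = None,
) -> dict[str, list[ProfileHit]]:
    """Ranked hit lists per profile (each unordered pair scored once)."""
    ranked: dict[str, list[ProfileHit]] = {p.og_id: [] for p in profiles}
    for i in range(len(profiles)):
        for j in range(i, len(profiles)):
            p, q = profiles[i], profiles[j]
            score, cols = profile_pair_score(p, q, gap_open, gap_extend)
            if cols < min_cols or (min_score is not None and score < min_score):
                continue
            ranked[p.og_id].append(ProfileHit(p.og_id, q.og_id, score, cols))
            if i != j:
                ranked[q.og_id].append(ProfileHit(q.og_id, p.og_id, score, cols))
    for og in ranked:
        ranked[og].sort(key=lambda h: (-h.score, h.subject))
    return ranked


def calibrate_score_threshold(
    profiles: Sequence[ProfileModel],
    n_trials: int = 100,
    quantile: float | None = None,
    seed: int = 0,
    e_chance: float = 0.01,
    n_comparisons: int | None = None,
) -> float:
    """Empirical-null significance threshold for profile-profile scores.

    Column-shuffles random pairs of distinct profiles (destroying positional
    correspondence while preserving composition) to sample the null score
    distribution.  By default a Gumbel (extreme-value) distribution is fitted
    to the null scores -- the standard model for optimal local-alignment
    scores -- and the threshold is set so the expected number of chance hits
    over ``n_comparisons`` searches is ``e_chance``.  Passing ``quantile``
    instead returns that plain empirical quantile.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to calibrate")
    rng = substream(seed, "profile-null")
    scores = []
    for _ in range(n_trials):
        i, j = rng.choice(len(profiles), size=2, replace=False)
        a, b = profiles[i], profiles[j]
        pa = ProfileModel(a.og_id, a.emissions[rng.permutation(a.L)],
                          a.background, a.column_occupancy)
        pb = ProfileModel(b.og_id, b.emissions[rng.permutation(b.L)],
                          b.background, b.column_occupancy)
        s, _ = profile_pair_score(pa, pb)
        scores.append(s)
    if quantile is not None:
        return float(np.quantile(scores, quantile))
    from scipy import stats as _st

    loc, scale = _st.gumbel_r.fit(scores)
    n_comp = n_comparisons if n_comparisons else len(profiles) * (len(profiles) - 1) // 2
    p_per_pair = min(1.0, e_chance / max(n_comp, 1))
    return float(_st.gumbel_r.isf(p_per_pair, loc=loc, scale=scale))


# -- reciprocal best hits and lineage-set correction ------------------------


def reciprocal_best_hits(all_hits: Mapping[str, Sequence[ProfileHit]]) -> set[tuple[str, str]]:
    """(A, B) is an RBH iff each is the other's top-ranked non-self hit."""
    top: dict[str, str] = {}
    for og, hits in all_hits.items():
        for h in hits:
            if h.subject != og:
                top[og] = h.subject
                break
    pairs = set()
    for a, b in top.items():
        if top.get(b) == a:
            pairs.add((min(a, b), max(a, b)))
    return pairs


@dataclass(frozen=True)
class ValidationVerdict:
    og_id: str
    status: str          # retained | removed_ancient | merged
    partner: str | None
    reason: str


def correct_lineage_set(
    candidates: Iterable[str],
    rbh: set[tuple[str, str]],
    og_species: Mapping[str, Iterable[int]],
    taxonomy: TaxonomyTable,
    focal_clade: str = "Bilateria",
) -> list[ValidationVerdict]:
    """Remove candidates whose reciprocal partner betrays an older origin.

    A candidate is ``removed_ancient`` iff it has an RBH partner whose
    composition includes at least one species outside the focal clade;
    otherwise it is retained.
    """
    partner_of: dict[str, str] = {}
    for a, b in rbh:
        partner_of[a] = b
        partner_of[b] = a
    verdicts = []
    for og in sorted(candidates):
        partner = partner_of.get(og)
        if partner is None:
            verdicts.append(ValidationVerdict(og, "retained", None, "no reciprocal partner"))
            continue
        outside = [
            t for t in og_species.get(partner, ())
            if not taxonomy.is_within(t, focal_clade)
        ]
        if outside:
            verdicts.append(ValidationVerdict(
                og, "removed_ancient", partner,
                f"partner {partner} has {len(outside)} species outside {focal_clade}",
            ))
        else:
            verdicts.append(ValidationVerdict(
                og, "retained", partner, "partner composition within focal clade"))
    return verdicts
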