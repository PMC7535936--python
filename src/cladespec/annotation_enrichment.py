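"""Domain-annotation counting and enrichment statistics.

Consumes domain-scan tables (PfamScan column layout), counts
transcription-factor proteins (ten DNA-binding domain prefixes) and poly-zinc
-finger proteins (>= 6 zf-C2H2 copies), draws size-matched random control
sets from a reference proteome, and runs the enrichment tests: an upper-tail
normal probability from the control mean/sd, a binomial tail bound, and a
2x2 Pearson chi-square with Yates continuity correction.  Domains are mapped
to GO terms through a pfam2go flat file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .synthetic_data import substream

#: the ten DNA-binding domain prefixes that define a transcription factor here
TF_DOMAIN_PREFIXES: tuple[str, ...] = (
    "Basic", "bZIP_2", "HLH", "HNF-1_N", "Homeobox",
    "Hox9_act", "HPD", "SOBP", "THAP", "zf-",
)

DEFAULT_E_CUTOFF = 5e-5


@dataclass(frozen=True)
class DomainAnnotation:
    protein: str
    domain: str
    accession: str
    e_value: float
    start: int
    end: int


@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    details: dict = field(default_factory=dict)


# -- loading ----------------------------------------------------------------


def load_domain_annotations(
    path, e_cutoff: float = DEFAULT_E_CUTOFF
) -> tuple[list[DomainAnnotation], list[tuple[int, str]]]:
    """Parse a PfamScan-layout table, keeping rows with e_value < cutoff.

    Columns: protein, aln start/end, env start/end, accession, name, type,
    hmm start/end/length, bit score, e-value (tab- or whitespace-separated).
    Returns (annotations, malformed rows as (line number, reason)).
    """
    annotations: list[DomainAnnotation] = []
    malformed: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 13:
                malformed.append((lineno, f"expected 13 columns, got {len(fields)}"))
                continue
            try:
                ann = DomainAnnotation(
                    protein=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    accession=fields[5],
                    domain=fields[6],
                    e_value=float(fields[12]),
                )
            except ValueError as exc:
                malformed.append((lineno, str(exc)))
                continue
            if ann.e_value < e_cutoff:
                annotations.append(ann)
    return annotations, malformed


# -- domain-class counting --------------------------------------------------


def is_tf_domain(domain: str, prefixes: Sequence[str] = TF_DOMAIN_PREFIXES) -> bool:
    return any(domain.startswith(p) for p in prefixes)


def count_domain_classes(
    annotations: Iterable[DomainAnnotation],
    tf_prefixes: Sequence[str] = TF_DOMAIN_PREFIXES,
    zf_domain: str = "zf-C2H2",
    min_fingers: int = 6,
) -> tuple[int, int]:
    """(TF protein count, poly-ZF protein count).

    A protein is a TF iff any of its domains matches a prefix; poly-ZF iff it
    carries >= min_fingers copies of the zinc-finger domain.  Insensitive to
    annotation row order.
    """
    tf_proteins: set[str] = set()
    zf_copies: dict[str, int] = {}
    for ann in annotations:
        if is_tf_domain(ann.domain, tf_prefixes):
            tf_proteins.add(ann.protein)
        if ann.domain == zf_domain:
            zf_copies[ann.protein] = zf_copies.get(ann.protein, 0) + 1
    polyzf = sum(1 for c in zf_copies.values() if c >= min_fingers)
    return len(tf_proteins), polyzf


def tf_flags(annotations: Iterable[DomainAnnotation], proteins: Sequence[str],
             tf_prefixes: Sequence[str] = TF_DOMAIN_PREFIXES) -> np.ndarray:
    """Boolean TF flag per protein id in ``proteins`` order."""
    tf = {a.protein for a in annotations if is_tf_domain(a.domain, tf_prefixes)}
    return np.array([p in tf for p in proteins], dtype=bool)


# -- control draws ----------------------------------------------------------


def control_draw_stats(
    proteome_tf_flags: Sequence[bool], n: int, reps: int = 10, seed: int = 0
) -> tuple[float, float, list[int]]:
    """TF counts in ``reps`` random draws of ``n`` proteins without replacement.

    Returns (mean, sample sd with ddof=1, per-replicate counts).
    """
    flags = np.asarray(proteome_tf_flags, dtype=bool)
    if n > flags.size:
        raise ValueError(f"draw size {n} exceeds proteome size {flags.size}")
    rng = substream(seed, "control-draws")
    counts = [int(flags[rng.choice(flags.size, size=n, replace=False)].sum())
              for _ in range(reps)]
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1)) if reps > 1 else 0.0
    return mean, sd, counts


# -- the three enrichment tests ---------------------------------------------


def normal_tail_p(x: float, mu: float, sigma: float) -> StatResult:
    """Upper-tail probability P(X > x) for X ~ Normal(mu, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    p = float(stats.norm.sf(x, loc=mu, scale=sigma))
    return StatResult("normal_tail", statistic=(x - mu) / sigma, p_value=p,
                      details={"mu": mu, "sigma": sigma})


def binomial_tail_p(k: int, n: int, p: float) -> StatResult:
    """P(X >= k) for X ~ Binomial(n, p), by log-space summation."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k == 0:
        tail = 1.0
    else:
        ks = np.arange(k, n + 1)
        tail = float(np.exp(logsumexp(stats.binom.logpmf(ks, n, p))))
    return StatResult("binomial_tail", statistic=float(k), p_value=min(tail, 1.0),
                      details={"n": n, "p": p})


def chisq_2x2(table: Sequence[Sequence[float]], yates: bool = True) -> StatResult:
    """Pearson chi-square on a 2x2 table, df=1.

    With ``yates`` the continuity correction min(0.5, |O-E|) is subtracted
    from each |O-E| (so O = E yields a statistic of exactly 0).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = row @ col / total
    diff = np.abs(obs - expected)
    if yates:
        diff = diff - np.minimum(0.5, diff)
    stat = float((diff ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return StatResult("chisq_2x2", statistic=stat, p_value=p,
                      details={"df": 1, "yates": yates})


# -- GO mapping -------------------------------------------------------------


def parse_pfam2go(lines: Iterable[str]) -> dict[str, list[tuple[str, str]]]:
    """Parse pfam2go flat-file lines.

    Format: ``Pfam:PF00046 Homeobox > GO:... ; GO:0003677``.  Returns
    accession (without version) -> [(GO name, GO id), ...].
    """
    mapping: dict[str, list[tuple[str, str]]] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        try:
            lhs, rhs = line.split(">", 1)
            acc = lhs.split()[0].split(":", 1)[1]
            go_name, go_id = rhs.rsplit(";", 1)
        except (ValueError, IndexError):
            continue
        mapping.setdefault(acc, []).append((go_name.strip(), go_id.strip()))
    return mapping


def map_go_terms(
    annotations: Iterable[DomainAnnotation],
    pfam2go: Mapping[str, list[tuple[str, str]]],
) -> tuple[dict[str, float], int]:
    """GO-term relative frequencies over mapped domains.

    Each annotated domain joins all its GO terms; domains without a mapping
    are tallied separately.  Relative frequencies sum to 1 over mapped terms.
    Returns (GO id -> relative frequency, unmapped domain count).
    """
    counts: dict[str, int] = {}
    unmapped = 0
    for ann in annotations:
        acc = ann.accession.split(".")[0]
        terms = pfam2go.get(acc)
        if not terms:
            unmapped += 1
            continue
        for _, go_id in terms:
            counts[go_id] = counts.get(go_id, 0) + 1
    total = sum(counts.values())
    freqs = {go: c / total for go, c in counts.items()} if total else {}
    return freqs, unmapped


# -- poly-ZF census over node-specific orthogroup sets ----------------------


def polyzf_node_census(
    rule_passing: Mapping[str, Sequence[str]],
    representative: Mapping[str, str],
    annotations: Iterable[DomainAnnotation],
    zf_domain: str = "zf-C2H2",
    min_fingers: int = 6,
) -> dict[str, int]:
    """Poly-ZF count per node-specific set.

    ``rule_passing`` maps a node name (e.g. "opisthokont") to the og ids that
    pass its composition rule; ``representative`` maps og id to the scanned
    protein (the longest member).  Counts representatives carrying
    >= min_fingers zinc-finger copies.
    """
    copies: dict[str, int] = {}
    for ann in annotations:
        if ann.domain == zf_domain:
            copies[ann.protein] = copies.get(ann.protein, 0) + 1
    out = {}
    for node, ogs in rule_passing.items():
        out[node] = sum(
            1 for og in ogs
            if copies.get(representative.get(og, ""), 0) >= min_fingers
        )
    return out
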