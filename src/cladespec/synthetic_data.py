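"""Synthetic study fixtures with known ground truth.

Generates (i) a labelled opisthokont species tree, (ii) per-species proteomes
produced by gene families born at named internal nodes and evolved down the
tree with per-branch loss, duplication and per-site substitution, (iii)
genome contigs with the proteins embedded in intergenic DNA (to exercise
six-frame ORF extraction and X-run splitting), and (iv) matching
domain-annotation and protein-protein-interaction fixtures with a known
age-class structure.  Every emitted byte is a deterministic function of the
seed; all randomness flows from one seed via named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .taxonomy_filters import TaxonomyTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: first-listed codon per amino acid in the standard genetic code
#: (deterministic back-translation)
_BACK_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG substream derived from one global seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


# -- species tree ----------------------------------------------------------

# Consensus opisthokont backbone; keys are internal clade labels, leaves of
# the dict are the terminal clades species can be placed in.
_BACKBONE: dict = {
    "Opisthokonta": {
        "Fungi": {},
        "Metazoa": {
            "Porifera": {},
            "Ctenophora": {},
            "Eumetazoa": {
                "Cnidaria": {},
                "Bilateria": {
                    "Deuterostomia": {
                        "Vertebrata": {"Gnathostomata": {}},
                        "Ambulacraria": {},
                    },
                    "Protostomia": {
                        "Lophotrochozoa": {},
                        "Ecdysozoa": {
                            "Nematoda": {},
                            "Arthropoda": {
                                "Chelicerata": {},
                                "Myriapoda": {},
                                "Pancrustacea": {"Crustacea": {}, "Insecta": {}},
                            },
                        },
                    },
                },
            },
        },
    }
}

LEAF_TAXID_BASE = 1000


@dataclass
class SpeciesTree:
    """Rooted labelled species tree.

    ``nodes`` lists node ids; ``parent`` maps child -> parent (root maps to
    itself); ``leaf_taxa`` maps leaf node id -> species taxon id;
    ``clade_labels`` maps clade names to internal node ids.
    """

    nodes: list[str]
    parent: dict[str, str]
    leaf_taxa: dict[str, int]
    clade_labels: dict[str, str]

    @property
    def root(self) -> str:
        return next(n for n in self.nodes if self.parent[n] == n)

    def children(self, node: str) -> list[str]:
        return [n for n in self.nodes if self.parent[n] == node and n != node]

    def leaves_below(self, node: str) -> list[str]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            kids = self.children(n)
            if not kids and n in self.leaf_taxa:
                out.append(n)
            stack.extend(sorted(kids, reverse=True))
        return out

    def species_below(self, node: str) -> set[int]:
        return {self.leaf_taxa[l] for l in self.leaves_below(node)}

    def to_taxonomy_table(self) -> TaxonomyTable:
        """Export the tree as a taxonomy table (internal nodes get small ids)."""
        node_taxid: dict[str, int] = {}
        internal = [n for n in self.nodes if n not in self.leaf_taxa]
        for i, n in enumerate(internal, start=1):
            node_taxid[n] = i
        for leaf, taxid in self.leaf_taxa.items():
            node_taxid[leaf] = taxid
        label_of = {v: k for k, v in self.clade_labels.items()}
        parent = {node_taxid[n]: node_taxid[self.parent[n]] for n in self.nodes}
        names = {
            node_taxid[n]: label_of.get(n, n) for n in self.nodes
        }
        return TaxonomyTable(parent, names)


def _terminal_clades(sub: dict | None = None, acc: list | None = None) -> list[str]:
    if sub is None:
        sub = _BACKBONE
    if acc is None:
        acc = []
    for label, kids in sub.items():
        if kids:
            _terminal_clades(kids, acc)
        else:
            acc.append(label)
    return acc


def _descendant_terminals(label: str) -> list[str]:
    """Terminal clades at or below a backbone label, in fixed backbone order."""

    def find(sub: dict) -> dict | None:
        for k, kids in sub.items():
            if k == label:
                return kids if kids else {k: {}}
            hit = find(kids)
            if hit is not None:
                return hit
        return None

    sub = find(_BACKBONE)
    if sub is None:
        raise KeyError(f"unknown clade label {label!r}")
    if sub == {label: {}}:
        return [label]
    return _terminal_clades(sub)


def build_species_fixture(
    n_species_per_clade: Mapping[str, int], seed: int = 0
) -> SpeciesTree:
    """Build a species tree with the requested leaf counts per clade.

    A count requested at an internal clade is distributed round-robin over
    the terminal clades below it (fixed backbone order), so the placement is
    deterministic for a fixed request.
    """
    per_terminal: dict[str, int] = {t: 0 for t in _terminal_clades()}
    for label, count in n_species_per_clade.items():
        if count < 0:
            raise ValueError(f"negative species count for {label!r}")
        terminals = _descendant_terminals(label)
        for i in range(count):
            per_terminal[terminals[i % len(terminals)]] += 1
    total = sum(per_terminal.values())
    if total == 0:
        raise ValueError("zero total species requested")

    nodes: list[str] = []
    parent: dict[str, str] = {}
    clade_labels: dict[str, str] = {}

    def walk(label: str, kids: dict, par: str | None) -> None:
        nodes.append(label)
        parent[label] = par if par is not None else label
        clade_labels[label] = label
        for k, sub in kids.items():
            walk(k, sub, label)

    for label, kids in _BACKBONE.items():
        walk(label, kids, None)

    leaf_taxa: dict[str, int] = {}
    taxid = LEAF_TAXID_BASE
    for terminal in _terminal_clades():
        for _ in range(per_terminal[terminal]):
            leaf = f"L{taxid}"
            nodes.append(leaf)
            parent[leaf] = terminal
            leaf_taxa[leaf] = taxid
            taxid += 1
    return SpeciesTree(nodes=nodes, parent=parent, leaf_taxa=leaf_taxa,
                       clade_labels=clade_labels)


# -- gene-family simulation ------------------------------------------------


@dataclass
class FamilyParams:
    """Simulation parameters for gene-family birth, loss and divergence.

    Defaults are the package's standard study conditions: 200 families, 10%
    born at the bilaterian ancestor and the rest spread over older and
    younger nodes, 5% per-branch loss, 2% per-branch duplication, 100-residue
    root proteins, and 5% per-site substitution per branch.
    """

    n_families: int = 200
    birth_node_weights: dict[str, float] = field(default_factory=lambda: {
        "Opisthokonta": 0.15, "Metazoa": 0.15, "Bilateria": 0.10,
        "Deuterostomia": 0.12, "Protostomia": 0.12, "Ecdysozoa": 0.12,
        "Lophotrochozoa": 0.12, "Arthropoda": 0.12,
    })
    loss_prob: float = 0.05
    dup_prob: float = 0.02
    root_length: int = 100
    subst_rate: float = 0.05
    seed: int = 0
    #: per-branch substitution-rate overrides, clade label -> rate on the
    #: branch entering that clade (models episodic stem-lineage divergence,
    #: e.g. metazoan families whose bilaterian members diverged so strongly
    #: that sequence-level clustering pulls the two sides apart)
    stem_rate_boost: dict[str, float] = field(default_factory=dict)
    #: family-id prefix, so batches simulated with different parameters can
    #: be combined without id collisions
    fam_prefix: str = "F"

    def validate(self) -> None:
        for p in (self.loss_prob, self.dup_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.birth_node_weights.values()) - 1.0) > 1e-9:
            raise ValueError("birth_node_weights must sum to 1")
        if self.root_length < 50:
            raise ValueError("root_length must be >= 50")
        if self.n_families < 1:
            raise ValueError("need at least one family")


@dataclass
class FamilyTruth:
    birth_node: str
    surviving_species: set[int]
    members: list[str]


@dataclass
class GroundTruth:
    """family_id -> (birth node, surviving species, member sequence ids)."""

    families: dict[str, FamilyTruth]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family_id\tbirth_node\tmember_id\n")
            for fam_id in sorted(self.families):
                t = self.families[fam_id]
                for m in t.members:
                    fh.write(f"{fam_id}\t{t.birth_node}\t{m}\n")

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        fams: dict[str, FamilyTruth] = {}
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("family_id")
            for line in fh:
                fam_id, birth, member = line.rstrip("\n").split("\t")
                t = fams.setdefault(fam_id, FamilyTruth(birth, set(), []))
                t.members.append(member)
                t.surviving_species.add(int(member.split("|")[0]))
        return cls(fams)


def _mutate(seq: np.ndarray, subst_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution to a uniformly chosen *different* amino acid."""
    if subst_rate <= 0:
        return seq.copy()
    hit = rng.random(seq.size) < min(1.0, subst_rate)
    out = seq.copy()
    if hit.any():
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def simulate_gene_families(
    tree: SpeciesTree, params: FamilyParams
) -> tuple[dict[int, list[tuple[str, str]]], GroundTruth]:
    """Evolve gene families down the tree; return per-species proteomes + truth.

    Each family starts from an i.i.d. random root sequence at its birth node.
    Per branch and per gene copy: the copy is lost with ``loss_prob``;
    otherwise each site substitutes with probability ``subst_rate`` and, with
    ``dup_prob``, an independently mutated duplicate (id suffix ``-d<k>``) is
    added.  Emitted ids follow ``<taxid>|ncbi|<family><suffix>``.
    """
    params.validate()
    rng = substream(params.seed, "gene-families")
    labels = sorted(params.birth_node_weights)
    weights = np.array([params.birth_node_weights[l] for l in labels])
    for l in labels:
        if l not in tree.clade_labels:
            raise ValueError(f"birth clade {l!r} not labelled in tree")

    proteomes: dict[int, list[tuple[str, str]]] = {t: [] for t in tree.leaf_taxa.values()}
    truth: dict[str, FamilyTruth] = {}

    for i in range(params.n_families):
        fam_id = f"{params.fam_prefix}{i:04d}"
        birth_label = labels[int(rng.choice(len(labels), p=weights))]
        birth_node = tree.clade_labels[birth_label]
        root_seq = rng.integers(0, 20, size=params.root_length)
        dup_counter = [0]
        surviving: set[int] = set()
        members: list[str] = []

        def descend(node: str, copies: list[tuple[str, np.ndarray]]) -> None:
            kids = tree.children(node)
            if not kids:
                taxid = tree.leaf_taxa.get(node)
                if taxid is None:
                    return
                for suffix, seq in copies:
                    seq_id = f"{taxid}|ncbi|{fam_id}{suffix}"
                    proteomes[taxid].append(
                        (seq_id, "".join(AMINO_ACIDS[a] for a in seq))
                    )
                    members.append(seq_id)
                    surviving.add(taxid)
                return
            for child in sorted(kids):
                label = next(
                    (l for l, n in tree.clade_labels.items() if n == child), None)
                branch_rate = params.stem_rate_boost.get(label, params.subst_rate)
                child_copies: list[tuple[str, np.ndarray]] = []
                for suffix, seq in copies:
                    if rng.random() < params.loss_prob:
                        continue
                    evolved = _mutate(seq, branch_rate, rng)
                    child_copies.append((suffix, evolved))
                    if rng.random() < params.dup_prob:
                        dup_counter[0] += 1
                        dup = _mutate(seq, branch_rate, rng)
                        child_copies.append((f"{suffix}-d{dup_counter[0]}", dup))
                if child_copies:
                    descend(child, child_copies)

        descend(birth_node, [("", root_seq)])
        truth[fam_id] = FamilyTruth(birth_label, surviving, members)

    return proteomes, GroundTruth(truth)


# -- genome fixtures -------------------------------------------------------


@dataclass
class GenomeNoise:
    """Noise settings for genome-fixture generation.

    ``x_run_prob`` -- probability per protein of inserting a sequencing-gap
    N-run into its CDS; the run spans ``x_run_codons`` codon-aligned codons
    so it translates to exactly that many 'X' residues.
    ``revcomp_prob`` -- probability of reverse-complementing the finished
    contig (exercises the negative reading frames).
    """

    x_run_prob: float = 0.0
    x_run_codons: int = 12
    revcomp_prob: float = 0.5


@dataclass
class Embedding:
    """Forward-strand record of where a protein was embedded (0-based, half-open)."""

    contig: str
    frame: int
    start: int
    end: int
    protein_id: str
    n_run_at: int | None = None  # residue offset of the inserted X-run, if any
    n_run_codons: int = 0


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(dna: str) -> str:
    return dna.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


def generate_genome_fixture(
    proteome: Iterable[tuple[str, str]],
    noise: GenomeNoise | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[Embedding]]:
    """Back-translate proteins into contigs embedded in random intergenic DNA.

    Each protein is back-translated with the first-listed codon per amino
    acid, flanked by in-frame stop codons, and surrounded by random DNA, so a
    six-frame extraction recovers it exactly.  With ``x_run_prob`` an N-run
    is inserted mid-CDS at a codon boundary to exercise X-run splitting.
    """
    noise = noise or GenomeNoise()
    rng = substream(seed, "genome-fixture")
    contigs: list[tuple[str, str]] = []
    embeddings: list[Embedding] = []
    proteome = list(proteome)
    if not proteome:
        cid = "contig0000"
        contigs.append((cid, _random_dna(rng, 600)))
        return contigs, embeddings

    for idx, (pid, residues) in enumerate(proteome):
        cid = f"contig{idx:04d}"
        cds = "".join(_BACK_CODON[a] for a in residues)
        n_run_at = None
        n_codons = 0
        if noise.x_run_prob > 0 and rng.random() < noise.x_run_prob:
            n_codons = noise.x_run_codons
            codon_pos = len(residues) // 2
            n_run_at = codon_pos
            cds = cds[: 3 * codon_pos] + "N" * (3 * n_codons) + cds[3 * codon_pos:]
        left = _random_dna(rng, int(rng.integers(30, 90)))
        right = _random_dna(rng, int(rng.integers(30, 90)))
        contig = left + "TAA" + cds + "TAA" + right
        start = len(left) + 3
        end = start + len(cds)
        frame = start % 3 + 1
        if rng.random() < noise.revcomp_prob:
            L = len(contig)
            contig = _revcomp(contig)
            frame = -(start % 3 + 1)  # offset of the ORF when re-reading the reverse strand
            start, end = L - end, L - start
        contigs.append((cid, contig))
        embeddings.append(Embedding(cid, frame, start, end, pid, n_run_at, n_codons))
    return contigs, embeddings


def write_embeddings_tsv(embeddings: Iterable[Embedding], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tframe\tstart\tend\tprotein_id\n")
        for e in embeddings:
            fh.write(f"{e.contig}\t{e.frame:+d}\t{e.start}\t{e.end}\t{e.protein_id}\n")


# -- annotation & PPI fixtures --------------------------------------------

_DOMAIN_ACCESSIONS = {
    "Homeobox": "PF00046.29", "zf-C2H2": "PF00096.26", "HLH": "PF00010.29",
    "bZIP_2": "PF07716.15", "Pkinase": "PF00069.25", "WD40": "PF00400.32",
    "EGF": "PF00008.27",
}


@dataclass
class AnnotationPpiParams:
    """Shape of the domain-annotation and PPI fixtures.

    Fractions apply to families (one representative protein per family).
    ``within_class_odds`` multiplies the sampling weight of same-age-class
    edges; 1.0 means random mixing.  Scores sit on the STRING 0-1000 scale.
    """

    tf_fraction: float = 0.2
    tf_domains: tuple[str, ...] = ("Homeobox", "HLH", "bZIP_2")
    polyzf_fraction: float = 0.05
    zf_copy_number: int = 6
    other_domains: tuple[str, ...] = ("Pkinase", "WD40", "EGF")
    annotated_fraction: float = 0.9
    fail_fraction: float = 0.1  # rows emitted above the E-value cutoff
    e_cutoff: float = 5e-5
    n_edges: int = 400
    within_class_odds: float = 3.0
    below_score_fraction: float = 0.1
    focal_clade: str = "Bilateria"


@dataclass
class AnnotationPpiFixture:
    domain_rows: list[tuple]
    ppi_rows: list[tuple[str, str, int]]
    node_classes: dict[str, str]
    tf_families: set[str]
    polyzf_families: set[str]
    n_domain_rows_passing: int
    n_ppi_edges_passing: int

    def write_domain_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# protein\taln_start\taln_end\tenv_start\tenv_end\t"
                     "acc\tname\ttype\thmm_start\thmm_end\thmm_len\tbit\te_value\n")
            for row in self.domain_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

    def write_ppi_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for a, b, s in self.ppi_rows:
                fh.write(f"{a}\t{b}\t{s}\n")

    def write_node_class_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein\tclass\n")
            for p in sorted(self.node_classes):
                fh.write(f"{p}\t{self.node_classes[p]}\n")


def generate_annotation_and_ppi_fixtures(
    truth: GroundTruth,
    tree: SpeciesTree,
    params: AnnotationPpiParams | None = None,
    seed: int = 0,
) -> AnnotationPpiFixture:
    """Domain table (PfamScan column layout) and PPI edge list over family
    representatives, with known TF / poly-ZF membership and age classes."""
    if not truth.families:
        raise ValueError("ground truth is empty")
    params = params or AnnotationPpiParams()
    rng = substream(seed, "annotation-ppi")

    fam_ids = sorted(truth.families)
    reps = {f: min(truth.families[f].members) for f in fam_ids if truth.families[f].members}
    fam_ids = sorted(reps)

    focal_node = tree.clade_labels[params.focal_clade]
    focal_species = tree.species_below(focal_node)
    node_classes = {}
    for f in fam_ids:
        birth = truth.families[f].birth_node
        birth_node = tree.clade_labels.get(birth, birth)
        inside = set(tree.species_below(birth_node)) <= focal_species if birth_node in tree.nodes else False
        node_classes[reps[f]] = "B" if inside else "M"

    n = len(fam_ids)
    perm = rng.permutation(n)
    n_tf = int(round(params.tf_fraction * n))
    n_zf = int(round(params.polyzf_fraction * n))
    tf_families = {fam_ids[i] for i in perm[:n_tf]}
    polyzf_families = {fam_ids[i] for i in perm[n_tf:n_tf + n_zf]}

    domain_rows: list[tuple] = []
    n_passing = 0

    def add_row(protein: str, domain: str, passing: bool) -> None:
        nonlocal n_passing
        start = int(rng.integers(1, 40))
        length = int(rng.integers(30, 80))
        e = 10.0 ** float(rng.uniform(-30, -8)) if passing else 10.0 ** float(rng.uniform(-4, -1))
        if passing:
            n_passing += 1
        bit = float(np.round(rng.uniform(20, 200), 1))
        acc = _DOMAIN_ACCESSIONS.get(domain, "PF99999.1")
        domain_rows.append((protein, start, start + length, start, start + length + 2,
                            acc, domain, "Domain", 1, length, length,
                            bit, f"{e:.3g}"))

    for f in fam_ids:
        protein = reps[f]
        if f in tf_families:
            dom = params.tf_domains[int(rng.integers(len(params.tf_domains)))]
            add_row(protein, dom, passing=True)
        elif f in polyzf_families:
            for _ in range(params.zf_copy_number):
                add_row(protein, "zf-C2H2", passing=True)
        elif rng.random() < params.annotated_fraction:
            dom = params.other_domains[int(rng.integers(len(params.other_domains)))]
            add_row(protein, dom, passing=True)
        if rng.random() < params.fail_fraction:
            add_row(protein, "WD40", passing=False)

    # PPI edges over representatives, same-class edges upweighted
    rep_list = [reps[f] for f in fam_ids]
    pairs = [(rep_list[i], rep_list[j]) for i in range(n) for j in range(i + 1, n)]
    w = np.array([
        params.within_class_odds if node_classes[a] == node_classes[b] else 1.0
        for a, b in pairs
    ])
    n_edges = min(params.n_edges, len(pairs))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False, p=w / w.sum())
    ppi_rows: list[tuple[str, str, int]] = []
    n_pass_edges = 0
    for idx in sorted(chosen):
        a, b = pairs[idx]
        if rng.random() < params.below_score_fraction:
            score = int(rng.integers(100, 400))
        else:
            score = int(rng.integers(400, 1000))
            n_pass_edges += 1
        ppi_rows.append((a, b, score))

    return AnnotationPpiFixture(
        domain_rows=domain_rows,
        ppi_rows=ppi_rows,
        node_classes=node_classes,
        tf_families=tf_families,
        polyzf_families=polyzf_families,
        n_domain_rows_passing=n_passing,
        n_ppi_edges_passing=n_pass_edges,
    )
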