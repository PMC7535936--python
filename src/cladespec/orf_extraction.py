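"""Genomic/transcriptomic preprocessing.

Six-frame ORF extraction (stop-to-stop stretches, sequence ends counting as
boundaries), splitting of long 'X' runs produced by sequencing gaps and
masked repeats, a similarity prefilter against a reference protein set, and
greedy redundancy reduction at an identity threshold.  Coordinates are
0-based half-open on the forward strand throughout; translation uses the
standard genetic code with 'N'-containing codons rendered as 'X'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# -- records and configuration ---------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One protein/ORF with a provenance-encoding id ``<taxid>|<source>|<uid>``."""

    id: str
    residues: str

    @property
    def taxon(self) -> int:
        return int(self.id.split("|", 1)[0])

    @property
    def source(self) -> str:
        return self.id.split("|")[1]


@dataclass(frozen=True)
class OrfRecord:
    """A stop-free translated stretch; coordinates on the forward strand."""

    contig: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    start: int
    end: int
    residues: str

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if (self.end - self.start) // 3 != len(self.residues):
            raise ValueError("residue count does not match coordinates")


@dataclass
class PreprocessConfig:
    min_orf_len: int = 25       # residues; published minimum ORF length
    x_run_len: int = 9          # 'X' run length that triggers splitting
    min_flank: int = 35         # valid residues a split flank must keep
    e_max: float = 10.0         # similarity-prefilter expectation cutoff
    identity_threshold: float = 0.90
    top_k_tx: int = 3           # longest ORFs kept per transcriptome contig


# -- translation -----------------------------------------------------------

_CODON_TABLE = {}
for _aa, _codons in {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "*": ["TAA", "TAG", "TGA"],
}.items():
    for _c in _codons:
        _CODON_TABLE[_c] = _aa

_COMP = str.maketrans("ACGTN", "TGCAN")


def translate_frame(dna: str, offset: int) -> str:
    """Translate one frame; codons containing 'N' become 'X', stops '*'."""
    out = []
    for i in range(offset, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMP)[::-1]


# -- six-frame ORF extraction ----------------------------------------------


def six_frame_orfs(
    contig: str, config: PreprocessConfig | None = None, contig_id: str = "contig"
) -> list[OrfRecord]:
    """Maximal stop-free stretches of >= min_orf_len residues in all 6 frames.

    Sequence ends count as stop boundaries.  Reverse-frame coordinates are
    mapped back to the forward strand.
    """
    config = config or PreprocessConfig()
    contig = contig.upper()
    if not contig:
        return []
    L = len(contig)
    orfs: list[OrfRecord] = []
    for strand, seq in ((1, contig), (-1, reverse_complement(contig))):
        for offset in range(3):
            protein = translate_frame(seq, offset)
            frame = strand * (offset + 1)
            pos = 0
            for stretch in protein.split("*"):
                if len(stretch) >= config.min_orf_len:
                    s = offset + 3 * pos
                    e = offset + 3 * (pos + len(stretch))
                    if strand == 1:
                        start, end = s, e
                    else:
                        start, end = L - e, L - s
                    orfs.append(OrfRecord(contig_id, frame, start, end, stretch))
                pos += len(stretch) + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


# -- X-run splitting -------------------------------------------------------


def split_x_runs(
    record: SequenceRecord, config: PreprocessConfig | None = None
) -> list[SequenceRecord]:
    """Split on runs of >= x_run_len 'X'; keep flanks with >= min_flank valid residues.

    Records without a qualifying run pass through unchanged.  Split products
    are re-identified with a ``.<k>`` suffix on the uid.
    """
    config = config or PreprocessConfig()
    pattern = re.compile("X{%d,}" % config.x_run_len)
    if not pattern.search(record.residues):
        return [record]
    out = []
    k = 0
    for flank in pattern.split(record.residues):
        n_valid = sum(1 for a in flank if a != "X")
        if n_valid >= config.min_flank:
            k += 1
            out.append(SequenceRecord(id=f"{record.id}.{k}", residues=flank))
    return out


# -- transcriptome top-k ---------------------------------------------------


def transcriptome_top_orfs(
    orfs: Iterable[OrfRecord], config: PreprocessConfig | None = None
) -> list[OrfRecord]:
    """Keep the ``top_k_tx`` longest ORFs per contig.

    Ties broken by earlier start, then lexicographic frame label.
    """
    config = config or PreprocessConfig()
    by_contig: dict[str, list[OrfRecord]] = {}
    for o in orfs:
        by_contig.setdefault(o.contig, []).append(o)
    kept: list[OrfRecord] = []
    for contig in sorted(by_contig):
        ranked = sorted(
            by_contig[contig],
            key=lambda o: (-len(o.residues), o.start, f"{o.frame:+d}"),
        )
        kept.extend(ranked[: config.top_k_tx])
    return kept


# -- similarity prefilter --------------------------------------------------


def similarity_prefilter(
    orfs: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    config: PreprocessConfig | None = None,
    aligner_config=None,
) -> list[SequenceRecord]:
    """Keep ORFs whose best local-alignment E-value vs the reference is < e_max."""
    from .similarity_clustering import AlignerConfig, best_evalue

    config = config or PreprocessConfig()
    if not reference:
        raise ValueError("reference set must be non-empty")
    aligner_config = aligner_config or AlignerConfig(
        db_size=sum(len(r.residues) for r in reference)
    )
    kept = []
    for orf in orfs:
        e = best_evalue(orf, reference, aligner_config)
        if e < config.e_max:
            kept.append(orf)
    return kept


# -- redundancy reduction --------------------------------------------------

_global_aligner = None


def _get_global_aligner():
    global _global_aligner
    if _global_aligner is None:
        from Bio.Align import PairwiseAligner, substitution_matrices

        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12.0
        a.extend_gap_score = -1.0
        _global_aligner = a
    return _global_aligner


def global_identity(a: str, b: str) -> float:
    """Identity = matches in the optimal global alignment / shorter length."""
    if not a or not b:
        return 0.0
    aligner = _get_global_aligner()
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def _kmers(s: str, k: int = 4) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def reduce_redundancy(
    records: Sequence[SequenceRecord], config: PreprocessConfig | None = None
) -> list[SequenceRecord]:
    """Greedy clustering by descending length at the identity threshold.

    Each record joins the first existing representative it matches at
    >= identity_threshold (global-alignment matches over the shorter
    length); otherwise it founds a new representative.  A shared-k-mer
    prescreen skips representatives that cannot plausibly reach the
    threshold.  Idempotent on its own output.
    """
    config = config or PreprocessConfig()
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    reps: list[SequenceRecord] = []
    rep_kmers: list[set[str]] = []
    for rec in ordered:
        km = _kmers(rec.residues)
        placed = False
        for rep, rkm in zip(reps, rep_kmers):
            # at >= 90% identity a large share of 4-mers must be shared
            if km and rkm and len(km & rkm) < 0.2 * min(len(km), len(rkm)):
                continue
            if global_identity(rec.residues, rep.residues) >= config.identity_threshold:
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_kmers.append(km)
    return reps


# -- percent-reduction bookkeeping -----------------------------------------


def percent_reduction(before: int, after: int, decimals: int = 1) -> float:
    """Percent count reduction, truncated (not rounded) to ``decimals``."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    scale = 10 ** decimals
    return ((before - after) * 100 * scale // before) / scale


# -- FASTA I/O -------------------------------------------------------------


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=r.id, residues=str(r.seq)) for r in SeqIO.parse(path, "fasta")
    ]


def write_fasta(records: Iterable, path) -> None:
    """60-column-wrapped FASTA; accepts SequenceRecords or (id, seq) pairs."""
    bio = []
    for r in records:
        if isinstance(r, tuple):
            rid, seq = r
        else:
            rid, seq = r.id, r.residues
        bio.append(_BioSeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(bio, path, "fasta")


def orf_to_record(orf: OrfRecord, taxid: int, uid: str, source: str = "orf") -> SequenceRecord:
    return SequenceRecord(id=f"{taxid}|{source}|{uid}", residues=orf.residues)


# -- pipelined preprocessing ----------------------------------------------


def preprocess_genomic(
    contigs: Sequence[tuple[str, str]],
    taxid: int,
    reference: Sequence[SequenceRecord] | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """translate -> split X-runs -> flank/length filter -> prefilter -> dedup.

    Returns kept records and a (record id, reason) manifest for discards.
    """
    config = config or PreprocessConfig()
    manifest: list[tuple[str, str]] = []
    records: list[SequenceRecord] = []
    uid = 0
    for cid, dna in contigs:
        for orf in six_frame_orfs(dna, config, contig_id=cid):
            uid += 1
            rec = orf_to_record(orf, taxid, f"{cid}.{uid}")
            pieces = split_x_runs(rec, config)
            if not pieces:
                manifest.append((rec.id, "x_split_flanks_too_short"))
            records.extend(pieces)
    if reference is not None:
        kept = similarity_prefilter(records, reference, config)
        kept_ids = {r.id for r in kept}
        manifest.extend((r.id, "prefilter_e_value") for r in records if r.id not in kept_ids)
        records = kept
    reps = reduce_redundancy(records, config)
    rep_ids = {r.id for r in reps}
    manifest.extend((r.id, "redundant") for r in records if r.id not in rep_ids)
    return reps, manifest
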