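"""Small-RNA tail calling: retention, exact prefix mapping, tail extraction
and species classification.

The caller reproduces the behaviour of soft-clip-based tail identification:
the longest read prefix that matches the genome exactly (either strand) is
the templated body, and the remaining 3' suffix is the nontemplated tail.
Because matching is maximal, a tail whose first base happens to equal the
genomic continuation is absorbed into the body — reported tails are
maximally short. This is a known bias shared with aligner soft-clipping;
the simulator sidesteps it by construction so truth comparisons are exact.

Reads whose longest prefix matches more than one genomic location are
discarded as multimappers rather than assigned at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from ._seq import dna_to_rna, revcomp
from .reference import Feature, ReferenceSet

logger = logging.getLogger(__name__)

MIN_BODY = 15
RETAIN_MIN, RETAIN_MAX = 15, 26
QUALITY_CUTOFF = 20
MIN_CDS_OVERLAP = 0.9

#: species precedence when a body satisfies several class definitions
_CLASS_PRECEDENCE = ("miRNA", "piRNA", "siRNA")


# ---------------------------------------------------------------- retention


def retain_read(
    seq: str,
    qualities,
    min_len: int = RETAIN_MIN,
    max_len: int = RETAIN_MAX,
    quality_cutoff: int = QUALITY_CUTOFF,
) -> str | None:
    """Apply the read-retention rule; returns the trimmed sequence or None.

    3' bases with Phred quality below ``quality_cutoff`` are trimmed from
    the end, then the read is kept iff its trimmed length lies in
    [min_len, max_len].
    """
    if len(seq) != len(qualities):
        raise ValueError("sequence and quality lengths differ")
    end = len(seq)
    while end > 0 and qualities[end - 1] < quality_cutoff:
        end -= 1
    trimmed = seq[:end]
    if min_len <= len(trimmed) <= max_len:
        return trimmed
    return None


def parse_fastq(path):
    """Yield (read_id, seq, qualities list) from FASTQ(.gz)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:].split()[0], seq, [ord(c) - 33 for c in qual]


# ------------------------------------------------------------------ mapping


class GenomeIndex:
    """Exact-match seed index over both strands of a reference genome.

    Seeds every ``seed_len``-mer of the forward strand; minus-strand hits
    are found by looking up the reverse complement of the read prefix.
    """

    def __init__(self, ref: ReferenceSet, seed_len: int = MIN_BODY):
        self.ref = ref
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in ref.chromosomes.items():
            for pos in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[pos : pos + seed_len], []).append(
                    (chrom, pos)
                )

    def candidates(self, prefix: str) -> list[tuple[str, int, str]]:
        fwd = [(c, p, "+") for c, p in self._index.get(prefix, ())]
        rev = [(c, p, "-") for c, p in self._index.get(revcomp(prefix), ())]
        return fwd + rev


@dataclass(frozen=True)
class BodyAlignment:
    """Templated prefix of a read: where it maps and how far it extends."""

    read_id: str
    read_seq: str
    chrom: str
    start: int  # genomic interval of the body, 0-based half-open
    end: int
    strand: str
    body_len: int


def _extend(read: str, chrom_seq: str, pos: int, strand: str, seed_len: int) -> int:
    """Greedy extension of a seed hit: length of the matching read prefix."""
    k = seed_len
    n = len(read)
    if strand == "+":
        # read[i] == chrom_seq[pos + i]
        limit = len(chrom_seq) - pos
        while k < n and k < limit and read[k] == chrom_seq[pos + k]:
            k += 1
    else:
        # read[i] == complement(chrom_seq[pos + seed_len - 1 - i])
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        while k < n and pos + seed_len - 1 - k >= 0 and (
            comp.get(read[k]) == chrom_seq[pos + seed_len - 1 - k]
        ):
            k += 1
    return k


def map_prefix(
    read_id: str,
    read_seq: str,
    index: GenomeIndex,
    min_body: int = MIN_BODY,
) -> BodyAlignment | None:
    """Map the longest exactly-matching read prefix to a unique location.

    Returns None for unmapped reads; multimappers (several locations tie
    for the longest prefix) are also dropped, with a debug log line.
    """
    if len(read_seq) < min_body:
        return None
    seed = read_seq[: index.seed_len]
    best_len = 0
    best: list[tuple[str, int, str]] = []
    for chrom, pos, strand in index.candidates(seed):
        k = _extend(read_seq, index.ref.chromosomes[chrom], pos, strand, index.seed_len)
        if k > best_len:
            best_len, best = k, [(chrom, pos, strand)]
        elif k == best_len:
            best.append((chrom, pos, strand))
    if best_len < min_body or not best:
        return None
    if len(best) > 1:
        logger.debug("read %s discarded as multimapper (%d hits)", read_id, len(best))
        return None
    chrom, pos, strand = best[0]
    if strand == "+":
        start, end = pos, pos + best_len
    else:
        # read 5' end sits at genomic position pos + seed_len - 1, extending left
        end = pos + index.seed_len
        start = end - best_len
    return BodyAlignment(read_id, read_seq, chrom, start, end, strand, best_len)


# ----------------------------------------------------------------- calling


def classify_tail_type(tail_seq: str) -> str:
    """Collapse a tail to {A,C,G,U,other,none}: homopolymers by base,
    mixed-nucleotide tails as 'other', empty as 'none'."""
    if tail_seq == "":
        return "none"
    bases = set(tail_seq)
    if not bases <= set("ACGU"):
        raise ValueError(f"invalid tail sequence {tail_seq!r}")
    if len(bases) == 1:
        return tail_seq[0]
    return "other"


def call_tail(alignment: BodyAlignment) -> tuple[str, str, int, str]:
    """Extract (tail_seq, tail_type, tail_len, last_templated_nt) in RNA
    alphabet from a mapped body; the last templated base is reported in
    read orientation."""
    tail_seq = dna_to_rna(alignment.read_seq[alignment.body_len :])
    last_nt = dna_to_rna(alignment.read_seq[alignment.body_len - 1])
    return tail_seq, classify_tail_type(tail_seq), len(tail_seq), last_nt


class FeatureLookup:
    """Interval lookup of annotated features per chromosome."""

    def __init__(self, ref: ReferenceSet):
        self._trees: dict[str, IntervalTree] = {}
        for f in ref.features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def classify_species(
    alignment: BodyAlignment,
    lookup: FeatureLookup,
    min_overlap: float = MIN_CDS_OVERLAP,
) -> tuple[str, str | None]:
    """Assign a mapped body to an sRNA species.

    miRNA/piRNA: the body lies sense within the locus. siRNA: the body
    maps antisense to a gene and >= ``min_overlap`` of it is covered by
    that gene's CDS exons; the species is the gene. Precedence when
    several definitions apply: miRNA > piRNA > siRNA.
    """
    hits = lookup.overlapping(alignment.chrom, alignment.start, alignment.end)
    assignments: dict[str, list[str]] = {c: [] for c in _CLASS_PRECEDENCE}
    for f in hits:
        if f.biotype in ("miRNA", "piRNA"):
            if (
                f.strand == alignment.strand
                and f.start <= alignment.start
                and alignment.end <= f.end
            ):
                assignments[f.biotype].append(f.feature_id)
        elif f.biotype == "protein_coding" and f.strand != alignment.strand:
            covered = sum(
                max(0, min(alignment.end, e) - max(alignment.start, s))
                for s, e in f.exons
            )
            if covered >= min_overlap * (alignment.end - alignment.start):
                assignments["siRNA"].append(f.feature_id)
    for cls in _CLASS_PRECEDENCE:
        ids = assignments[cls]
        if ids:
            if len(ids) > 1:
                logger.debug(
                    "read %s overlaps several %s features %s; keeping %s",
                    alignment.read_id, cls, ids, sorted(ids)[0],
                )
            return cls, sorted(ids)[0]
    return "unassigned", None


# ----------------------------------------------------------------- pipeline

_CALL_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand", "species_class", "species_id",
    "tail_seq", "tail_type", "tail_len", "last_templated_nt", "replicate",
]


def _alignment_to_row(
    alignment: BodyAlignment, lookup: FeatureLookup, replicate: str,
    min_overlap: float,
) -> tuple:
    tail_seq, tail_type, tail_len, last_nt = call_tail(alignment)
    cls, species_id = classify_species(alignment, lookup, min_overlap)
    return (
        alignment.read_id, alignment.chrom, alignment.start, alignment.end,
        alignment.strand, cls, species_id, tail_seq, tail_type, tail_len,
        last_nt, replicate,
    )


def call_tails(
    reads,
    ref: ReferenceSet,
    replicate: str = "rep1",
    min_body: int = MIN_BODY,
    min_overlap: float = MIN_CDS_OVERLAP,
    index: GenomeIndex | None = None,
    lookup: FeatureLookup | None = None,
    apply_retention: bool = True,
) -> pd.DataFrame:
    """Run retention, mapping, tail calling and classification.

    ``reads`` is an iterable of (read_id, seq) or (read_id, seq, qualities)
    tuples; qualities default to uniformly high when absent. Returns the
    per-read TailCall table; unmapped reads and multimappers are excluded.
    """
    index = index or GenomeIndex(ref, seed_len=min_body)
    lookup = lookup or FeatureLookup(ref)
    rows = []
    for rec in reads:
        if len(rec) == 2:
            rid, seq = rec
            quals = [40] * len(seq)
        else:
            rid, seq, quals = rec
        if apply_retention:
            retained = retain_read(seq, quals)
            if retained is None:
                continue
            seq = retained
        aln = map_prefix(rid, seq, index, min_body=min_body)
        if aln is None:
            continue
        rows.append(_alignment_to_row(aln, lookup, replicate, min_overlap))
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def call_tails_fastq(path, ref: ReferenceSet, replicate: str, **kwargs) -> pd.DataFrame:
    return call_tails(parse_fastq(path), ref, replicate, **kwargs)


def call_tails_sam(
    path,
    ref: ReferenceSet,
    replicate: str = "rep1",
    min_body: int = MIN_BODY,
    min_overlap: float = MIN_CDS_OVERLAP,
) -> pd.DataFrame:
    """Ingest an existing alignment (SAM/BAM): soft-clipped 3' suffixes are
    tail candidates, then the same greedy absorption of templated-looking
    bases is applied so calls match the exact-match path.

    Secondary/supplementary alignments are skipped; reads with a reported
    mapping are trusted (no retention is re-applied).
    """
    import pysam

    lookup = FeatureLookup(ref)
    rows = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.get_forward_sequence()
            if seq is None:
                continue
            seq = seq.upper()
            cigar = rec.cigartuples or []
            # soft clip at the read 3' end, in read orientation
            clip = 0
            if rec.is_reverse:
                if cigar and cigar[0][0] == 4:
                    clip = cigar[0][1]
            else:
                if cigar and cigar[-1][0] == 4:
                    clip = cigar[-1][1]
            chrom = rec.reference_name
            chrom_seq = ref.chromosomes.get(chrom)
            if chrom_seq is None:
                continue
            start, end = rec.reference_start, rec.reference_end
            strand = "-" if rec.is_reverse else "+"
            body_len = len(seq) - clip
            # greedy absorption: extend body while the next read base is
            # templated by the genomic continuation
            while clip > 0:
                if strand == "+":
                    if end < len(chrom_seq) and seq[body_len] == chrom_seq[end]:
                        end += 1
                    else:
                        break
                else:
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    if start > 0 and comp.get(seq[body_len]) == chrom_seq[start - 1]:
                        start -= 1
                    else:
                        break
                body_len += 1
                clip -= 1
            aln = BodyAlignment(rec.query_name, seq, chrom, start, end, strand, body_len)
            rows.append(_alignment_to_row(aln, lookup, replicate, min_overlap))
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)
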