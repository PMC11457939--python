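"""Toy reference genomes with stranded, biotyped annotation.

A :class:`ReferenceSet` bundles chromosome sequences with non-overlapping
gene features of three biotypes (protein_coding, miRNA, piRNA), which is
all the downstream tail-calling machinery needs: siRNA species are defined
by antisense overlap with CDS exons, miRNA/piRNA species by sense mapping
within their loci.

Coordinates are 0-based half-open internally; the GTF writer emits 1-based
inclusive coordinates and the BED writer 0-based half-open ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

BIOTYPES = ("protein_coding", "miRNA", "piRNA")


@dataclass(frozen=True)
class Feature:
    """One annotated gene/locus on the toy genome."""

    feature_id: str
    biotype: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    exons: tuple[tuple[int, int], ...] = ()  # CDS exons, 0-based half-open

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("feature interval must be non-empty and non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceSet:
    """Chromosome sequences plus stranded annotation intervals."""

    chromosomes: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            clen = len(self.chromosomes[f.chrom])
            if f.end > clen:
                raise ValueError(f"{f.feature_id} extends past {f.chrom} ({clen} nt)")
            for s, e in f.exons:
                if not (f.start <= s < e <= f.end):
                    raise ValueError(f"exon of {f.feature_id} outside feature bounds")

    def features_by_biotype(self, biotype: str) -> list[Feature]:
        return [f for f in self.features if f.biotype == biotype]

    def transcript(self, feature: Feature) -> str:
        """mRNA sequence of a protein-coding gene: spliced CDS exons, sense strand."""
        if feature.biotype != "protein_coding":
            raise ValueError("transcripts are derived from protein_coding features")
        chrom = self.chromosomes[feature.chrom]
        spliced = "".join(chrom[s:e] for s, e in sorted(feature.exons))
        return spliced if feature.strand == "+" else revcomp(spliced)

    def transcriptome(self) -> dict[str, str]:
        return {
            f.feature_id: self.transcript(f)
            for f in self.features_by_biotype("protein_coding")
        }

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, path, "fasta")

    def transcriptome_to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=tid, description="")
            for tid, seq in self.transcriptome().items()
        ]
        SeqIO.write(records, path, "fasta")

    def to_gtf(self, path) -> None:
        """Write gene + (for coding genes) CDS lines, 1-based inclusive."""
        with open(path, "w") as fh:
            for f in self.features:
                attrs = f'gene_id "{f.feature_id}"; gene_biotype "{f.biotype}";'
                fh.write(
                    f"{f.chrom}\tutailor\tgene\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t{attrs}\n"
                )
                for s, e in sorted(f.exons):
                    fh.write(
                        f"{f.chrom}\tutailor\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{f.strand}\t.\t{attrs}\n"
                    )

    def to_bed(self, path) -> None:
        """BED6 mirror of the gene intervals (0-based half-open)."""
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
                )


def load_reference(fasta_path, gtf_path) -> ReferenceSet:
    """Read a genome FASTA plus a gene/CDS GTF back into a ReferenceSet.

    Accepts the GTF dialect written by :meth:`ReferenceSet.to_gtf`:
    ``gene`` lines carry ``gene_id`` and ``gene_biotype`` attributes and
    ``CDS`` lines attach exons to their gene.
    """
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    genes: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, kind, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(
                (kv.split(" ", 1)[0], kv.split(" ", 1)[1].strip('"'))
                for kv in (a.strip() for a in attrs.strip().strip(";").split(";"))
                if kv
            )
            gid = fields["gene_id"]
            entry = genes.setdefault(
                gid, {"chrom": chrom, "strand": strand, "exons": []}
            )
            if kind == "gene":
                entry.update(
                    start=int(start) - 1,
                    end=int(end),
                    biotype=fields.get("gene_biotype", "protein_coding"),
                )
            elif kind == "CDS":
                entry["exons"].append((int(start) - 1, int(end)))
    features = [
        Feature(
            feature_id=gid,
            biotype=g["biotype"],
            chrom=g["chrom"],
            start=g["start"],
            end=g["end"],
            strand=g["strand"],
            exons=tuple(sorted(g["exons"])),
        )
        for gid, g in genes.items()
    ]
    return ReferenceSet(chromosomes=chroms, features=features)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_reference(
    n_genes: int,
    n_mirna: int,
    n_pirna: int,
    chrom_len: int = 200_000,
    seed: int = 0,
    *,
    gene_len_range: tuple[int, int] = (150, 400),
    small_locus_len_range: tuple[int, int] = (26, 40),
    margin: int = 50,
    max_tries: int = 10_000,
) -> ReferenceSet:
    """Generate a single random chromosome carrying disjoint features.

    Protein-coding genes get one or two CDS exons; miRNA/piRNA loci are
    short single intervals long enough to template 18-24 nt reads.
    Feature placement rejects any overlap with previously placed features
    and keeps a margin from the chromosome ends so that every read body
    has a templated genomic continuation on both sides.

    Deterministic for a fixed seed.
    """
    if min(n_genes, n_mirna, n_pirna) < 1:
        raise ValueError("counts >= 1 required for n_genes, n_mirna and n_pirna")
    chrom_len = int(chrom_len)
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    seq = _random_seq(rng, chrom_len)

    placed: list[tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(max_tries):
            start = int(rng.integers(margin, chrom_len - margin - length))
            if all(start >= e or start + length <= s for s, e in placed):
                placed.append((start, start + length))
                return start
        raise RuntimeError(
            "could not place all features without overlap: "
            "chrom_len too small for the requested feature counts"
        )

    features: list[Feature] = []
    for i in range(n_genes):
        glen = int(rng.integers(*gene_len_range))
        start = place(glen)
        strand = "+" if rng.random() < 0.5 else "-"
        if glen >= 220 and rng.random() < 0.5:
            # two CDS exons separated by a short intron
            e1 = int(rng.integers(80, glen - 120))
            intron = int(rng.integers(20, 40))
            exons = ((start, start + e1), (start + e1 + intron, start + glen))
        else:
            exons = ((start, start + glen),)
        features.append(
            Feature(f"gene{i + 1:04d}", "protein_coding", chrom, start, start + glen,
                    strand, exons)
        )
    for biotype, prefix, n in (("miRNA", "mir", n_mirna), ("piRNA", "pir", n_pirna)):
        for i in range(n):
            llen = int(rng.integers(*small_locus_len_range))
            start = place(llen)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(f"{prefix}{i + 1:04d}", biotype, chrom, start, start + llen,
                        strand)
            )
    # ensure both strands represented
    if len({f.strand for f in features}) < 2:
        f0 = features[0]
        features[0] = Feature(
            f0.feature_id, f0.biotype, f0.chrom, f0.start, f0.end,
            "+" if f0.strand == "-" else "-", f0.exons,
        )
    return ReferenceSet(chromosomes={chrom: seq}, features=features)
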