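"""Read simulation with ground-truth nontemplated tails.

Small-RNA reads are drawn from annotated loci — siRNAs antisense to CDS
exons, miRNAs and piRNAs sense within their loci — and mRNA-end reads
from the 3' ends of spliced transcripts. Tails are appended according to
a :class:`~utailor.profiles.SimProfile` and every emitted read gets one
truth record, so the tail caller can be validated base-for-base.

To keep the templated/nontemplated boundary unambiguous, a read body is
re-positioned (bounded retries) whenever the genomic base that would
continue the body equals the first tail base.  Resampling the *position*
rather than the tail keeps the configured tail-type and length mixtures
exact, which is what the recovery analyses measure.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import complement_base, dna_to_rna, rna_to_dna, revcomp
from .profiles import SimProfile, SRNA_CLASSES
from .reference import Feature, ReferenceSet

#: Phred 40 for every base — comfortably above the 3' Q20 retention cutoff.
_QUAL_CHAR = "I"

_BODY_LEN_RANGE = (18, 24)  # inclusive; keeps body+tail near the 15-26 window
_MRNA_BODY_RANGE = (40, 80)
_MAX_PLACEMENT_TRIES = 200


@dataclass
class SimulatedReads:
    """Per-replicate reads plus the truth table."""

    reads: dict[str, list[tuple[str, str]]]  # replicate -> [(read_id, seq)]
    truth: pd.DataFrame  # read_id, species_id, class, true_tail_seq, replicate

    def write_fastq(self, outdir, prefix: str) -> list[str]:
        paths = []
        import os

        for rep, recs in self.reads.items():
            path = os.path.join(outdir, f"{prefix}_{rep}.fq.gz")
            with gzip.open(path, "wt") as fh:
                for rid, seq in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")
            paths.append(path)
        return paths

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _choice(rng: np.random.Generator, mix: dict) -> object:
    keys = list(mix)
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _draw_tail(rng: np.random.Generator, params) -> str:
    """Tail sequence in DNA alphabet ('' if untailed)."""
    if rng.random() >= params.p_tail:
        return ""
    ttype = _choice(rng, params.tail_type_mix)
    if ttype == "other":
        # 2-nt heterogeneous tail, e.g. UG
        b1, b2 = rng.choice(4, size=2, replace=False)
        return "ACGT"[b1] + "ACGT"[b2]
    length = int(_choice(rng, params.u_len_mix))
    return rna_to_dna(ttype) * length


def _species_weights(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-uniform relative abundances over two decades."""
    return 10 ** rng.uniform(0.0, 2.0, size=n)


def _body_window(
    rng: np.random.Generator,
    ref: ReferenceSet,
    feature: Feature,
    srna_class: str,
    body_len: int,
) -> tuple[int, str]:
    """Pick a genomic window [s, s+body_len) for a read body.

    Returns (start, read_strand). siRNA reads map antisense to the gene,
    miRNA/piRNA reads map sense within the locus.
    """
    if srna_class == "siRNA":
        exons = [e for e in feature.exons if e[1] - e[0] >= body_len]
        if not exons:
            raise ValueError(f"no CDS exon of {feature.feature_id} fits a read body")
        s0, e0 = exons[int(rng.integers(len(exons)))]
        strand = "-" if feature.strand == "+" else "+"
    else:
        s0, e0 = feature.start, feature.end
        if e0 - s0 < body_len:
            raise ValueError(f"locus {feature.feature_id} shorter than read body")
        strand = feature.strand
    start = int(rng.integers(s0, e0 - body_len + 1))
    return start, strand


def _read_from_window(chrom_seq: str, start: int, body_len: int, strand: str) -> str:
    window = chrom_seq[start : start + body_len]
    return window if strand == "+" else revcomp(window)


def _continuation(chrom_seq: str, start: int, body_len: int, strand: str) -> str:
    """Genomic base that would extend the body in read orientation."""
    if strand == "+":
        pos = start + body_len
        return chrom_seq[pos] if pos < len(chrom_seq) else "N"
    return complement_base(chrom_seq[start - 1]) if start > 0 else "N"


def simulate_srna_reads(ref: ReferenceSet, profile: SimProfile) -> SimulatedReads:
    """Simulate small-RNA reads for every replicate of a genotype.

    Species are loci sampled per class with log-uniform abundances shared
    across replicates; per replicate, ``reads_per_replicate`` reads are
    allocated multinomially across species.
    """
    rng = np.random.default_rng(profile.seed)
    by_class = {
        "siRNA": [
            f
            for f in ref.features_by_biotype("protein_coding")
            if any(e - s >= _BODY_LEN_RANGE[0] for s, e in f.exons)
        ],
        "miRNA": ref.features_by_biotype("miRNA"),
        "piRNA": ref.features_by_biotype("piRNA"),
    }
    species: list[tuple[Feature, str]] = []
    for cls in SRNA_CLASSES:
        if cls not in profile.class_params:
            continue
        pool = by_class[cls]
        if not pool:
            raise ValueError(f"annotation has no loci for class {cls}")
        n = min(profile.n_species_per_class.get(cls, 0), len(pool))
        if n < 1:
            raise ValueError(f"n_species_per_class[{cls!r}] must be >= 1")
        idx = rng.choice(len(pool), size=n, replace=False)
        species.extend((pool[i], cls) for i in idx)

    weights = _species_weights(rng, len(species))
    weights = weights / weights.sum()

    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[tuple] = []
    for r in range(1, profile.n_replicates + 1):
        rep = f"rep{r}"
        counts = rng.multinomial(profile.reads_per_replicate, weights)
        recs: list[tuple[str, str]] = []
        serial = 0
        for (feature, cls), n_reads in zip(species, counts):
            chrom_seq = ref.chromosomes[feature.chrom]
            params = profile.class_params[cls]
            for _ in range(n_reads):
                serial += 1
                tail = _draw_tail(rng, params)
                # body+tail must stay inside the 15-26 nt retention window,
                # else long-tailed reads would be preferentially dropped and
                # the configured tail mixtures distorted
                hi = min(_BODY_LEN_RANGE[1], 26 - len(tail))
                for _try in range(_MAX_PLACEMENT_TRIES):
                    body_len = int(rng.integers(_BODY_LEN_RANGE[0], hi + 1))
                    start, strand = _body_window(rng, ref, feature, cls, body_len)
                    if not tail:
                        break
                    if _continuation(chrom_seq, start, body_len, strand) != tail[0]:
                        break
                else:
                    raise RuntimeError(
                        "could not place a read body with a nontemplated tail start"
                    )
                body = _read_from_window(chrom_seq, start, body_len, strand)
                rid = f"{profile.genotype_label}:{rep}:{serial:06d}"
                recs.append((rid, body + tail))
                truth_rows.append(
                    (rid, feature.feature_id, cls, dna_to_rna(tail), rep)
                )
        reads[rep] = recs
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "species_id", "class", "true_tail_seq", "replicate"],
    )
    return SimulatedReads(reads=reads, truth=truth)


def simulate_mrna_reads(ref: ReferenceSet, profile: SimProfile) -> SimulatedReads:
    """Simulate mRNA-end reads: a 3' transcript portion plus a tail.

    Tail classes follow ``profile.mrna_params``: strict A-run, strict
    U-run, A-run-then-U-run, or untailed. Reads always run to the
    transcript 3' end so the appended tail is nontemplated by construction.
    """
    if profile.mrna_params is None:
        raise ValueError("profile has no mrna_params")
    mp = profile.mrna_params
    rng = np.random.default_rng(profile.seed + 1)
    transcripts = ref.transcriptome()
    if not transcripts:
        raise ValueError("reference has no protein-coding transcripts")
    tids = sorted(transcripts)
    weights = _species_weights(rng, len(tids))
    weights = weights / weights.sum()
    class_mix = {
        "polyA": mp.frac_polyA,
        "polyU": mp.frac_polyU,
        "polyA_U": mp.frac_AU,
        "none": mp.frac_untailed,
    }

    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[tuple] = []
    for r in range(1, profile.n_replicates + 1):
        rep = f"rep{r}"
        counts = rng.multinomial(profile.reads_per_replicate, weights)
        recs: list[tuple[str, str]] = []
        serial = 0
        for tid, n_reads in zip(tids, counts):
            tseq = transcripts[tid]
            lo = min(_MRNA_BODY_RANGE[0], len(tseq))
            hi = min(_MRNA_BODY_RANGE[1], len(tseq))
            for _ in range(n_reads):
                serial += 1
                body_len = int(rng.integers(lo, hi + 1))
                body = tseq[-body_len:]
                cls = _choice(rng, class_mix)
                tail = ""
                if cls in ("polyA", "polyA_U"):
                    tail += "A" * int(_choice(rng, mp.a_len_dist))
                if cls in ("polyU", "polyA_U"):
                    tail += "T" * int(_choice(rng, mp.u_len_dist))
                rid = f"{profile.genotype_label}:mrna:{rep}:{serial:06d}"
                recs.append((rid, body + tail))
                truth_rows.append((rid, tid, "mRNA", dna_to_rna(tail), rep))
        reads[rep] = recs
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "species_id", "class", "true_tail_seq", "replicate"],
    )
    return SimulatedReads(reads=reads, truth=truth)
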