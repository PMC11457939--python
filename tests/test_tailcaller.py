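import numpy as np
import pandas as pd
import pytest

from utailor import ReferenceSet, call_tails, classify_tail_type, retain_read
from utailor._seq import revcomp
from utailor.reference import Feature
from utailor.tailcaller import (
    BodyAlignment,
    FeatureLookup,
    GenomeIndex,
    call_tail,
    call_tails_sam,
    classify_species,
    map_prefix,
)


# --------------------------------------------------------------- retention


@pytest.mark.parametrize(
    "length,quals,expected_len",
    [
        (22, [30] * 22, 22),           # in-window, high quality
        (14, [30] * 14, None),         # below window
        (27, [30] * 26 + [10], 26),    # 3' low-quality base trimmed into window
        (30, [30] * 30, None),         # above window, nothing to trim
        (20, [30] * 17 + [10] * 3, 17),  # multiple 3' bases trimmed
        (16, [10] * 16, None),         # everything trimmed away
    ],
)
def test_retention_rule(length, quals, expected_len):
    seq = "A" * length
    got = retain_read(seq, quals)
    if expected_len is None:
        assert got is None
    else:
        assert got == "A" * expected_len


# ----------------------------------------------------------------- mapping


@pytest.fixture(scope="module")
def toy_ref():
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
    # force a duplicated 40-mer for the multimapper test
    seq = seq[:2000] + seq[100:140] + seq[2040:]
    return ReferenceSet(chromosomes={"c1": seq}, features=[])


def test_identity_read_has_empty_tail(toy_ref):
    idx = GenomeIndex(toy_ref)
    read = toy_ref.chromosomes["c1"][300:322]
    aln = map_prefix("r", read, idx)
    assert aln is not None and (aln.start, aln.end, aln.strand) == (300, 322, "+")
    tail_seq, tail_type, tail_len, _ = call_tail(aln)
    assert (tail_seq, tail_type, tail_len) == ("", "none", 0)


def test_mismatching_suffix_becomes_tail(toy_ref):
    chrom = toy_ref.chromosomes["c1"]
    idx = GenomeIndex(toy_ref)
    body = chrom[500:520]
    cont = chrom[520]
    suffix = "TT" if cont != "T" else "GG"
    aln = map_prefix("r", body + suffix, idx)
    assert aln.body_len == 20
    tail_seq, tail_type, tail_len, last = call_tail(aln)
    assert tail_len == 2
    assert tail_seq == suffix.replace("T", "U")


def test_templated_continuation_absorbed_into_body(toy_ref):
    """A 3' base equal to the genomic continuation joins the body (greedy)."""
    chrom = toy_ref.chromosomes["c1"]
    idx = GenomeIndex(toy_ref)
    body = chrom[700:720]
    cont = chrom[720]
    aln = map_prefix("r", body + cont, idx)
    assert aln.body_len == 21
    assert call_tail(aln)[1] == "none"


def test_minus_strand_mapping(toy_ref):
    chrom = toy_ref.chromosomes["c1"]
    idx = GenomeIndex(toy_ref)
    read = revcomp(chrom[800:822])
    aln = map_prefix("r", read, idx)
    assert (aln.start, aln.end, aln.strand) == (800, 822, "-")


def test_unmapped_and_multimapper_discarded(toy_ref):
    idx = GenomeIndex(toy_ref)
    assert map_prefix("r", "ACGTACGTACGTAC", idx) is None  # below min body
    dup = toy_ref.chromosomes["c1"][100:130]  # present twice by construction
    assert map_prefix("r", dup, idx) is None


def test_last_templated_nt_in_read_orientation(toy_ref):
    chrom = toy_ref.chromosomes["c1"]
    idx = GenomeIndex(toy_ref)
    for read in (chrom[900:921], revcomp(chrom[950:971])):
        aln = map_prefix("r", read, idx)
        assert call_tail(aln)[3] == read[aln.body_len - 1].replace("T", "U")


# ------------------------------------------------------------ tail typing


@pytest.mark.parametrize(
    "tail,expected",
    [("UU", "U"), ("UG", "other"), ("", "none"), ("AAA", "A"), ("U", "U"),
     ("GAU", "other"), ("CCCC", "C")],
)
def test_classify_tail_type(tail, expected):
    assert classify_tail_type(tail) == expected


def test_classify_tail_type_rejects_dna():
    with pytest.raises(ValueError):
        classify_tail_type("TT")


# ------------------------------------------------------- species classing


@pytest.fixture(scope="module")
def annotated_ref():
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=5000)])
    feats = [
        Feature("geneA", "protein_coding", "c1", 100, 400, "-",
                exons=((100, 250), (300, 400))),
        Feature("mirA", "miRNA", "c1", 1000, 1030, "+"),
        Feature("pirA", "piRNA", "c1", 2000, 2030, "-"),
        # miRNA locus nested in a gene, to exercise precedence
        Feature("geneB", "protein_coding", "c1", 3000, 3300, "-",
                exons=((3000, 3300),)),
        Feature("mirB", "miRNA", "c1", 3100, 3130, "+"),
    ]
    return ReferenceSet(chromosomes={"c1": seq}, features=feats)


def _aln(ref, start, end, strand):
    return BodyAlignment("r", "", "c1", start, end, strand, end - start)


def test_antisense_cds_read_is_sirna(annotated_ref):
    lookup = FeatureLookup(annotated_ref)
    # geneA is on '-', so a '+' body over its exon is antisense
    assert classify_species(_aln(annotated_ref, 120, 142, "+"), lookup) == (
        "siRNA", "geneA",
    )
    # sense body over the same exon is not an siRNA
    assert classify_species(_aln(annotated_ref, 120, 142, "-"), lookup)[0] == (
        "unassigned"
    )


def test_sense_read_within_mirna_locus(annotated_ref):
    lookup = FeatureLookup(annotated_ref)
    assert classify_species(_aln(annotated_ref, 1005, 1027, "+"), lookup) == (
        "miRNA", "mirA",
    )
    assert classify_species(_aln(annotated_ref, 2002, 2024, "-"), lookup) == (
        "piRNA", "pirA",
    )


def test_intergenic_read_unassigned(annotated_ref):
    lookup = FeatureLookup(annotated_ref)
    assert classify_species(_aln(annotated_ref, 4500, 4522, "+"), lookup)[0] == (
        "unassigned"
    )


def test_exon_overlap_threshold(annotated_ref):
    lookup = FeatureLookup(annotated_ref)
    # body 240-262 covers 10 nt of exon1 (240-250) out of 22 -> below 0.9
    assert classify_species(_aln(annotated_ref, 240, 262, "+"), lookup)[0] == (
        "unassigned"
    )


def test_mirna_precedence_over_sirna(annotated_ref):
    lookup = FeatureLookup(annotated_ref)
    # '+' body inside mirB is sense-miRNA and antisense to geneB's CDS
    assert classify_species(_aln(annotated_ref, 3105, 3127, "+"), lookup) == (
        "miRNA", "mirB",
    )


# --------------------------------------------------- pipeline invariants


def test_caller_recovers_truth_exactly(wt_calls, wt_sim):
    merged = wt_calls.merge(wt_sim.truth, on="read_id", how="inner")
    assert len(merged) == len(wt_calls)
    assert (merged["tail_seq"].fillna("")
            == merged["true_tail_seq"].fillna("")).all()
    assert (merged["species_class"] == merged["class"]).all()
    assert (merged["replicate_x"] == merged["replicate_y"]).all()


def test_tailcall_field_invariants(wt_calls):
    assert (wt_calls["tail_len"] == wt_calls["tail_seq"].fillna("").str.len()).all()
    assert ((wt_calls["tail_type"] == "none")
            == (wt_calls["tail_len"] == 0)).all()
    assert not wt_calls["tail_seq"].fillna("").str.contains("T").any()
    body_len = wt_calls["end"] - wt_calls["start"]
    assert (body_len + wt_calls["tail_len"]).between(15, 26).all()
    assert wt_calls["last_templated_nt"].isin(list("ACGU")).all()


def test_retained_reads_partition(small_ref, wt_sim, genome_index):
    """Every retained read is exactly one of unmapped/multimapper/called."""
    recs = wt_sim.reads["rep1"][:2000]
    retained = [(rid, seq) for rid, seq in recs
                if retain_read(seq, [40] * len(seq)) is not None]
    calls = call_tails(recs, small_ref, index=genome_index)
    called_ids = set(calls["read_id"])
    assert called_ids <= {rid for rid, _ in retained}
    for rid, seq in retained:
        aln = map_prefix(rid, seq, genome_index)
        assert (aln is not None) == (rid in called_ids)


def test_strand_symmetry(small_ref, wt_sim, genome_index):
    """Reverse-complementing the genome and flipping annotation leaves
    calls invariant up to coordinate reflection."""
    chrom = small_ref.chromosomes["chrT"]
    L = len(chrom)
    flipped = ReferenceSet(
        chromosomes={"chrT": revcomp(chrom)},
        features=[
            Feature(
                f.feature_id, f.biotype, f.chrom, L - f.end, L - f.start,
                "+" if f.strand == "-" else "-",
                tuple(sorted((L - e, L - s) for s, e in f.exons)),
            )
            for f in small_ref.features
        ],
    )
    recs = wt_sim.reads["rep1"][:800]
    a = call_tails(recs, small_ref, index=genome_index).set_index("read_id")
    b = call_tails(recs, flipped).set_index("read_id")
    assert set(a.index) == set(b.index)
    b = b.loc[a.index]
    for col in ("species_class", "species_id", "tail_seq", "tail_type",
                "tail_len", "last_templated_nt"):
        assert (a[col].fillna("") == b[col].fillna("")).all(), col
    assert (b["start"] == L - a["end"]).all()
    assert (a["strand"] != b["strand"]).all()


# ------------------------------------------------------------------- SAM


def _write_sam(path, chrom_len, rows):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:c1\tLN:{chrom_len}\n")
        for name, flag, pos, cigar, seq in rows:
            fh.write(
                f"{name}\t{flag}\tc1\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t"
                f"{'I' * len(seq)}\n"
            )


def test_sam_ingestion_matches_exact_path(toy_ref, tmp_path):
    chrom = toy_ref.chromosomes["c1"]
    idx = GenomeIndex(toy_ref)
    body = chrom[500:520]
    cont = chrom[520]
    tail = "TT" if cont != "T" else "GG"
    stop = next(b for b in "ACGT" if b != chrom[521])
    absorbed = body + cont + stop
    sam = tmp_path / "reads.sam"
    _write_sam(
        sam,
        len(chrom),
        [
            ("tailed", 0, 501, "20M2S", body + tail),
            # aligner clipped 2 bases but the first is templated: greedy
            # absorption must move it into the body
            ("absorb", 0, 501, "20M2S", absorbed),
            # SAM stores minus-strand reads in reference orientation
            ("minus", 16, 801, "22M", chrom[800:822]),
        ],
    )
    calls = call_tails_sam(str(sam), toy_ref).set_index("read_id")
    assert calls.loc["tailed", "tail_seq"] == tail.replace("T", "U")
    assert calls.loc["absorb", "tail_len"] == 1
    assert calls.loc["absorb", "end"] == 521
    assert calls.loc["minus", "strand"] == "-"
    assert calls.loc["minus", "tail_type"] == "none"
    # cross-check the tailed read against the exact-match path
    aln = map_prefix("x", body + tail, idx)
    assert call_tail(aln)[0] == calls.loc["tailed", "tail_seq"]
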