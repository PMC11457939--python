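"""Poly(U)-aware mRNA tail classification from mRNA-end reads.

A read's 5' portion is aligned as a suffix of its transcript (exact
match, maximal prefix); the remaining nontemplated 3' suffix is parsed as
a maximal A-run followed by a maximal U-run and classified:

* polyA   — A-run >= min_a, no U-run (strict A-tail)
* polyU   — U-run >= 3 with no leading A (strict U-tail)
* polyA_U — A-run >= min_a then U-run >= 3
* none    — everything else, including U-runs shorter than the 3-U
  detection floor and suffixes that are not A-then-U shaped

The 3-U floor mirrors the resolution limit of signal-space tail calling
on nanopore data: stretches of fewer than 3 Us, and As intermixed with
Us, are not recoverable there, so the sequence-space classifier applies
the same rule and therefore undercounts short/intermixed U additions by
design.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_U_RUN = 3  # detection floor for U-runs
MIN_A_RUN = 3
MIN_GROUP_READS = 50  # tail-length groups below this are excluded from stats

_SUFFIX_RE = re.compile(r"(A*)(T*)\Z")


@dataclass(frozen=True)
class MrnaTailCall:
    read_id: str
    transcript_id: str | None
    tail_class: str  # polyA / polyU / polyA_U / none
    a_len: int
    u_len: int
    replicate: str = "rep1"


def classify_suffix(
    suffix: str, min_a: int = MIN_A_RUN, min_u: int = MIN_U_RUN
) -> tuple[str, int, int]:
    """Classify a nontemplated DNA suffix into (tail_class, a_len, u_len).

    Run lengths below their floors are zeroed in the output so reported
    lengths always satisfy the class definition.
    """
    m = _SUFFIX_RE.fullmatch(suffix)
    if m is None:
        return "none", 0, 0  # not A-then-U shaped: unclassifiable
    a, u = len(m.group(1)), len(m.group(2))
    if a >= min_a and u >= min_u:
        return "polyA_U", a, u
    if a >= min_a and u < min_u:
        return "polyA", a, 0
    if a == 0 and u >= min_u:
        return "polyU", 0, u
    return "none", 0, 0


class TranscriptIndex:
    """Seed index of transcript k-mers for suffix alignment of end reads."""

    def __init__(self, transcripts: dict[str, str], seed_len: int = 20):
        self.transcripts = transcripts
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in transcripts.items():
            for pos in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[pos : pos + seed_len], []).append(
                    (tid, pos)
                )

    def align_end(self, read_seq: str) -> tuple[str, str] | None:
        """Align a read prefix to a transcript 3' region.

        Returns (transcript_id, nontemplated_suffix) or None when the read
        is unmapped or ambiguous between transcripts. The body is maximal:
        it extends as far into the transcript as the read matches; tails
        only arise past the transcript 3' end.
        """
        if len(read_seq) < self.seed_len:
            return None
        hits = self._index.get(read_seq[: self.seed_len], ())
        matches: list[tuple[str, int]] = []
        for tid, pos in hits:
            tseq = self.transcripts[tid]
            body_len = min(len(read_seq), len(tseq) - pos)
            if read_seq[:body_len] == tseq[pos : pos + body_len]:
                matches.append((tid, body_len))
        if not matches:
            return None
        tids = {t for t, _ in matches}
        if len(tids) > 1:
            logger.debug("ambiguous end read across transcripts %s", sorted(tids))
            return None
        tid = tids.pop()
        body_len = max(b for t, b in matches if t == tid)
        return tid, read_seq[body_len:]


def call_mrna_tail(
    read_seq: str,
    transcript_seq: str,
    min_a: int = MIN_A_RUN,
    min_u: int = MIN_U_RUN,
    min_body: int = 20,
) -> tuple[str, int, int] | None:
    """Classify one read against one transcript; None if unmapped.

    The templated body is the longest read prefix equal to a suffix-region
    of the transcript; the remainder is the tail candidate.
    """
    n = min(len(read_seq), len(transcript_seq))
    for body_len in range(n, min_body - 1, -1):
        if read_seq[:body_len] == transcript_seq[-body_len:]:
            return classify_suffix(read_seq[body_len:], min_a, min_u)
    return None


def call_mrna_tails(
    reads,
    transcripts: dict[str, str],
    replicate: str = "rep1",
    min_a: int = MIN_A_RUN,
    min_u: int = MIN_U_RUN,
    index: TranscriptIndex | None = None,
) -> pd.DataFrame:
    """Classify an iterable of (read_id, seq) mRNA-end reads.

    Unmapped/ambiguous reads are excluded (counted in the log).
    """
    index = index or TranscriptIndex(transcripts)
    rows = []
    n_unmapped = 0
    for rid, seq in reads:
        hit = index.align_end(seq.upper())
        if hit is None:
            n_unmapped += 1
            continue
        tid, suffix = hit
        cls, a_len, u_len = classify_suffix(suffix, min_a, min_u)
        rows.append((rid, tid, cls, a_len, u_len, replicate))
    if n_unmapped:
        logger.info("%d mRNA-end reads unmapped or ambiguous", n_unmapped)
    return pd.DataFrame(
        rows,
        columns=["read_id", "transcript_id", "tail_class", "a_len", "u_len",
                 "replicate"],
    )


def _length_stats(lengths: pd.Series, min_group: int) -> tuple[float, float]:
    """(mean, mode) over tail lengths, using only length groups with
    >= min_group reads; NaN when no group qualifies."""
    counts = lengths.value_counts()
    kept = counts[counts >= min_group]
    if kept.empty:
        return float("nan"), float("nan")
    mean = float((kept.index.to_numpy() * kept.to_numpy()).sum() / kept.sum())
    mode = float(kept.sort_index(ascending=True).idxmax())
    return mean, mode


def tail_profile(
    calls: pd.DataFrame,
    genotype: str = "",
    min_cpm: float = 10.0,
    min_group_reads: int = MIN_GROUP_READS,
) -> dict:
    """Per-genotype tail-class fractions and length statistics.

    Class fractions are the mean over replicates of per-replicate read
    fractions. Length mean/mode are computed over reads of the class,
    restricted to length groups with >= ``min_group_reads`` reads.
    Per-transcript strict-U frequencies cover transcripts at
    >= ``min_cpm`` CPM (mean across replicates).
    """
    if calls.empty:
        raise ValueError("no mRNA tail calls")
    frac = (
        calls.groupby("replicate")["tail_class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["polyA", "polyU", "polyA_U", "none"], fill_value=0.0)
        .mean(axis=0)
    )
    a_mean, a_mode = _length_stats(
        calls.loc[calls["tail_class"] == "polyA", "a_len"], min_group_reads
    )
    u_mean, u_mode = _length_stats(
        calls.loc[calls["tail_class"] == "polyU", "u_len"], min_group_reads
    )
    # transcript-level strict-U frequency, on transcripts with enough reads
    per_rep = calls.groupby(["replicate", "transcript_id"]).size().rename("n")
    lib = calls.groupby("replicate").size()
    tx_cpm = (per_rep * 1e6 / lib.reindex(
        per_rep.index.get_level_values("replicate")).to_numpy())
    mean_cpm = tx_cpm.groupby("transcript_id").mean()
    kept_tx = mean_cpm.index[mean_cpm >= min_cpm]
    sub = calls[calls["transcript_id"].isin(kept_tx)]
    per_tx = sub.groupby("transcript_id").agg(
        total=("read_id", "size"),
        strict_u=("tail_class", lambda s: int((s == "polyU").sum())),
    )
    per_tx["u_freq"] = per_tx["strict_u"] / per_tx["total"]
    return {
        "genotype": genotype,
        "frac_polyA": float(frac["polyA"]),
        "frac_polyU": float(frac["polyU"]),
        "frac_AU": float(frac["polyA_U"]),
        "frac_none": float(frac["none"]),
        "a_len_mean": a_mean,
        "a_len_mode": a_mode,
        "u_len_mean": u_mean,
        "u_len_mode": u_mode,
        "per_transcript_u_freq": per_tx["u_freq"],
    }


def u_freq_by_gene_set(
    profile: dict, gene_sets: dict[str, list[str]]
) -> pd.Series:
    """Unweighted mean per-transcript strict-U frequency within each set;
    NaN for sets with no profiled transcript."""
    freqs = profile["per_transcript_u_freq"]
    out = {}
    for name, genes in gene_sets.items():
        present = freqs.index.intersection(pd.Index(genes))
        out[name] = float(freqs.loc[present].mean()) if len(present) else float("nan")
    return pd.Series(out, name="mean_u_freq")
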