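"""Uridylation quantification over species x replicate count tables.

All frequency arithmetic uses raw read counts, never CPM: the pooled
U-tail frequency of a species in a genotype is the number of U-tailed
reads summed across that genotype's replicates divided by the total reads
summed across the same replicates. CPM is used only for abundance
filtering.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

TAIL_TYPES = ("A", "C", "G", "U", "other")


def build_species_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-read tail calls into a species x replicate table.

    ``calls`` is a TailCall table (see :mod:`utailor.tailcaller`);
    unassigned reads are dropped. Columns: class, total_reads, one count
    column per tail type, and library_size (species-assigned reads in the
    replicate).
    """
    df = calls[calls["species_class"] != "unassigned"]
    if df.empty:
        raise ValueError("no species-assigned reads to aggregate")
    g = df.groupby(["species_id", "replicate"])
    table = g.agg(
        species_class=("species_class", "first"),
        total_reads=("read_id", "size"),
    )
    for t in TAIL_TYPES:
        table[f"tailed_{t}"] = (
            df[df["tail_type"] == t].groupby(["species_id", "replicate"]).size()
        )
    table = table.fillna(0)
    count_cols = ["total_reads"] + [f"tailed_{t}" for t in TAIL_TYPES]
    table[count_cols] = table[count_cols].astype(int)
    lib = df.groupby("replicate").size()
    table = table.reset_index()
    table["library_size"] = table["replicate"].map(lib)
    return table


def tail_length_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Long-format (species_id, replicate, tail_type, tail_len) -> count."""
    tailed = calls[(calls["tail_type"] != "none")
                   & (calls["species_class"] != "unassigned")]
    out = (
        tailed.groupby(["species_id", "replicate", "tail_type", "tail_len"])
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def pooled_u_frequency(tailed_counts, total_counts) -> float:
    """Sum of U-tailed reads over sum of total reads across replicates.

    Returns NaN (missing) when the species has no reads at all — 0/0 is
    not evidence of absent tailing.
    """
    total = int(np.sum(total_counts))
    if total == 0:
        return float("nan")
    return float(np.sum(tailed_counts)) / total


def cpm(counts, library_size) -> np.ndarray:
    """Counts per million species-assigned reads."""
    library_size = np.asarray(library_size, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def log2fc_uridylation(mut_freq: float, wt_freq: float) -> float:
    """log2(mutant frequency / wild-type frequency).

    A zero numerator maps to -inf and a zero denominator to +inf; callers
    treat the infinities as sentinels and exclude them from plots.
    """
    if math.isnan(mut_freq) or math.isnan(wt_freq):
        return float("nan")
    if mut_freq == 0 and wt_freq == 0:
        return float("nan")
    if mut_freq == 0:
        return float("-inf")
    if wt_freq == 0:
        return float("inf")
    return math.log2(mut_freq / wt_freq)


def replicate_u_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species, per-replicate U-tail frequency (NaN where no reads)."""
    out = table[["species_id", "replicate", "species_class"]].copy()
    out["u_freq"] = table["tailed_U"] / table["total_reads"].replace(0, np.nan)
    return out


def uridylation_frequencies(
    table: pd.DataFrame, genotype_of: dict[str, str]
) -> pd.DataFrame:
    """Pooled U-tail frequency per species x genotype.

    ``genotype_of`` maps replicate label -> genotype. Rows: species_id,
    species_class, genotype, pooled_u_freq, n_replicates, total_reads.
    """
    df = table.copy()
    df["genotype"] = df["replicate"].map(genotype_of)
    if df["genotype"].isna().any():
        missing = sorted(df.loc[df["genotype"].isna(), "replicate"].unique())
        raise ValueError(f"replicates missing from the sample sheet: {missing}")
    rows = []
    for (sp, geno), sub in df.groupby(["species_id", "genotype"]):
        rows.append(
            {
                "species_id": sp,
                "species_class": sub["species_class"].iloc[0],
                "genotype": geno,
                "pooled_u_freq": pooled_u_frequency(
                    sub["tailed_U"], sub["total_reads"]
                ),
                "n_replicates": len(sub),
                "total_reads": int(sub["total_reads"].sum()),
            }
        )
    return pd.DataFrame(rows)


def log2fc_table(
    freqs: pd.DataFrame, wt_label: str, mut_label: str
) -> pd.DataFrame:
    """Per-species log2FC of pooled U-tail frequency, mutant vs wild type.

    ``freqs`` is the output of :func:`uridylation_frequencies`. Species
    missing from either genotype get NaN; zero frequencies produce the
    +/-inf sentinels of :func:`log2fc_uridylation`.
    """
    wide = freqs.pivot_table(index="species_id", columns="genotype",
                             values="pooled_u_freq", aggfunc="first")
    for label in (wt_label, mut_label):
        if label not in wide.columns:
            raise ValueError(f"genotype {label!r} absent from frequency table")
    out = wide[[wt_label, mut_label]].copy()
    out.columns = ["wt_freq", "mut_freq"]
    out["log2fc_u"] = [
        log2fc_uridylation(m, w) if not (math.isnan(m) or math.isnan(w))
        else float("nan")
        for m, w in zip(out["mut_freq"], out["wt_freq"])
    ]
    return out


def tail_length_spectrum(
    len_counts: pd.DataFrame,
    replicates: list[str] | None = None,
    species_class: str | None = None,
    tail_type: str = "U",
) -> pd.Series:
    """Share of each tail length among tails of one type, pooled over
    replicates (and optionally restricted to one sRNA class via a
    species_class column merged upstream)."""
    df = len_counts[len_counts["tail_type"] == tail_type]
    if replicates is not None:
        df = df[df["replicate"].isin(replicates)]
    if species_class is not None:
        if "species_class" not in df.columns:
            raise ValueError("len_counts has no species_class column")
        df = df[df["species_class"] == species_class]
    if df.empty:
        raise ValueError("no tailed reads of the requested type")
    counts = df.groupby("tail_len")["count"].sum().sort_index()
    return counts / counts.sum()


def last_templated_distribution(calls: pd.DataFrame) -> pd.Series:
    """Distribution of the final templated nucleotide among U-tailed reads."""
    u = calls[calls["tail_type"] == "U"]
    if u.empty:
        raise ValueError("no U-tailed calls")
    counts = u["last_templated_nt"].value_counts()
    return (counts / counts.sum()).reindex(list("ACGU"), fill_value=0.0)


def cpm_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Species x replicate CPM matrix from a species table."""
    wide = table.pivot_table(
        index="species_id", columns="replicate", values="total_reads",
        aggfunc="sum", fill_value=0,
    )
    lib = table.drop_duplicates("replicate").set_index("replicate")["library_size"]
    return wide * 1e6 / lib.reindex(wide.columns)
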