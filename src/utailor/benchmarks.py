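"""End-to-end parameter-recovery runs on the built-in genotype fixtures.

Each function generates a reference and reads with the built-in profiles,
pushes them through the full pipeline (retention, mapping, tail calling,
classification, quantification, filtering) and measures the summary
statistics the fixtures were configured from. Every estimate is returned
with its standard error and the problem size, so callers can check
statistical recovery rather than point equality.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import filters, quant
from .mrna import TranscriptIndex, call_mrna_tails, tail_profile
from .profiles import SimProfile, pup1_null_profile, pup3_null_profile, wild_type_profile
from .reference import ReferenceSet, make_reference
from .simulate import simulate_mrna_reads, simulate_srna_reads
from .tailcaller import FeatureLookup, GenomeIndex, call_tails


def _mean_se(values) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = len(arr)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(n)), n


def _share_se(k: int, n: int) -> float:
    p = k / n
    return math.sqrt(p * (1 - p) / n)


def run_srna_pipeline(
    ref: ReferenceSet, profile: SimProfile
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one genotype and call tails for every replicate.

    Returns (tail calls, truth) with reads from all replicates pooled.
    """
    sim = simulate_srna_reads(ref, profile)
    index = GenomeIndex(ref)
    lookup = FeatureLookup(ref)
    calls = pd.concat(
        [
            call_tails(recs, ref, replicate=rep, index=index, lookup=lookup)
            for rep, recs in sim.reads.items()
        ],
        ignore_index=True,
    )
    return calls, sim.truth


def srna_recovery(
    seed: int,
    n_genes: int = 220,
    n_mirna: int = 80,
    n_pirna: int = 80,
    chrom_len: int = 400_000,
    reads_per_replicate: int = 90_000,
    n_replicates: int = 3,
) -> dict[str, dict]:
    """Wild-type and pup-1 null sRNA fixtures through the full pipeline.

    Measures, as percentages: mean pooled U-tail frequency per class in
    wild type; the single-U share of siRNA U-tails in wild type and in
    the pup-1 null; and the mean pooled U-tail frequency, in the pup-1
    genotype, of siRNA species the overlap filter calls down-uridylated.
    """
    n_species = {"siRNA": n_genes - 20, "miRNA": n_mirna, "piRNA": n_pirna}
    ref = make_reference(n_genes, n_mirna, n_pirna, chrom_len=chrom_len, seed=seed)
    wt = wild_type_profile(
        n_species_per_class=n_species,
        reads_per_replicate=reads_per_replicate,
        n_replicates=n_replicates,
        seed=seed + 1,
    )
    pup1 = pup1_null_profile(
        n_species_per_class=n_species,
        reads_per_replicate=reads_per_replicate,
        n_replicates=n_replicates,
        seed=seed + 2,
    )
    wt_calls, _ = run_srna_pipeline(ref, wt)
    mut_calls, _ = run_srna_pipeline(ref, pup1)

    wt_table = quant.build_species_table(wt_calls)
    wt_freqs = quant.uridylation_frequencies(
        wt_table, {f"rep{i + 1}": "wild_type" for i in range(n_replicates)}
    )
    out: dict[str, dict] = {}
    for key, cls in (("wt_sirna_u_freq", "siRNA"), ("wt_mirna_u_freq", "miRNA"),
                     ("wt_pirna_u_freq", "piRNA")):
        vals = wt_freqs.loc[wt_freqs["species_class"] == cls, "pooled_u_freq"]
        mean, se, n = _mean_se(vals)
        out[key] = {"value": 100 * mean, "se": 100 * se, "n": n}

    def u1_share(calls: pd.DataFrame) -> dict:
        u = calls[(calls["species_class"] == "siRNA") & (calls["tail_type"] == "U")]
        k, n = int((u["tail_len"] == 1).sum()), len(u)
        return {"value": 100 * k / n, "se": 100 * _share_se(k, n), "n": n}

    out["wt_sirna_u1_share"] = u1_share(wt_calls)
    out["pup1_sirna_u1_share"] = u1_share(mut_calls)

    # overlap filter: wild type vs pup-1, abundance cutoff first
    mut_calls = mut_calls.copy()
    mut_calls["replicate"] = mut_calls["replicate"].str.replace("rep", "mrep")
    all_calls = pd.concat([wt_calls, mut_calls], ignore_index=True)
    table = quant.build_species_table(all_calls)
    genotype_of = {f"rep{i + 1}": "wild_type" for i in range(n_replicates)}
    genotype_of.update({f"mrep{i + 1}": "pup1_null" for i in range(n_replicates)})
    cpm_mat = quant.cpm_matrix(table)
    passing = filters.abundance_filter(
        cpm_mat, {s: genotype_of[s] for s in cpm_mat.columns}, min_cpm=50.0
    )
    rep_freqs = quant.replicate_u_frequencies(table)
    verdicts = filters.overlap_verdicts(
        rep_freqs, genotype_of, "wild_type", ["pup1_null"], abundance_pass=passing
    )
    freqs = quant.uridylation_frequencies(table, genotype_of)
    sirna_ids = set(
        freqs.loc[freqs["species_class"] == "siRNA", "species_id"]
    )
    down = [
        sp
        for sp in verdicts.index[verdicts["pup1_null"] == filters.DOWN]
        if sp in sirna_ids
    ]
    mut_freqs = freqs[(freqs["genotype"] == "pup1_null")
                      & freqs["species_id"].isin(down)]
    mean, se, n = _mean_se(mut_freqs["pooled_u_freq"])
    out["pup1_down_sirna_u_freq"] = {"value": 100 * mean, "se": 100 * se, "n": n}
    return out


def run_mrna_pipeline(
    ref: ReferenceSet, profile: SimProfile
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sim = simulate_mrna_reads(ref, profile)
    transcripts = ref.transcriptome()
    index = TranscriptIndex(transcripts)
    calls = pd.concat(
        [
            call_mrna_tails(recs, transcripts, replicate=rep, index=index)
            for rep, recs in sim.reads.items()
        ],
        ignore_index=True,
    )
    return calls, sim.truth


def mrna_recovery(
    seed: int,
    n_genes: int = 120,
    chrom_len: int = 200_000,
    reads_per_replicate: int = 40_000,
    n_replicates: int = 3,
) -> dict[str, dict]:
    """Wild-type and pup-3 null mRNA-end fixtures through the classifier.

    Measures strict-A/strict-U read percentages and length means from the
    profiled output (length groups below 50 reads excluded, as in the
    profiling rule).
    """
    ref = make_reference(n_genes, 1, 1, chrom_len=chrom_len, seed=seed + 10)
    out: dict[str, dict] = {}
    for label, factory, dseed in (("wt", wild_type_profile, 3),
                                  ("pup3", pup3_null_profile, 4)):
        profile = factory(
            reads_per_replicate=reads_per_replicate,
            n_replicates=n_replicates,
            seed=seed + dseed,
        )
        calls, _ = run_mrna_pipeline(ref, profile)
        prof = tail_profile(calls, genotype=label)
        n = len(calls)
        for key, frac in (("frac_polyA", prof["frac_polyA"]),
                          ("frac_polyU", prof["frac_polyU"])):
            k = int(round(frac * n))
            out[f"{label}_{key}"] = {
                "value": 100 * frac, "se": 100 * _share_se(max(k, 1), n), "n": n,
            }
        if label == "wt":
            a_lens = calls.loc[calls["tail_class"] == "polyA", "a_len"]
            u_lens = calls.loc[calls["tail_class"] == "polyU", "u_len"]
            for key, lens, mean in (("a_len_mean", a_lens, prof["a_len_mean"]),
                                    ("u_len_mean", u_lens, prof["u_len_mean"])):
                se = float(lens.std(ddof=1) / math.sqrt(len(lens)))
                out[f"wt_{key}"] = {"value": mean, "se": se, "n": int(len(lens))}
    return out
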