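"""Target selection: abundance cutoff and the replicate-range overlap filter.

Uridylation frequency is a proportion, so conventional differential
expression machinery does not apply directly. Two selection rules are
used instead:

* an abundance cutoff — keep species with >= ``min_cpm`` CPM in at least
  k samples, k defaulting to the smallest group size (the filterByExpr
  heuristic, restated explicitly);
* the overlap filter — a species' uridylation is called meaningfully
  altered in a mutant when the [min, max] range of its per-replicate
  U-tail frequencies in the mutant is strictly disjoint from the
  wild-type range. Touching endpoints count as overlap.

Species altered in at least one mutant are the high-confidence
uridylation targets.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

NOT_ALTERED, UP, DOWN = "not_altered", "up", "down"


def abundance_filter(
    cpm: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    min_cpm: float = 50.0,
    min_samples: int | None = None,
) -> pd.Index:
    """Return the species (rows of ``cpm``) passing the abundance cutoff.

    ``groups`` maps sample (column) -> group label; ``min_samples``
    defaults to the smallest group size.
    """
    if cpm.empty:
        raise ValueError("empty CPM matrix")
    groups = pd.Series(groups)
    sizes = groups.loc[groups.index.intersection(cpm.columns)].value_counts()
    if len(sizes) < 2:
        raise ValueError("abundance filter needs >= 2 groups")
    k = int(sizes.min()) if min_samples is None else int(min_samples)
    passing = (cpm >= min_cpm).sum(axis=1) >= k
    return cpm.index[passing]


def overlap_filter(
    wt_freqs: Sequence[float], mut_freqs: Sequence[float]
) -> str:
    """Compare per-replicate frequency ranges between wild type and mutant.

    Returns 'up' when every mutant replicate frequency exceeds every
    wild-type one, 'down' for the reverse, else 'not_altered'. Any
    undefined (NaN) replicate frequency raises — callers exclude such
    species beforehand.
    """
    wt = np.asarray(wt_freqs, dtype=float)
    mut = np.asarray(mut_freqs, dtype=float)
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("overlap filter needs >= 2 replicate values per side")
    if np.isnan(wt).any() or np.isnan(mut).any():
        raise ValueError("undefined replicate frequency; exclude this species")
    if mut.min() > wt.max():
        return UP
    if mut.max() < wt.min():
        return DOWN
    return NOT_ALTERED


def overlap_verdicts(
    rep_freqs: pd.DataFrame,
    genotype_of: dict[str, str],
    wt_label: str,
    mutant_labels: Sequence[str],
    abundance_pass: pd.Index | None = None,
) -> pd.DataFrame:
    """Apply the overlap filter per species for each mutant vs wild type.

    ``rep_freqs`` has columns species_id, replicate, u_freq. Species with
    an undefined frequency in any replicate of a comparison, or failing
    the abundance cutoff, are excluded from that comparison (status NaN).
    Returns species x mutant status table plus a high_confidence flag.
    """
    df = rep_freqs.copy()
    df["genotype"] = df["replicate"].map(genotype_of)
    wide = df.pivot_table(
        index="species_id", columns=["genotype", "replicate"], values="u_freq",
        aggfunc="first",
    )
    species = wide.index
    out = pd.DataFrame(index=species)
    for mut in mutant_labels:
        statuses = []
        for sp in species:
            if abundance_pass is not None and sp not in abundance_pass:
                statuses.append(np.nan)
                continue
            wt_vals = wide.loc[sp, wt_label].to_numpy(dtype=float)
            mut_vals = wide.loc[sp, mut].to_numpy(dtype=float)
            if np.isnan(wt_vals).any() or np.isnan(mut_vals).any():
                statuses.append(np.nan)
                continue
            statuses.append(overlap_filter(wt_vals, mut_vals))
        out[mut] = statuses
    altered = out.isin([UP, DOWN]).any(axis=1)
    out["high_confidence"] = altered
    return out


def high_confidence_union(verdicts: pd.DataFrame) -> tuple[pd.Index, pd.DataFrame]:
    """High-confidence target set and UpSet-style intersection counts.

    ``verdicts`` is the species x mutant status table (statuses among
    up/down/not_altered/NaN). Returns the union of species altered in at
    least one mutant and a table of counts per direction-pattern across
    mutants (patterns like ``pupX:down|pupY:down``).
    """
    mut_cols = [c for c in verdicts.columns if c != "high_confidence"]
    altered_mask = verdicts[mut_cols].isin([UP, DOWN])
    union = verdicts.index[altered_mask.any(axis=1)]
    patterns = []
    for sp in union:
        parts = [
            f"{m}:{verdicts.at[sp, m]}"
            for m in mut_cols
            if isinstance(verdicts.at[sp, m], str)
            and verdicts.at[sp, m] in (UP, DOWN)
        ]
        patterns.append("|".join(parts))
    counts = (
        pd.Series(patterns, index=union, name="pattern")
        .value_counts()
        .rename_axis("pattern")
        .rename("n_species")
        .reset_index()
    )
    return union, counts
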