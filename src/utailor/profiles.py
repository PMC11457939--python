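"""Simulation profiles: tailing parameters per genotype.

A :class:`SimProfile` fixes, per sRNA class, the probability that a read
carries a nontemplated 3' tail, the tail-type mixture over
{A, C, G, U, other} and the U-tail length mixture; and, for mRNA-end
reads, the strict-A / strict-U / A+U / untailed composition with discrete
A- and U-length distributions.

The built-in genotype profiles encode the wild-type and poly(U)-polymerase
null tailing behaviour of the *C. elegans* adult hermaphrodite:

* wild type — mean U-tail frequency ~14% (siRNA), ~6% (miRNA), ~4%
  (piRNA); single-U additions dominate (64% of siRNA U-tails, 94% miRNA,
  96% piRNA); mRNA ends are ~72% strict A, ~3.4% strict U, ~0.93% A+U,
  with A-tails averaging ~51 nt (modes 30 and 33) and U-tails averaging
  ~5 nt (mode 3).
* pup-1 null — sRNA uridylation collapses to ~3% and oligouridylation is
  lost (>91% of remaining U-tails are a single U).
* pup-3 null — mRNA strict U-tailing drops to ~1.5% (A+U to ~0.6%) while
  strict A-tailing rises to ~78%.

The U fraction of the sRNA tail-type mixture is fixed at 0.8 (the
remaining tail types are not quantified individually in the source data);
each class's overall tailing probability is then set so that
``p_tail * P(U)`` reproduces the class U-tail frequency above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

TAIL_TYPES = ("A", "C", "G", "U", "other")
SRNA_CLASSES = ("siRNA", "miRNA", "piRNA")


def _check_mix(name: str, mix: dict, tol: float = 1e-9) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"{name} probabilities sum to {total}, expected 1")
    if any(p < 0 for p in mix.values()):
        raise ValueError(f"{name} contains negative probabilities")


@dataclass(frozen=True)
class ClassParams:
    """Tailing parameters for one sRNA class."""

    p_tail: float
    tail_type_mix: dict[str, float]
    u_len_mix: dict[int, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_tail <= 1.0:
            raise ValueError("p_tail must lie in [0, 1]")
        _check_mix("tail_type_mix", self.tail_type_mix)
        _check_mix("u_len_mix", self.u_len_mix)
        if any(t not in TAIL_TYPES for t in self.tail_type_mix):
            raise ValueError("tail types must be among " + ", ".join(TAIL_TYPES))
        if any(length < 1 for length in self.u_len_mix):
            raise ValueError("tail lengths must be >= 1")


@dataclass(frozen=True)
class MrnaParams:
    """mRNA-end tail composition and length distributions."""

    frac_polyA: float
    frac_polyU: float
    frac_AU: float
    frac_untailed: float
    a_len_dist: dict[int, float]
    u_len_dist: dict[int, float]

    def __post_init__(self) -> None:
        _check_mix(
            "mRNA tail-class fractions",
            {
                "A": self.frac_polyA,
                "U": self.frac_polyU,
                "AU": self.frac_AU,
                "none": self.frac_untailed,
            },
        )
        _check_mix("a_len_dist", self.a_len_dist)
        _check_mix("u_len_dist", self.u_len_dist)
        if any(l < 1 for l in self.a_len_dist) or any(l < 1 for l in self.u_len_dist):
            raise ValueError("tail lengths must be >= 1")


@dataclass(frozen=True)
class SimProfile:
    genotype_label: str
    class_params: dict[str, ClassParams]
    mrna_params: MrnaParams | None = None
    n_species_per_class: dict[str, int] = field(
        default_factory=lambda: {"siRNA": 50, "miRNA": 10, "piRNA": 10}
    )
    reads_per_replicate: int = 20_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c not in SRNA_CLASSES for c in self.class_params):
            raise ValueError("sRNA classes must be among " + ", ".join(SRNA_CLASSES))
        if self.reads_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("reads_per_replicate and n_replicates must be >= 1")

    def with_seed(self, seed: int) -> "SimProfile":
        return replace(self, seed=seed)


# ------------------------------------------------------------------ fixtures

_WT_TYPE_MIX = {"A": 0.10, "C": 0.03, "G": 0.03, "U": 0.80, "other": 0.04}

#: wild-type U-tail length mixtures per class (shares of U-tailed reads)
_WT_U_LEN = {
    "siRNA": {1: 0.64, 2: 0.20, 3: 0.10, 4: 0.04, 5: 0.02},
    "miRNA": {1: 0.94, 2: 0.04, 3: 0.02},
    "piRNA": {1: 0.96, 2: 0.03, 3: 0.01},
}

#: class U-tail frequencies divided by the U share of the type mixture
_WT_P_TAIL = {"siRNA": 0.14 / 0.80, "miRNA": 0.06 / 0.80, "piRNA": 0.04 / 0.80}

_PUP1_U_LEN = {1: 0.93, 2: 0.05, 3: 0.02}
_PUP1_U_FREQ = 0.03

# Strict-A lengths: spikes at the modal lengths 30 and 33 over a broad
# uniform background chosen so the mean is ~51 nt.
_A_LEN_DIST = {30: 0.08, 33: 0.07}
_A_LEN_DIST.update({l: 0.85 / 80 for l in range(15, 95) if l not in (30, 33)})
_A_LEN_DIST[30] += 0.85 / 80
_A_LEN_DIST[33] += 0.85 / 80

# Strict-U lengths: mode 3 (the detection floor), mean ~5 nt, bounded
# support so that desk-scale length-group filtering keeps nearly all mass.
_U_LEN_DIST = {3: 0.34, 4: 0.19, 5: 0.13, 6: 0.10, 7: 0.08, 8: 0.06,
               9: 0.04, 10: 0.03, 11: 0.02, 12: 0.01}

_WT_MRNA = MrnaParams(
    frac_polyA=0.72,
    frac_polyU=0.034,
    frac_AU=0.0093,
    frac_untailed=1.0 - 0.72 - 0.034 - 0.0093,
    a_len_dist=_A_LEN_DIST,
    u_len_dist=_U_LEN_DIST,
)

_PUP3_MRNA = MrnaParams(
    frac_polyA=0.78,
    frac_polyU=0.015,
    frac_AU=0.0058,
    frac_untailed=1.0 - 0.78 - 0.015 - 0.0058,
    a_len_dist=_A_LEN_DIST,
    u_len_dist=_U_LEN_DIST,
)


def wild_type_profile(**overrides) -> SimProfile:
    params = {
        cls: ClassParams(_WT_P_TAIL[cls], dict(_WT_TYPE_MIX), dict(_WT_U_LEN[cls]))
        for cls in SRNA_CLASSES
    }
    return SimProfile("wild_type", params, mrna_params=_WT_MRNA, **overrides)


def pup1_null_profile(**overrides) -> SimProfile:
    """pup-1(0): uridylation collapsed to ~3% with mostly mono-uridylation."""
    params = {
        cls: ClassParams(_PUP1_U_FREQ / 0.80, dict(_WT_TYPE_MIX), dict(_PUP1_U_LEN))
        for cls in SRNA_CLASSES
    }
    return SimProfile("pup1_null", params, mrna_params=_WT_MRNA, **overrides)


def pup3_null_profile(**overrides) -> SimProfile:
    """pup-3(0): mRNA strict-U tailing reduced; sRNA params as wild type."""
    params = {
        cls: ClassParams(_WT_P_TAIL[cls], dict(_WT_TYPE_MIX), dict(_WT_U_LEN[cls]))
        for cls in SRNA_CLASSES
    }
    return SimProfile("pup3_null", params, mrna_params=_PUP3_MRNA, **overrides)


PROFILES = {
    "wild_type": wild_type_profile,
    "pup1_null": pup1_null_profile,
    "pup3_null": pup3_null_profile,
}
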