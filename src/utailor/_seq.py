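"""Small sequence helpers shared across modules.

Reads and references are handled internally in the DNA alphabet (ACGT);
tails and last-templated nucleotides are reported in the RNA alphabet
(ACGU), matching how tailing is described in the small-RNA literature.
"""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMP)


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")
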