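"""Small allele-level helpers shared by harmonization and eQTL alignment.

Alleles are single DNA bases. A SNP is *palindromic* when its two alleles
are reverse complements of each other (A/T or C/G); for such SNPs the
strand cannot be inferred from the allele labels alone.
"""

from __future__ import annotations

VALID_ALLELES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Complementary base of a single-letter allele."""
    return _COMPLEMENT[allele]


def is_valid_allele(allele) -> bool:
    return isinstance(allele, str) and allele in VALID_ALLELES


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G SNPs, where strand flips are undetectable."""
    return _COMPLEMENT.get(a1) == a2


def match_alleles(ea_ref: str, oa_ref: str, ea_other: str, oa_other: str):
    """Classify how a second allele pair relates to a reference pair.

    Returns one of:
      ``"same"``          same effect/other assignment,
      ``"swap"``          effect and other alleles exchanged,
      ``"flip"``          reverse-complemented, same assignment,
      ``"flip_swap"``     reverse-complemented and exchanged,
      ``None``            incompatible allele sets.

    For palindromic SNPs "same" and "flip_swap" (and "swap"/"flip") are
    indistinguishable; callers must treat those separately via
    :func:`is_palindromic`.
    """
    if (ea_other, oa_other) == (ea_ref, oa_ref):
        return "same"
    if (ea_other, oa_other) == (oa_ref, ea_ref):
        return "swap"
    cea, coa = _COMPLEMENT.get(ea_other), _COMPLEMENT.get(oa_other)
    if (cea, coa) == (ea_ref, oa_ref):
        return "flip"
    if (cea, coa) == (oa_ref, ea_ref):
        return "flip_swap"
    return None
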