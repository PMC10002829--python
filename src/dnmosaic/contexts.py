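"""Canonical trinucleotide substitution classes.

Single-base substitutions are reported pyrimidine-centred: a substitution at
a purine reference base is reverse-complemented so the mutated base is C or T.
The 96 classes are the 6 substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 4 x 4 flanking bases, in the conventional catalog order
(grouped by substitution type, flanks alphabetical).
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 pyrimidine-centred classes in canonical order, e.g. "A[C>A]A".
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}

#: The 32 pyrimidine-centred trinucleotides (central base C or T).
PYRIMIDINE_TRINUCS = tuple(
    f"{five}{center}{three}"
    for center in ("C", "T")
    for five in BASES
    for three in BASES
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def parse_context(label: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into (five_prime, ref, alt, three_prime)."""
    try:
        five, rest = label[0], label[2:]
        ref, alt, three = rest[0], rest[2], rest[4]
        if label != f"{five}[{ref}>{alt}]{three}":
            raise ValueError
    except (IndexError, ValueError):
        raise ValueError(f"malformed context label: {label!r}") from None
    return five, ref, alt, three


def collapse_substitution(five: str, ref: str, alt: str, three: str) -> str:
    """Return the pyrimidine-centred class label for one substitution.

    Purine reference bases are reverse-complemented together with their
    flanks so the central base is C or T.
    """
    if ref in ("A", "G"):
        five, ref, alt, three = (
            COMPLEMENT[three],
            COMPLEMENT[ref],
            COMPLEMENT[alt],
            COMPLEMENT[five],
        )
    return f"{five}[{ref}>{alt}]{three}"
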