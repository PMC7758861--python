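"""Trinucleotide-context conventions for 96-channel substitution profiles.

Every single-base substitution is represented on the strand whose reference
base is a pyrimidine (C or T); purine-reference events are
reverse-complemented. Channels are ordered by the six pyrimidine
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) and, within each type, by
the 5' and 3' flanking bases in alphabetical order — 96 channels total.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: All 96 channel labels in canonical order, e.g. ``A[C>A]A``.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_TYPES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

#: The 32 pyrimidine-centred trinucleotide contexts, alphabetical.
PYR_CONTEXTS = tuple(
    sorted(f"{five}{center}{three}" for center in PYRIMIDINES for five in BASES for three in BASES)
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_of(triplet: str, alt: str) -> str:
    """Map a reference triplet and alternate centre base to its channel.

    If the centre reference base is a purine, both triplet and alternate are
    reverse-complemented onto the pyrimidine strand first.
    """
    ref = triplet[1]
    if ref not in PYRIMIDINES:
        triplet = revcomp(triplet)
        alt = COMPLEMENT[alt]
        ref = triplet[1]
    return f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"


def split_channel(channel: str) -> tuple[str, str, str, str]:
    """Return (5' flank, ref, alt, 3' flank) of a channel label."""
    five, rest = channel.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return five, ref, alt, three
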