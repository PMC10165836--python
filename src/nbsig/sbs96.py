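"""Canonical SBS96 mutation-type ordering.

The 96 single-base-substitution categories arise from the 6 strand-collapsed
base substitutions (pyrimidine reference: C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 4 possible 5' and 3' flanking bases.  The canonical order
used throughout this package sorts by substitution class first, then 5'
base, then 3' base, matching the convention of published signature catalogs.
"""

from __future__ import annotations

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

SBS96_TYPES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CANONICAL_INDEX = {t: i for i, t in enumerate(SBS96_TYPES)}


def is_sbs96_label(label: str) -> bool:
    return label in _CANONICAL_INDEX


def canonical_order(labels) -> list[int]:
    """Return the permutation that maps ``labels`` into canonical SBS96 order.

    Raises ``ValueError`` if any label is not a recognized SBS96 type or the
    set of labels is not exactly the 96 canonical types.
    """
    labels = list(labels)
    unknown = [l for l in labels if l not in _CANONICAL_INDEX]
    if unknown:
        raise ValueError(f"unrecognized SBS96 mutation-type label(s): {unknown[:5]}")
    if len(labels) != 96 or len(set(labels)) != 96:
        raise ValueError(f"expected 96 unique mutation types, got {len(labels)}")
    return sorted(range(96), key=lambda i: _CANONICAL_INDEX[labels[i]])
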