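"""The 96-category pyrimidine-collapsed trinucleotide classification.

Every single-base substitution is reported on the pyrimidine strand: a
mutation at a purine reference base is replaced by its reverse complement,
so only six substitution types remain (C>A, C>G, C>T, T>A, T>C, T>G), each
combined with the 4 x 4 possible 5'/3' flanking bases.

Category ordering is fixed: substitutions in the order above; within each
substitution the 5' base cycles A,C,G,T and, innermost, the 3' base cycles
A,C,G,T. Labels look like ``A(C>T)G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES: tuple[str, ...] = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def category_label(substitution: str, five: str, three: str) -> str:
    return f"{five}({substitution}){three}"


def parse_label(label: str) -> tuple[str, str, str]:
    """Inverse of :func:`category_label`; returns (substitution, 5', 3')."""
    try:
        five, rest = label[0], label[2:]
        sub, three = rest[:3], rest[4]
        if label != category_label(sub, five, three):
            raise ValueError(label)
    except (IndexError, ValueError) as exc:
        raise ValidationError(f"unparseable category label: {label!r}") from exc
    return sub, five, three


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_to_pyrimidine(ref: str, alt: str, five: str, three: str) -> tuple[str, str, str]:
    """Map a stranded (ref, alt, flanks) substitution onto the pyrimidine strand.

    Returns (substitution, 5' base, 3' base). Purine-reference mutations are
    reverse-complemented: the substitution is complemented and the flanks are
    swapped and complemented.
    """
    for base in (ref, alt, five, three):
        if base not in COMPLEMENT:
            raise ValidationError(f"invalid base {base!r}")
    if ref == alt:
        raise ValidationError(f"ref == alt ({ref})")
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}", five, three
    return (
        f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}",
        COMPLEMENT[three],
        COMPLEMENT[five],
    )


def _default_labels() -> tuple[str, ...]:
    return tuple(
        category_label(sub, five, three)
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    )


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered set of the 96 mutation categories."""

    labels: tuple[str, ...] = field(default_factory=_default_labels)

    def __post_init__(self) -> None:
        if len(self.labels) != 96 or len(set(self.labels)) != 96:
            raise ValidationError("a category scheme must contain exactly 96 distinct labels")

    def __len__(self) -> int:
        return 96

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise ValidationError(f"unknown category {label!r}") from exc

    def label_for(self, substitution: str, five: str, three: str) -> str:
        label = category_label(substitution, five, three)
        self.index(label)
        return label

    def substitution_of(self, label: str) -> str:
        return parse_label(label)[0]


DEFAULT_SCHEME = CategoryScheme()
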