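"""Point-mutation and variant-genotype notation.

Mutations use the standard one-letter convention ``<wt><position><mut>``
(e.g. ``F115C``), with 1-based positions on the engineering target sequence.
Variant genotypes are slash-separated mutation lists whose first token may be
a named-variant label resolved through a registry (e.g. ``6M2/F115C``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical one-letter amino-acid codes, alphabetical."""

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationParseError(ValueError):
    """Raised when a mutation or variant string does not match the grammar."""


class MutationValidationError(ValueError):
    """Raised when a syntactically valid mutation violates an invariant."""


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A single substitution: wild-type residue, 1-based position, replacement.

    Ordering is by position, then replacement residue, so sorted mutation
    sets yield the canonical genotype string.
    """

    position: int
    wt_residue: str
    mut_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationValidationError(
                f"position must be >= 1, got {self.position}"
            )
        for res, role in ((self.wt_residue, "wild-type"), (self.mut_residue, "mutant")):
            if res not in AMINO_ACIDS:
                raise MutationValidationError(
                    f"{role} residue {res!r} is not a canonical amino acid"
                )
        if self.wt_residue == self.mut_residue:
            raise MutationValidationError(
                f"{self.wt_residue}{self.position}{self.mut_residue}: "
                "identity substitution is not a mutation"
            )

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


def parse_mutation(text: str) -> MutationSpec:
    """Parse ``<AA><digits><AA>`` notation into a :class:`MutationSpec`.

    Raises
    ------
    MutationParseError
        If *text* does not match the grammar.
    MutationValidationError
        If the string encodes an identity substitution or a non-canonical
        residue.
    """
    m = _MUTATION_RE.match(text.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation token: {text!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return MutationSpec(position=pos, wt_residue=wt, mut_residue=mut)


def format_mutations(mutations: Iterable[MutationSpec]) -> str:
    """Canonical slash-joined form, mutations sorted by ascending position."""
    return "/".join(str(m) for m in sorted(mutations))


@dataclass(frozen=True)
class VariantGenotype:
    """A set of substitutions relative to the base (wild-type) sequence.

    ``base_label`` records the registry label the genotype was expanded from,
    if any; the mutation set is always fully expanded.
    """

    mutations: frozenset[MutationSpec] = field(default_factory=frozenset)
    base_label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise MutationValidationError(
                f"conflicting mutations at position(s) {dupes}"
            )

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def residue_at(self, position: int, wt_residue: str) -> str:
        """Residue occupying *position*: the substitution if present, else wt."""
        for m in self.mutations:
            if m.position == position:
                return m.mut_residue
        return wt_residue

    def with_mutation(self, m: MutationSpec, replace: bool = False) -> "VariantGenotype":
        """Return a genotype with *m* added; existing mutation at the same
        position is an error unless *replace*."""
        kept = {x for x in self.mutations if x.position != m.position}
        if not replace and len(kept) != len(self.mutations):
            raise MutationValidationError(
                f"position {m.position} already mutated; pass replace=True"
            )
        return VariantGenotype(mutations=frozenset(kept | {m}))

    def __str__(self) -> str:
        if not self.mutations:
            return "WT"
        return format_mutations(self.mutations)

    def __lt__(self, other: "VariantGenotype") -> bool:
        return str(self) < str(other)


WILD_TYPE = VariantGenotype()


class NamedVariantRegistry:
    """Mapping from a variant label (e.g. ``6M2``) to its substitution set."""

    def __init__(self, entries: Mapping[str, Iterable[MutationSpec]] | None = None):
        self._entries: dict[str, frozenset[MutationSpec]] = {}
        if entries:
            for label, muts in entries.items():
                self.register(label, muts)

    def register(self, label: str, mutations: Iterable[MutationSpec]) -> None:
        if label in self._entries:
            raise ValueError(f"duplicate registry label {label!r}")
        self._entries[label] = frozenset(mutations)

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __getitem__(self, label: str) -> frozenset[MutationSpec]:
        return self._entries[label]

    def labels(self) -> list[str]:
        return sorted(self._entries)


def parse_variant(
    text: str, registry: NamedVariantRegistry | None = None
) -> VariantGenotype:
    """Parse a slash-separated variant string into a genotype.

    The first token may be a registry label, which is expanded before the
    remaining substitutions are applied. ``"WT"`` (or an empty string) is the
    base genotype. Two substitutions at one position are rejected.
    """
    text = text.strip()
    if text in ("", "WT", "wt"):
        return WILD_TYPE
    tokens = text.split("/")
    mutations: set[MutationSpec] = set()
    base_label: str | None = None
    start = 0
    if registry is not None and tokens[0] in registry:
        base_label = tokens[0]
        mutations.update(registry[tokens[0]])
        start = 1
    for tok in tokens[start:]:
        try:
            mutations.add(parse_mutation(tok))
        except MutationParseError:
            if start == 0 and tok == tokens[0]:
                raise MutationParseError(
                    f"unknown registry label or malformed mutation: {tok!r}"
                )
            raise
    return VariantGenotype(mutations=frozenset(mutations), base_label=base_label)
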