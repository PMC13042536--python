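"""Smart-library design: diversity-constrained selection of single mutations
from ranked substitution scores, and fragment-combinatorial library
enumeration/sampling.

Single-site selection mimics the screening economy of a zero-shot scored
site: take the top-N substitutions by score, cluster all residues in an
amino-acid embedding space, and keep at most ``per_cluster_max`` of the
top-N per cluster so that chemically redundant substitutions do not crowd
the picks. Combinatorial libraries are defined by an ordered partition of
single mutations into gene fragments; every subset of each fragment is
realizable, so the library size is ∏ 2^|fragment|, including the unmutated
base genotype.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .mutations import AMINO_ACIDS, MutationSpec, VariantGenotype


@dataclass
class SiteSubstitutionScores:
    """Per-site substitution scores (higher = better), wild type excluded."""

    position: int
    wt_residue: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.wt_residue in self.scores:
            raise ValueError("wild-type residue must not carry a score")
        bad = [a for a in self.scores if a not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"non-canonical residues scored: {bad}")
        if any(not math.isfinite(v) for v in self.scores.values()):
            raise ValueError("substitution scores must be finite")

    def ranked(self) -> list[str]:
        """Residues by descending score, ties broken alphabetically."""
        return sorted(self.scores, key=lambda a: (-self.scores[a], a))


@dataclass
class SelectionPolicy:
    """Knobs of the diversity-constrained pick: top_n by score, k embedding
    clusters, at most per_cluster_max picks per cluster."""

    top_n: int = 9
    n_clusters: int = 7
    per_cluster_max: int = 2

    def __post_init__(self) -> None:
        if min(self.top_n, self.n_clusters, self.per_cluster_max) < 1:
            raise ValueError("policy fields must be positive")
        if self.per_cluster_max > self.top_n:
            raise ValueError("per_cluster_max cannot exceed top_n")


def cluster_amino_acids(
    embedding: Mapping[str, Sequence[float]], k: int = 7
) -> dict[str, int]:
    """Partition the 20 residues into *k* clusters of their embedding.

    Deterministic agglomerative clustering (average linkage, Euclidean
    distance); residues are processed in alphabetical order so the result
    is invariant to input ordering. Cluster ids are arbitrary but stable.
    """
    if not 1 <= k <= 20:
        raise ValueError("k must lie in 1..20")
    missing = [a for a in AMINO_ACIDS if a not in embedding]
    if missing:
        raise ValueError(f"embedding missing residues: {missing}")
    residues = list(AMINO_ACIDS)
    X = np.array([embedding[a] for a in residues], dtype=float)
    if k == 20:
        return {a: i for i, a in enumerate(residues)}
    Z = linkage(pdist(X), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters by their first (alphabetical) member for stability
    seen: dict[int, int] = {}
    out: dict[str, int] = {}
    for a, lab in zip(residues, labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[a] = seen[lab]
    if len(set(out.values())) != k:
        raise RuntimeError("linkage produced fewer than k non-empty clusters")
    return out


def select_diverse(
    site: SiteSubstitutionScores,
    clusters: Mapping[str, int],
    policy: SelectionPolicy = SelectionPolicy(),
) -> list[MutationSpec]:
    """Pick the top-scoring substitutions subject to the diversity cap.

    Walk the top-N substitutions in score order and keep one unless its
    cluster already holds ``per_cluster_max`` picks; never pad from outside
    the top N. Output order: score descending, then residue.
    """
    uncovered = [a for a in site.scores if a not in clusters]
    if uncovered:
        raise ValueError(f"clusters do not cover residues {uncovered}")
    top = site.ranked()[: policy.top_n]
    taken: Counter[int] = Counter()
    picks: list[str] = []
    for a in top:
        c = clusters[a]
        if taken[c] < policy.per_cluster_max:
            taken[c] += 1
            picks.append(a)
    return [
        MutationSpec(position=site.position, wt_residue=site.wt_residue, mut_residue=a)
        for a in picks
    ]


@dataclass
class CombinatorialLibrary:
    """All genotypes reachable by choosing any subset of each gene fragment.

    ``fragments`` is an ordered partition of single mutations into disjoint
    groups (one group per fragment of the synthetic gene); the member count
    ∏ 2^|f| includes the all-wild-type genotype.
    """

    fragments: list[list[MutationSpec]]
    base: VariantGenotype = field(default_factory=VariantGenotype)

    def __post_init__(self) -> None:
        seen: set[MutationSpec] = set()
        seen_pos: set[int] = set()
        for frag in self.fragments:
            for m in frag:
                if m in seen or m.position in seen_pos:
                    raise ValueError(f"fragments overlap at {m}")
                seen.add(m)
                seen_pos.add(m.position)

    @property
    def size(self) -> int:
        """Member count ∏ 2^|fragment|, available without enumeration."""
        return math.prod(2 ** len(f) for f in self.fragments)


def enumerate_library(lib: CombinatorialLibrary) -> Iterator[VariantGenotype]:
    """Lazily yield every library member exactly once.

    Enumeration order is the product of per-fragment subset orders
    (smallest subsets first), starting from the base genotype.
    """
    def subsets(frag: list[MutationSpec]) -> Iterator[tuple[MutationSpec, ...]]:
        for r in range(len(frag) + 1):
            yield from itertools.combinations(frag, r)

    for choice in itertools.product(*(list(subsets(f)) for f in lib.fragments)):
        muts = set(lib.base.mutations)
        for part in choice:
            muts.update(part)
        yield VariantGenotype(mutations=frozenset(muts))


def sample_library(
    lib: CombinatorialLibrary, n: int, seed: int
) -> list[VariantGenotype]:
    """Uniform sample of *n* members without replacement, seed-reproducible."""
    total = lib.size
    if n > total:
        raise ValueError(f"cannot sample {n} from a library of {total}")
    rng = np.random.default_rng(seed)
    idx = set(rng.choice(total, size=n, replace=False).tolist())
    return [g for i, g in enumerate(enumerate_library(lib)) if i in idx]


def order_breakdown(genotypes: Sequence[VariantGenotype]) -> dict[int, int]:
    """Count sampled genotypes by substitution order; values sum to the
    sample size."""
    counts: Counter[int] = Counter(g.n_mutations for g in genotypes)
    return dict(sorted(counts.items()))
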