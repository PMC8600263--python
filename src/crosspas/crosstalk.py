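"""Pairwise pathway crosstalk decomposition.

Two pathways sharing genes are factored into three sub-pathways: the shared
genes P_i ∩ P_j, the pathway-i-specific remainder P_i − (P_i ∩ P_j), and the
pathway-j-specific remainder P_j − (P_i ∩ P_j).  A pair is only decomposed
when the intersection holds at least ``min_overlap`` genes (default 3);
empty set differences are omitted.  Sub-pathways are scored as PAS features
in their own right, which removes the shared-gene collinearity that blurs
the specificity of whole-pathway scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

from .io_formats import GeneSetCollection


class SubPathwayKind(str, Enum):
    ORIGINAL = "original"
    INTERSECTION = "intersection"
    I_SPECIFIC = "i_specific"
    J_SPECIFIC = "j_specific"


@dataclass(frozen=True)
class SubPathway:
    feature_id: str
    kind: SubPathwayKind
    parents: tuple[str, ...]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"sub-pathway {self.feature_id!r} has no genes")
        n_parents = 1 if self.kind is SubPathwayKind.ORIGINAL else 2
        if len(self.parents) != n_parents:
            raise ValueError(f"{self.kind.value} sub-pathway needs {n_parents} parent(s)")


def decompose_pair(
    pathway_i: str,
    genes_i: frozenset[str] | set[str],
    pathway_j: str,
    genes_j: frozenset[str] | set[str],
    *,
    min_overlap: int = 3,
    min_specific: int = 1,
) -> list[SubPathway]:
    """Factor one pathway pair into crosstalk sub-pathways.

    Returns an empty list when |P_i ∩ P_j| < ``min_overlap``; otherwise the
    intersection sub-pathway plus each set-difference sub-pathway with at
    least ``min_specific`` genes (differences below that floor, in
    particular empty ones, are omitted).
    """
    if pathway_i == pathway_j:
        raise ValueError("pathway ids must be distinct")
    gi, gj = frozenset(genes_i), frozenset(genes_j)
    if not gi or not gj:
        raise ValueError("pathway gene sets must be non-empty")
    inter = gi & gj
    if len(inter) < min_overlap:
        return []
    out = [
        SubPathway(
            f"{pathway_i}|{pathway_j}|inter",
            SubPathwayKind.INTERSECTION,
            (pathway_i, pathway_j),
            inter,
        )
    ]
    i_spec = gi - inter
    if len(i_spec) >= max(min_specific, 1):
        out.append(
            SubPathway(
                f"{pathway_i}|{pathway_j}|{pathway_i}.spec",
                SubPathwayKind.I_SPECIFIC,
                (pathway_i, pathway_j),
                i_spec,
            )
        )
    j_spec = gj - inter
    if len(j_spec) >= max(min_specific, 1):
        out.append(
            SubPathway(
                f"{pathway_i}|{pathway_j}|{pathway_j}.spec",
                SubPathwayKind.J_SPECIFIC,
                (pathway_i, pathway_j),
                j_spec,
            )
        )
    return out


def build_crosstalk_features(
    collection: GeneSetCollection,
    *,
    min_overlap: int = 3,
    min_specific: int = 1,
) -> list[SubPathway]:
    """Original pathways plus all pairwise crosstalk sub-pathways, deduplicated.

    Pairs are enumerated in lexicographic pathway-id order (i < j), so a
    given sub-pathway receives the same feature id no matter how the input
    collection is ordered — ids must be comparable across cohorts whose
    screening ranked the same pathways differently.  Two sub-pathways with
    identical gene sets — from different pairs, or a sub-pathway duplicating
    an original — collapse onto the first feature produced, keeping the
    feature space free of perfectly collinear columns.
    """
    features: list[SubPathway] = []
    by_genes: dict[frozenset[str], SubPathway] = {}
    merges: list[tuple[str, str]] = []

    def _add(sp: SubPathway) -> None:
        kept = by_genes.get(sp.genes)
        if kept is None:
            by_genes[sp.genes] = sp
            features.append(sp)
        else:
            merges.append((sp.feature_id, kept.feature_id))

    for pid, (_, genes) in collection.items():
        _add(SubPathway(pid, SubPathwayKind.ORIGINAL, (pid,), frozenset(genes)))
    ordered = sorted(collection.items(), key=lambda kv: kv[0])
    for (pid_i, (_, gi)), (pid_j, (_, gj)) in itertools.combinations(ordered, 2):
        for sp in decompose_pair(
            pid_i, gi, pid_j, gj, min_overlap=min_overlap, min_specific=min_specific
        ):
            _add(sp)
    build_crosstalk_features.last_merges = merges  # exposed for the run report
    return features


def subpathways_to_collection(features: list[SubPathway]) -> GeneSetCollection:
    """Serialize sub-pathways as a gene-set collection so PAS scoring consumes them unchanged."""
    sets = {}
    for sp in features:
        desc = f"{sp.kind.value}:{'+'.join(sp.parents)}"
        sets[sp.feature_id] = (desc, sp.genes)
    return GeneSetCollection(sets)
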