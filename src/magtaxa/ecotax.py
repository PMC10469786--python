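"""Genus delineation from paired trees and 16S identity-based rank assignment.

A genus is a set of >= 2 sequences that is monophyletic in *both* the
neighbour-joining and the maximum-likelihood tree and whose minimum pairwise
16S identity exceeds 94.5%.  Coarser ranks use the conventional 16S
thresholds: 86.5% for family, 82.0% for order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

from .align import sequence_identity
from .io import CladeTree, SequenceRecord
from .matrices import SimilarityMatrix

RANK_THRESHOLDS: dict[str, float] = {"order": 82.0, "family": 86.5,
                                     "genus": 94.5}


@dataclass(frozen=True)
class GenusCall:
    """One delineated genus: a clade shared by both trees, above threshold."""

    index: int
    members: frozenset[str]
    min_identity: float


@dataclass(frozen=True)
class RankDecision:
    """Outcome of testing an id set against a rank's identity threshold."""

    assigned: bool
    rank: str
    threshold: float
    ids: frozenset[str]
    min_identity: float
    violating_pair: tuple[str, str] | None = None


def pairwise_identity(records: Sequence[SequenceRecord],
                      method: str = "auto") -> SimilarityMatrix:
    """All-pairs percent identity matrix over a set of sequences.

    Identity is matches over aligned columns with terminal gaps excluded;
    equal-length pairs take the exact Hamming route under ``method="auto"``.
    Sequences shorter than 100 nt are included with a warning (their
    identities are noisy).
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    short = [r.id for r in records if r.length < 100]
    if short:
        warnings.warn(f"sequences shorter than 100 nt included: {short}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    import numpy as np
    n = len(records)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = sequence_identity(records[i].residues,
                                         records[j].residues, method=method)
            vals[i, j] = vals[j, i] = ident
    return SimilarityMatrix.from_dense(ids, vals, kind="16S identity")


def call_genera(tree_a: CladeTree, tree_b: CladeTree, idm: SimilarityMatrix,
                genus_threshold: float = 94.5, min_size: int = 2,
                ) -> list[GenusCall]:
    """Delineate genera: maximal clades shared by both trees whose minimum
    pairwise identity is strictly above the genus threshold.

    Qualifying clades are selected top-down from the root of the first tree;
    a qualifying clade blocks its descendants, so calls are maximal and
    disjoint.  The result is invariant to swapping the two trees.
    """
    if tree_a.leaf_set != tree_b.leaf_set:
        only_a = sorted(tree_a.leaf_set - tree_b.leaf_set)
        only_b = sorted(tree_b.leaf_set - tree_a.leaf_set)
        raise ValueError(
            f"trees disagree on leaves: only in {tree_a.method_tag}: {only_a}; "
            f"only in {tree_b.method_tag}: {only_b}")
    missing = tree_a.leaf_set - set(idm.ids)
    if missing:
        raise ValueError(f"identity matrix lacks leaves: {sorted(missing)}")
    clades_b = tree_b.clade_sets()
    calls: list[frozenset[str]] = []

    def visit(node: dendropy.Node) -> None:
        leaves = tree_a.node_leafset(node)
        if len(leaves) >= min_size and leaves in clades_b:
            min_id, _ = idm.min_pairwise(leaves)
            if min_id > genus_threshold:
                calls.append(leaves)
                return
        for child in node.child_nodes():
            visit(child)

    visit(tree_a.tree.seed_node)
    calls.sort(key=min)
    return [GenusCall(i + 1, members, idm.min_pairwise(members)[0])
            for i, members in enumerate(calls)]


def assign_rank(ids: Iterable[str], idm: SimilarityMatrix, rank: str,
                thresholds: dict[str, float] | None = None) -> RankDecision:
    """Test whether an id set satisfies a rank's minimum-identity threshold.

    Assignment requires min pairwise identity >= the rank threshold; a
    refusal names the violating pair.  Singletons are assigned trivially.
    """
    thresholds = thresholds or RANK_THRESHOLDS
    if rank not in thresholds:
        raise ValueError(f"unknown rank {rank!r}; known: {sorted(thresholds)}")
    ids = frozenset(ids)
    threshold = thresholds[rank]
    min_id, pair = idm.min_pairwise(ids)
    if min_id >= threshold:
        return RankDecision(True, rank, threshold, ids, min_id)
    return RankDecision(False, rank, threshold, ids, min_id,
                        violating_pair=pair)


@dataclass(frozen=True)
class LengthPartition:
    backbone: tuple[str, ...]   # > backbone_min bp: used for tree inference
    addable: tuple[str, ...]    # [addable_min, backbone_min]: added by parsimony
    excluded: tuple[str, ...]   # < addable_min bp


def partition_by_length(records: Sequence[SequenceRecord],
                        backbone_min: int = 1200,
                        addable_min: int = 800) -> LengthPartition:
    """Split sequences into backbone (> 1200 bp), addable ([800, 1200] bp)
    and excluded (< 800 bp) sets for tree construction."""
    backbone, addable, excluded = [], [], []
    for r in records:
        if r.length > backbone_min:
            backbone.append(r.id)
        elif r.length >= addable_min:
            addable.append(r.id)
        else:
            excluded.append(r.id)
    return LengthPartition(tuple(backbone), tuple(addable), tuple(excluded))
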