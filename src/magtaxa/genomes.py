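"""Genome-level taxonomy: AAI computation, species/genus clustering and
dereplication.

Species are single-linkage components at >= 95% similarity (the conventional
ANI/AAI species threshold); genera are components connected strictly above a
65% AAI floor, so that distinct genera have all cross-pairs at or below the
floor.  Dereplication drops genomes failing the quality gate and keeps one
representative per species-level cluster, scored like dRep's default
(completeness - 5 x contamination).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import align_identity
from .io import QualityRecord, SequenceRecord
from .matrices import SimilarityMatrix, single_linkage_components
from .mags import quality_gate

SPECIES_THRESHOLD = 95.0   # percent ANI/AAI, inclusive
GENUS_AAI_FLOOR = 65.0     # genera are separated at AAI <= 65


@dataclass(frozen=True)
class SpeciesCluster:
    index: int
    members: frozenset[str]
    representative: str


@dataclass(frozen=True)
class AaiResult:
    """AAI of a genome pair: mean identity over reciprocal best-hit proteins.

    ``aai`` is None when no reciprocal pair passes the cutoffs (the pair is
    reported missing, i.e. below every threshold downstream).
    """

    aai: float | None
    n_pairs: int


def compute_aai(proteome_a: Sequence[SequenceRecord],
                proteome_b: Sequence[SequenceRecord],
                min_identity: float = 30.0,
                min_coverage: float = 0.7) -> AaiResult:
    """Average amino-acid identity between two proteomes.

    Reciprocal best hits are found by exhaustive pairwise alignment (free
    end gaps); a hit counts when identity >= 30% over >= 70% of the shorter
    protein, and AAI is the mean identity over reciprocal pairs.  Exhaustive
    alignment is quadratic -- intended for the small proteomes used here, not
    for full genomes.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")

    def best_hits(src, dst):
        best: dict[str, tuple[str, float]] = {}
        for p in src:
            top_score, top_id, top_ident = -np.inf, None, 0.0
            for q in dst:
                res = align_identity(p.residues, q.residues)
                if res.identity >= min_identity and res.coverage_short >= min_coverage:
                    score = res.matches
                    if score > top_score:
                        top_score, top_id, top_ident = score, q.id, res.identity
            if top_id is not None:
                best[p.id] = (top_id, top_ident)
        return best

    ab = best_hits(proteome_a, proteome_b)
    ba = best_hits(proteome_b, proteome_a)
    idents = [ident for a, (b, ident) in ab.items()
              if ba.get(b, (None,))[0] == a]
    if not idents:
        return AaiResult(None, 0)
    return AaiResult(float(np.mean(idents)), len(idents))


def species_clusters(sim: SimilarityMatrix,
                     threshold: float = SPECIES_THRESHOLD) -> list[SpeciesCluster]:
    """Single-linkage species clusters at similarity >= threshold.

    Missing pairs count as below threshold.  Clusters are indexed by their
    lexicographically smallest member; the representative defaults to that
    member (see :func:`dereplicate` for quality-aware representatives).
    """
    ids = sim.ids

    def edge(a: str, b: str) -> bool:
        v = sim.value(a, b)
        return not np.isnan(v) and v >= threshold

    comps = single_linkage_components(ids, edge)
    return [SpeciesCluster(i + 1, members, min(members))
            for i, members in enumerate(comps)]


def genus_clusters(sim: SimilarityMatrix,
                   genus_floor: float = GENUS_AAI_FLOOR) -> list[frozenset[str]]:
    """Single-linkage genus partition with edges strictly above the floor.

    Distinct genera then have all cross-pairs at similarity <= genus_floor.
    """
    def edge(a: str, b: str) -> bool:
        v = sim.value(a, b)
        return not np.isnan(v) and v > genus_floor

    return single_linkage_components(sim.ids, edge)


@dataclass(frozen=True)
class DereplicationResult:
    representatives: tuple[str, ...]
    clusters: tuple[frozenset[str], ...]
    excluded_low_quality: tuple[str, ...]


def dereplicate(qualities: Sequence[QualityRecord], sim: SimilarityMatrix,
                ani: float = 95.0, min_completeness: float = 80.0,
                max_contamination: float = 5.0) -> DereplicationResult:
    """Quality-gate genomes, cluster survivors at >= ``ani`` and keep one
    representative per cluster.

    Representative score = completeness - 5 x contamination; ties broken by
    larger assembly, then lexicographic id.
    """
    by_id = {q.genome: q for q in qualities}
    missing = set(sim.ids) - set(by_id)
    passing = [q.genome for q in qualities
               if quality_gate(q, min_completeness, max_contamination)
               and q.genome not in missing]
    excluded = tuple(sorted(set(by_id) - set(passing)))

    def edge(a: str, b: str) -> bool:
        v = sim.value(a, b)
        return not np.isnan(v) and v >= ani

    comps = single_linkage_components(sorted(passing), edge)
    reps = []
    for members in comps:
        def sort_key(g: str):
            q = by_id[g]
            return (-(q.completeness - 5.0 * q.contamination),
                    -q.assembly_size, g)
        reps.append(sorted(members, key=sort_key)[0])
    return DereplicationResult(tuple(reps), tuple(comps), excluded)
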