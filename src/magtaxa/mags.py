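"""MAG decontamination, quality gating and genome-size statistics.

Curation follows a single pass of two deterministic filters: contigs whose
read depth changes more than twofold with respect to the mean depth are
removed, then contigs carrying proteins but none affiliated to the
assembly's consensus taxon are removed.  Quality gating requires
completeness above 80% and contamination below 5% (both strict).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import QualityRecord, TabularHit
from .amplicon import filter_best_hits


@dataclass(frozen=True)
class ContigProfile:
    """Per-contig evidence used for curation."""

    contig: str
    length: int
    depth: float
    taxon_votes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.contig}: length must be >= 1")
        if self.depth < 0:
            raise ValueError(f"{self.contig}: negative depth")


@dataclass(frozen=True)
class CurationReport:
    """Outcome of the depth + taxonomy curation pass on one MAG."""

    removed_by_depth: frozenset[str]
    removed_by_taxonomy: frozenset[str]
    retained: frozenset[str]
    consensus_taxon: str
    mean_depth_before: float
    mean_depth_after: float

    @property
    def removed(self) -> frozenset[str]:
        return self.removed_by_depth | self.removed_by_taxonomy


class ConsensusTieError(ValueError):
    """Raised when the plurality taxon is tied and no override is given."""


def contig_depth(hits: Iterable[TabularHit], contig_lengths: Mapping[str, int],
                 min_identity: float = 95.0,
                 min_coverage: float = 0.7) -> dict[str, float]:
    """Sequencing depth per contig from read-mapping hits.

    Per read only the best hit is kept, filtered at >= 95% identity and
    >= 70% query coverage; depth = summed aligned length of kept reads /
    contig length.  Contigs with no kept reads get depth 0.
    """
    hits = list(hits)
    unknown = {h.sseqid for h in hits} - set(contig_lengths)
    if unknown:
        raise ValueError(f"hits reference unknown contigs: {sorted(unknown)}")
    kept = filter_best_hits(hits, min_identity=min_identity,
                            min_query_coverage=min_coverage)
    aligned: Counter[str] = Counter()
    for h in kept:
        aligned[h.sseqid] += h.length
    return {c: aligned.get(c, 0) / length
            for c, length in contig_lengths.items()}


def depth_filter(depths: Mapping[str, float], fold: float = 2.0,
                 lengths: Mapping[str, int] | None = None,
                 weighted: bool = False) -> tuple[frozenset[str], float]:
    """Remove contigs whose depth changes more than ``fold``-fold versus the
    mean depth.

    The mean is the simple (unweighted) mean over contigs by default
    (``weighted=True`` switches to length-weighting); removal is strict:
    depth > fold * mean or depth < mean / fold.  Single pass, the mean is not
    recomputed after removals.  Returns (removed ids, mean used).
    """
    if len(depths) < 2:
        raise ValueError("need at least two contigs")
    vals = np.array(list(depths.values()), dtype=float)
    if not (vals > 0).any():
        raise ValueError("all contig depths are zero")
    if weighted:
        if lengths is None:
            raise ValueError("weighted mean requires contig lengths")
        w = np.array([lengths[c] for c in depths], dtype=float)
        mean = float(np.average(vals, weights=w))
    else:
        mean = float(vals.mean())
    removed = frozenset(c for c, d in depths.items()
                        if d > fold * mean or d < mean / fold)
    return removed, mean


def votes_from_protein_hits(hits: Iterable[TabularHit],
                            contig_of=None,
                            taxon_of=None) -> dict[str, Counter]:
    """Aggregate per-contig taxon votes from best-hit-per-protein tables.

    By default the protein's contig is the qseqid up to the last ``_p`` and
    the taxon is the bracketed organism in ``stitle`` (its first word, e.g.
    a phylum label); both extractors can be overridden.
    """
    if contig_of is None:
        contig_of = lambda h: h.qseqid.rsplit("_p", 1)[0]
    if taxon_of is None:
        def taxon_of(h):
            if h.stitle and "[" in h.stitle:
                return h.stitle.rsplit("[", 1)[1].rstrip("]").split()[0]
            return None
    best: dict[str, TabularHit] = {}
    for h in hits:
        cur = best.get(h.qseqid)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[h.qseqid] = h
    votes: dict[str, Counter] = {}
    for h in best.values():
        taxon = taxon_of(h)
        if taxon is None:
            continue
        votes.setdefault(contig_of(h), Counter())[taxon] += 1
    return votes


def taxonomy_filter(contig_votes: Mapping[str, Mapping[str, int]],
                    consensus: str | None = None,
                    ) -> tuple[frozenset[str], str]:
    """Remove contigs with protein evidence but none for the consensus taxon.

    The consensus is the taxon with the highest total vote count across all
    contigs; a tie raises :class:`ConsensusTieError` unless an explicit
    ``consensus`` override is given.  Contigs with no proteins at all are
    retained (no evidence against them).
    """
    totals: Counter[str] = Counter()
    for votes in contig_votes.values():
        totals.update(votes)
    if not totals:
        raise ValueError("no contig has taxon votes")
    if consensus is None:
        ranked = totals.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            tied = sorted(t for t, n in ranked if n == ranked[0][1])
            raise ConsensusTieError(
                f"consensus taxon tied between {tied}; pass consensus= to "
                "override")
        consensus = ranked[0][0]
    removed = frozenset(
        c for c, votes in contig_votes.items()
        if sum(votes.values()) >= 1 and votes.get(consensus, 0) == 0)
    return removed, consensus


def curate(contigs: Sequence[ContigProfile], fold: float = 2.0,
           consensus: str | None = None) -> CurationReport:
    """Single-pass curation: the depth filter, then the taxonomy filter."""
    depths = {c.contig: c.depth for c in contigs}
    removed_depth, mean_before = depth_filter(depths, fold=fold)
    survivors = [c for c in contigs if c.contig not in removed_depth]
    votes = {c.contig: dict(c.taxon_votes) for c in survivors}
    removed_tax, consensus_taxon = taxonomy_filter(votes, consensus=consensus)
    retained = frozenset(c.contig for c in survivors
                         if c.contig not in removed_tax)
    after = [depths[c] for c in retained]
    mean_after = float(np.mean(after)) if after else 0.0
    return CurationReport(removed_depth, removed_tax, retained,
                          consensus_taxon, mean_before, mean_after)


def quality_gate(quality: QualityRecord, min_completeness: float = 80.0,
                 max_contamination: float = 5.0) -> bool:
    """Good quality iff completeness above 80% and contamination below 5%
    (both strict)."""
    return (quality.completeness > min_completeness
            and quality.contamination < max_contamination)


def estimated_genome_size(assembly_size: float, completeness: float) -> float:
    """Estimated genome size = assembly size / completeness (fraction 0-1)."""
    if not (0.0 < completeness <= 1.0):
        raise ValueError("completeness must lie in (0, 1]")
    if assembly_size <= 0:
        raise ValueError("assembly size must be positive")
    return assembly_size / completeness


def normalized_abundance(mapped_reads: int, metagenome_size: float,
                         genome_size: float) -> float:
    """Abundance index = mapped reads / (metagenome size x genome size).

    ``mapped_reads`` should already be best-hit filtered at >= 95% identity
    and >= 70% coverage (see :func:`contig_depth` for the filter).
    """
    if metagenome_size <= 0 or genome_size <= 0:
        raise ValueError("sizes must be positive")
    if mapped_reads < 0:
        raise ValueError("negative read count")
    return mapped_reads / (metagenome_size * genome_size)


@dataclass(frozen=True)
class SizeOriginReport:
    """One-way ANOVA of estimated genome size by origin, with Tukey HSD."""

    f_statistic: float
    p_value: float
    origins: tuple[str, ...]
    pairwise: dict[tuple[str, str], float]   # pair -> Tukey HSD p-value
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise.items() if p < self.alpha]


def size_by_origin_test(records: Sequence[QualityRecord],
                        alpha: float = 0.05) -> SizeOriginReport:
    """Test whether estimated genome size differs between MAG origins.

    One-way analysis of variance on assembly_size / completeness by origin,
    followed by all-pairs Tukey honestly-significant-difference comparisons
    (unbalanced groups allowed).
    """
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.origin, []).append(
            estimated_genome_size(r.assembly_size, r.completeness / 100.0))
    if len(groups) < 2:
        raise ValueError("need at least two origins")
    small = [o for o, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"origins with fewer than two genomes: {sorted(small)}")
    origins = sorted(groups)
    samples = [groups[o] for o in origins]
    pairwise = {}
    if len({v for s in samples for v in s}) == 1:
        # degenerate: every genome the same size -> no effect by definition
        f_stat, p = 0.0, 1.0
        for i in range(len(origins)):
            for j in range(i + 1, len(origins)):
                pairwise[(origins[i], origins[j])] = 1.0
    else:
        f_stat, p = stats.f_oneway(*samples)
        hsd = stats.tukey_hsd(*samples)
        for i in range(len(origins)):
            for j in range(i + 1, len(origins)):
                pairwise[(origins[i], origins[j])] = float(hsd.pvalue[i, j])
    return SizeOriginReport(float(f_stat), float(p), tuple(origins), pairwise,
                            alpha=alpha)
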