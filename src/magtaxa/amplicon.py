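"""16S clustering, amplicon screening and abundance/frequency summaries.

The screening model: representative 16S sequences are searched against
amplicon datasets; per read only the best hit (highest bitscore) is kept and
must reach 97% identity and 70% query coverage; relative abundance is the
percentage of passing reads over the total 16S reads of the sample.  Members
below 0.1% relative abundance belong to the rare biosphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import IUPAC_BITS, encode_iupac, reverse_complement, sequence_identity
from .io import SequenceRecord, TabularHit


@dataclass(frozen=True)
class ClusterSet:
    """A partition of sequences into identity clusters with representatives.

    The representative of each cluster is its founding -- hence longest --
    member.
    """

    clusters: Mapping[str, tuple[str, ...]]      # cluster id -> member ids
    representatives: Mapping[str, str]           # cluster id -> representative

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def representative_ids(self) -> list[str]:
        return [self.representatives[c] for c in self.clusters]

    def as_partition(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.clusters.values()}


def greedy_cluster(records: Sequence[SequenceRecord],
                   identity_threshold: float = 97.0,
                   short_coverage: float = 0.9,
                   identity_method: str = "auto") -> ClusterSet:
    """Greedy length-sorted identity clustering (cd-hit-est style).

    Records are sorted by length descending (stable); each joins the first
    cluster whose representative it matches at >= ``identity_threshold``
    percent identity with the alignment covering >= ``short_coverage`` of the
    shorter sequence, else founds a new cluster.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not (50.0 < identity_threshold <= 100.0):
        raise ValueError("identity_threshold must lie in (50, 100]")
    order = sorted(range(len(records)), key=lambda i: -records[i].length)
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for i in order:
        rec = records[i]
        for ci, rep in enumerate(reps):
            ident, cov = sequence_identity(rec.residues, rep.residues,
                                           method=identity_method)
            if ident >= identity_threshold and cov >= short_coverage:
                members[ci].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    clusters = {f"cluster{ci:04d}": tuple(m) for ci, m in enumerate(members)}
    representatives = {f"cluster{ci:04d}": reps[ci].id
                       for ci in range(len(reps))}
    return ClusterSet(clusters, representatives)


def filter_best_hits(hits: Iterable[TabularHit], min_identity: float = 97.0,
                     min_query_coverage: float = 0.7) -> list[TabularHit]:
    """Per query keep the single best hit, then apply the screening filter.

    Best = highest bitscore; ties broken by lowest evalue, then input order.
    Survivors satisfy pident >= ``min_identity`` and length/qlen >=
    ``min_query_coverage`` (both inclusive).  Output preserves first-seen
    query order.
    """
    best: dict[str, TabularHit] = {}
    for h in hits:
        cur = best.get(h.qseqid)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[h.qseqid] = h
    return [h for h in best.values()
            if h.pident >= min_identity and h.qcov >= min_query_coverage]


@dataclass(frozen=True)
class AbundanceTable:
    """Sample x taxon relative abundances as percent of total 16S reads."""

    table: pd.DataFrame                 # percent values, samples x taxa
    totals: Mapping[str, int]

    def not_detected(self, sample: str) -> bool:
        return bool((self.table.loc[sample] == 0).all())


def relative_abundance(passing_hits: Mapping[str, Iterable[TabularHit]],
                       totals: Mapping[str, int]) -> AbundanceTable:
    """Relative abundance per sample and taxon from filter survivors.

    abundance(sample, taxon) = 100 * passing reads assigned to the taxon /
    total 16S reads of the sample.
    """
    missing = set(passing_hits) - set(totals)
    if missing:
        raise ValueError(f"samples without totals: {sorted(missing)}")
    counts: dict[str, dict[str, int]] = {}
    taxa: set[str] = set()
    for sample, hits in passing_hits.items():
        if totals[sample] <= 0:
            raise ValueError(f"sample {sample}: total read count must be > 0")
        c: dict[str, int] = {}
        for h in hits:
            c[h.sseqid] = c.get(h.sseqid, 0) + 1
        counts[sample] = c
        taxa.update(c)
    samples = sorted(counts)
    cols = sorted(taxa)
    table = pd.DataFrame(0.0, index=samples, columns=cols)
    for sample in samples:
        for taxon, n in counts[sample].items():
            table.loc[sample, taxon] = 100.0 * n / totals[sample]
    return AbundanceTable(table, dict(totals))


RARE_BIOSPHERE_THRESHOLD = 0.1  # percent relative abundance


def classify_biosphere(abundance: float) -> str:
    """Rare-vs-abundant biosphere call: abundant strictly above 0.1%.

    The rare biosphere is defined as relative abundance < 0.1%; exactly 0.1
    is assigned rare for determinism.
    """
    if abundance < 0:
        raise ValueError("abundance cannot be negative")
    return "abundant" if abundance > RARE_BIOSPHERE_THRESHOLD else "rare"


def genus_frequency(detections: Mapping[str, Iterable[str]],
                    positives: Iterable[str],
                    env: Mapping[str, str]) -> pd.DataFrame:
    """Percent of group-positive samples per environment where each genus is
    detected.

    ``positives`` are the samples where the group is present at all; the
    denominator per environment is the number of its positive samples.
    Environments with zero positive samples are omitted with a warning.
    """
    positives = sorted(set(positives))
    if not positives:
        raise ValueError("no positive samples")
    genera = sorted({g for s in positives for g in detections.get(s, ())})
    envs = sorted({env[s] for s in positives if s in env})
    skipped = sorted(set(env.values()) - set(envs))
    if skipped:
        warnings.warn(f"environments without positive samples omitted: {skipped}")
    out = pd.DataFrame(0.0, index=envs, columns=genera)
    for e in envs:
        samples_e = [s for s in positives if env.get(s) == e]
        for g in genera:
            n = sum(1 for s in samples_e if g in set(detections.get(s, ())))
            out.loc[e, g] = 100.0 * n / len(samples_e)
    return out


def oligo_coverage(oligo: str, targets: Sequence[SequenceRecord],
                   max_mismatches: int = 0, search_rc: bool = True) -> float:
    """Percent of target sequences containing a window matching the oligo.

    A window matches when at most ``max_mismatches`` positions are
    incompatible; IUPAC ambiguity codes expand on the target side only (a
    target Y is compatible with an oligo C or T).  The reverse complement of
    the oligo is searched too unless disabled.
    """
    oligo = oligo.upper().replace("U", "T")
    if len(oligo) < 10:
        raise ValueError("oligo must be at least 10 nt")
    if set(oligo) - set("ACGT"):
        raise ValueError("oligo must be unambiguous (ACGT only)")
    if not targets:
        raise ValueError("empty target set")
    probes = [encode_iupac(oligo)]
    if search_rc:
        probes.append(encode_iupac(reverse_complement(oligo)))
    n_cov = sum(1 for t in targets
                if any(_scan(encode_iupac(t.residues), p, max_mismatches)
                       for p in probes))
    return 100.0 * n_cov / len(targets)


def _scan(target_bits: np.ndarray, probe_bits: np.ndarray,
          max_mismatches: int) -> bool:
    k = len(probe_bits)
    n = len(target_bits)
    if n < k:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(target_bits, k)
    compatible = (windows & probe_bits[None, :]) != 0
    mismatches = k - compatible.sum(axis=1)
    return bool((mismatches <= max_mismatches).any())
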