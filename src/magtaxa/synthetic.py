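"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is driven by a single integer seed and is bit-reproducible.
Ground truth (genus assignments, true proportions, contaminant flags, planted
pathway completeness) is returned alongside the artifacts so downstream
stages can be scored exactly.

Sequence evolution is deliberately minimal: uniform random substitutions
without indels, so that pairwise identity is exactly ``1 - Hamming/L`` and
the identity oracle stays trivial.  Within a genus the mutated position sets
of the members are disjoint, which makes within-genus identities *exact*;
between-genus identities are controlled in expectation by solving the
per-site divergence equation for independent random mutation sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CladeTree, SequenceRecord, TabularHit, read_newick_string

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# planted ground-truth containers


@dataclass(frozen=True)
class PlantedTaxonomy:
    """True genus assignments behind a simulated 16S clade."""

    genus_of: Mapping[str, int]          # leaf id -> genus index
    within_identity: float               # target within-genus percent identity
    between_identity: float              # target between-genus percent identity

    def partition(self) -> set[frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for leaf, g in self.genus_of.items():
            groups.setdefault(g, set()).add(leaf)
        return {frozenset(v) for v in groups.values()}


@dataclass(frozen=True)
class PlantedCommunity:
    """Per-sample environments, target taxon proportions and read totals."""

    environment_of: Mapping[str, str]
    proportions: Mapping[str, Mapping[str, float]]  # sample -> taxon -> fraction
    total_reads: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.environment_of:
            raise ValueError("community has no samples")
        for s, props in self.proportions.items():
            if any(p < 0 for p in props.values()):
                raise ValueError(f"sample {s}: negative proportion")
            if sum(props.values()) > 1.0 + 1e-9:
                raise ValueError(f"sample {s}: proportions sum above 1")
        if any(t < 1 for t in self.total_reads.values()):
            raise ValueError("per-sample total reads must be >= 1")


@dataclass(frozen=True)
class PlantedAssembly:
    """Ground truth for one simulated MAG contig set."""

    contig_lengths: Mapping[str, int]
    true_depth: Mapping[str, float]
    contaminant_kind: Mapping[str, str | None]  # None | "depth" | "taxonomy"
    protein_taxa: Mapping[str, tuple[str, ...]]  # contig -> per-protein labels
    consensus_taxon: str

    @property
    def contaminants(self) -> frozenset[str]:
        return frozenset(c for c, k in self.contaminant_kind.items() if k)


# ---------------------------------------------------------------------------
# 16S clade with planted sub-genus structure


def _between_mutation_count(seq_length: int, between_id: float) -> int:
    """Positions each genus ancestor mutates so that the expected pairwise
    ancestor divergence equals the target.

    With two independent uniform mutation sets of per-site density m, a site
    differs with probability 2m(1-m) + (2/3)m^2 (both mutated: each picks one
    of 3 alternative bases).  Solve 2m - (4/3)m^2 = d for the smaller root.
    """
    d = (100.0 - between_id) / 100.0
    disc = 4.0 - 16.0 * d / 3.0
    if disc < 0:
        raise ValueError("between-genus identity too low to plant")
    m = (2.0 - math.sqrt(disc)) / (8.0 / 3.0)
    return round(m * seq_length)


def simulate_sequences(n_genera: int, members_per_genus: int, seq_length: int,
                       within_id: float, between_id: float, seed: int,
                       discordant_pairs: int = 0,
                       ) -> tuple[list[SequenceRecord], PlantedTaxonomy,
                                  tuple[CladeTree, CladeTree]]:
    """Simulate a clade of 16S sequences with planted genus structure.

    Returns the records, the planted taxonomy, and the true genealogy twice
    (tagged NJ and ML) as stand-ins for independently inferred trees.  With
    ``discordant_pairs > 0`` that many adjacent genus pairs have one leaf
    swapped in the second tree, destroying their monophyly there.
    """
    if not (0.0 < between_id < within_id <= 100.0):
        raise ValueError("need 0 < between_id < within_id <= 100")
    if n_genera < 1 or members_per_genus < 1 or seq_length < 1:
        raise ValueError("counts and length must be positive")
    if discordant_pairs > n_genera // 2:
        raise ValueError("not enough genus pairs to make discordant")

    rng = np.random.default_rng(seed)
    root = rng.choice(_BASES, size=seq_length)

    k_between = _between_mutation_count(seq_length, between_id)
    j_within = round(seq_length * (100.0 - within_id) / 200.0)
    if j_within * members_per_genus > seq_length:
        raise ValueError("seq_length too short for the requested within-genus "
                         "divergence and member count")

    records: list[SequenceRecord] = []
    genus_of: dict[str, int] = {}
    for g in range(n_genera):
        ancestor = root.copy()
        pos = rng.choice(seq_length, size=k_between, replace=False)
        ancestor[pos] = _mutate_bases(ancestor[pos], rng)
        # disjoint member mutation sets -> exact pairwise within identity
        member_pos = rng.choice(seq_length, size=j_within * members_per_genus,
                                replace=False)
        for m in range(members_per_genus):
            seq = ancestor.copy()
            mp = member_pos[m * j_within:(m + 1) * j_within]
            seq[mp] = _mutate_bases(seq[mp], rng)
            rid = f"g{g:02d}_m{m:02d}"
            records.append(SequenceRecord(rid, seq.tobytes().decode()))
            genus_of[rid] = g

    taxonomy = PlantedTaxonomy(genus_of, within_id, between_id)

    def genus_clade(g: int, members: Sequence[str]) -> str:
        return "(" + ",".join(members) + ")"

    members_by_genus = [[r.id for r in records if genus_of[r.id] == g]
                        for g in range(n_genera)]
    newick_a = "(" + ",".join(genus_clade(g, m)
                              for g, m in enumerate(members_by_genus)) + ");"

    members_b = [list(m) for m in members_by_genus]
    for p in range(discordant_pairs):
        g1, g2 = 2 * p, 2 * p + 1
        members_b[g1][0], members_b[g2][0] = members_b[g2][0], members_b[g1][0]
    newick_b = "(" + ",".join(genus_clade(g, m)
                              for g, m in enumerate(members_b)) + ");"

    tree_nj = read_newick_string(newick_a, "NJ")
    tree_ml = read_newick_string(newick_b, "ML")
    return records, taxonomy, (tree_nj, tree_ml)


def _mutate_bases(bases: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with one of the three other bases, uniformly."""
    out = bases.copy()
    for i in range(len(out)):
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


# ---------------------------------------------------------------------------
# amplicon screening fixtures


def simulate_amplicon(community: PlantedCommunity,
                      representatives: Sequence[SequenceRecord] | Sequence[str],
                      seed: int, *, read_length: int = 250,
                      pident_floor: float = 97.5,
                      decoy_hit_fraction: float = 0.2,
                      ) -> tuple[dict[str, list[TabularHit]], pd.DataFrame,
                                 dict[str, dict[str, int]]]:
    """Simulate per-sample screening hit tables against representative 16S
    sequences.

    Target reads produce hits that pass the best-hit screen (pident >=
    ``pident_floor``, query coverage >= 0.7); a fraction of the background
    reads produce decoy hits that fail it, half via low identity and half via
    low coverage.  Returns (per-sample hits, metadata table, realized target
    read counts per sample and taxon).
    """
    taxa = sorted({t for props in community.proportions.values() for t in props})
    if not taxa:
        raise ValueError("community plants no target taxa")
    rep_ids = [r.id if isinstance(r, SequenceRecord) else str(r)
               for r in representatives]
    slen = {r.id: r.length for r in representatives
            if isinstance(r, SequenceRecord)}
    unknown = set(taxa) - set(rep_ids)
    if unknown:
        raise ValueError(f"community taxa without representatives: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    hits_by_sample: dict[str, list[TabularHit]] = {}
    truth: dict[str, dict[str, int]] = {}
    meta_rows = []
    for sample in sorted(community.environment_of):
        env = community.environment_of[sample]
        total = community.total_reads[sample]
        props = community.proportions.get(sample, {})
        p = [props.get(t, 0.0) for t in taxa]
        p.append(max(0.0, 1.0 - sum(p)))
        counts = rng.multinomial(total, p)
        sample_hits: list[TabularHit] = []
        truth[sample] = {}
        read_no = 0
        for t, c in zip(taxa, counts[:-1]):
            truth[sample][t] = int(c)
            for _ in range(c):
                sample_hits.append(_target_hit(sample, read_no, t, rng,
                                               read_length, pident_floor,
                                               slen.get(t, 1500)))
                read_no += 1
        n_decoys = rng.binomial(counts[-1], decoy_hit_fraction)
        for _ in range(n_decoys):
            sample_hits.append(_decoy_hit(sample, read_no,
                                          taxa[rng.integers(len(taxa))], rng,
                                          read_length))
            read_no += 1
        hits_by_sample[sample] = sample_hits
        meta_rows.append({"sample_id": sample, "environment": env,
                          "latitude": round(float(rng.uniform(-70, 70)), 4),
                          "longitude": round(float(rng.uniform(-180, 180)), 4),
                          "total_reads": total})
    metadata = pd.DataFrame(meta_rows)
    return hits_by_sample, metadata, truth


def _target_hit(sample: str, read_no: int, taxon: str, rng: np.random.Generator,
                read_length: int, pident_floor: float, slen: int) -> TabularHit:
    pident = round(float(rng.uniform(pident_floor, 100.0)), 2)
    length = int(rng.integers(math.ceil(0.7 * read_length), read_length + 1))
    return TabularHit(f"{sample}_r{read_no}", taxon, pident, length,
                      mismatch=int(round(length * (100 - pident) / 100)),
                      gapopen=0, qstart=1, qend=length, sstart=1, send=length,
                      evalue=1e-80, bitscore=float(2 * length),
                      qlen=read_length, slen=slen)


def _decoy_hit(sample: str, read_no: int, taxon: str, rng: np.random.Generator,
               read_length: int) -> TabularHit:
    # fail via identity or via coverage with equal probability, exercising
    # both clauses of the screening filter
    if rng.random() < 0.5:
        pident = round(float(rng.uniform(80.0, 96.9)), 2)
        length = int(rng.integers(math.ceil(0.7 * read_length), read_length + 1))
    else:
        pident = round(float(rng.uniform(97.0, 100.0)), 2)
        length = int(rng.integers(read_length // 4, math.ceil(0.7 * read_length)))
    return TabularHit(f"{sample}_r{read_no}", taxon, pident, max(length, 1),
                      mismatch=int(round(length * (100 - pident) / 100)),
                      gapopen=0, qstart=1, qend=max(length, 1), sstart=1,
                      send=max(length, 1), evalue=1e-20,
                      bitscore=float(max(length, 1)),
                      qlen=read_length, slen=1500)


def simulate_screening_table(n_rows: int, seed: int,
                             min_identity: float = 97.0,
                             min_query_coverage: float = 0.7,
                             ) -> tuple[list[TabularHit],
                                        set[tuple[str, str]]]:
    """A labelled hit table for exercising the best-hit screening filter.

    Queries carry one to three hits each; per query the intended best hit
    (strictly highest bitscore) is planted to either pass or fail the
    identity/coverage filter, and the expected survivor set of (qseqid,
    sseqid) pairs is returned alongside.  Rows are emitted in shuffled order.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be positive")
    rng = np.random.default_rng(seed)
    hits: list[TabularHit] = []
    expected: set[tuple[str, str]] = set()
    qlen = 300
    q = 0
    while len(hits) < n_rows:
        qseqid = f"q{q:06d}"
        q += 1
        n_h = int(rng.integers(1, 4))
        fate = rng.choice(["pass", "fail_identity", "fail_coverage"])
        best_bitscore = float(rng.uniform(200, 400))
        for rank in range(n_h):
            is_best = rank == 0
            if is_best and fate == "pass":
                pident = round(float(rng.uniform(min_identity, 100.0)), 2)
                length = int(rng.integers(
                    math.ceil(min_query_coverage * qlen), qlen + 1))
            elif is_best and fate == "fail_identity":
                pident = round(float(rng.uniform(80.0, min_identity - 0.1)), 2)
                length = int(rng.integers(
                    math.ceil(min_query_coverage * qlen), qlen + 1))
            elif is_best and fate == "fail_coverage":
                pident = round(float(rng.uniform(min_identity, 100.0)), 2)
                length = int(rng.integers(
                    50, math.ceil(min_query_coverage * qlen) - 1))
            else:  # non-best hits: anything goes, strictly lower bitscore
                pident = round(float(rng.uniform(80.0, 100.0)), 2)
                length = int(rng.integers(50, qlen + 1))
            bitscore = best_bitscore if is_best \
                else float(rng.uniform(50, best_bitscore - 1))
            sseqid = f"rep{rng.integers(100):03d}" if not is_best \
                else f"best{q:06d}"
            hits.append(TabularHit(qseqid, sseqid, pident, length, 0, 0, 1,
                                   length, 1, length, 1e-40, bitscore,
                                   qlen, 1500))
            if is_best and fate == "pass":
                expected.add((qseqid, sseqid))
    hits = hits[:n_rows]
    # drop truncated queries whose best hit fell off the end
    kept_queries = {h.qseqid for h in hits}
    expected = {(qs, ss) for qs, ss in expected if qs in kept_queries}
    perm = rng.permutation(len(hits))
    return [hits[i] for i in perm], expected


def planted_similarity_matrix(genus_species_counts: Sequence[int],
                              genomes_per_species: Sequence[int],
                              within_species: float = 97.0,
                              within_genus: float = 75.0,
                              between_genera: float = 55.0,
                              ) -> tuple["SimilarityMatrix",
                                         set[frozenset[str]],
                                         set[frozenset[str]]]:
    """A hierarchical block AAI matrix with planted species/genus structure.

    ``genus_species_counts[i]`` is the number of species in genus ``i``;
    ``genomes_per_species`` lists the genome count of each species in genus
    order.  Returns (matrix, species partition, genus partition).
    """
    from .matrices import SimilarityMatrix

    if sum(genus_species_counts) != len(genomes_per_species):
        raise ValueError("species counts do not match genomes_per_species")
    if not (between_genera < within_genus < within_species <= 100.0):
        raise ValueError("need between < within_genus < within_species")
    ids: list[str] = []
    species_sets: list[frozenset[str]] = []
    genus_sets: list[frozenset[str]] = []
    sp_index = 0
    for g, n_species in enumerate(genus_species_counts):
        genus_members: list[str] = []
        for s in range(n_species):
            members = [f"G{g:02d}S{sp_index:02d}M{m}" for m in
                       range(genomes_per_species[sp_index])]
            sp_index += 1
            species_sets.append(frozenset(members))
            genus_members.extend(members)
            ids.extend(members)
        genus_sets.append(frozenset(genus_members))
    n = len(ids)
    vals = np.full((n, n), between_genera, dtype=float)
    pos = {gid: i for i, gid in enumerate(ids)}
    for genus in genus_sets:
        idx = [pos[g] for g in genus]
        vals[np.ix_(idx, idx)] = within_genus
    for species in species_sets:
        idx = [pos[g] for g in species]
        vals[np.ix_(idx, idx)] = within_species
    np.fill_diagonal(vals, 100.0)
    return (SimilarityMatrix.from_dense(ids, vals, kind="AAI"),
            set(species_sets), set(genus_sets))


# ---------------------------------------------------------------------------
# MAG curation fixtures


def simulate_assembly(n_clean: int, n_depth_contaminants: int,
                      n_taxon_contaminants: int, mean_depth: float, seed: int,
                      *, consensus_taxon: str = "Gemmatimonadota",
                      alien_taxon: str = "Pseudomonadota",
                      depth_sigma: float = 0.1, depth_shift: float = 4.0,
                      read_length: int = 100,
                      ) -> tuple[PlantedAssembly, list[TabularHit], list[TabularHit]]:
    """Simulate one MAG: clean contigs plus planted depth and taxonomy
    contaminants, with the read-mapping and protein-hit tables that encode
    them.

    Clean depths are lognormal around ``mean_depth`` with a sigma small
    enough that a clean contig essentially never leaves the twofold band
    (P < 1e-4 at sigma 0.1); depth contaminants sit at ``depth_shift``-fold
    above/below the mean, alternating.
    """
    if n_clean < 2:
        raise ValueError("need at least 2 clean contigs")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)

    lengths: dict[str, int] = {}
    depth: dict[str, float] = {}
    kind: dict[str, str | None] = {}
    order: list[str] = []

    def add(name: str, d: float, k: str | None) -> None:
        lengths[name] = int(rng.integers(2_000, 8_000))
        n_reads = max(1, round(d * lengths[name] / read_length))
        depth[name] = n_reads * read_length / lengths[name]  # realizable depth
        kind[name] = k
        order.append(name)

    for i in range(n_clean):
        add(f"contig{i:03d}", float(mean_depth * np.exp(rng.normal(0, depth_sigma))),
            None)
    for i in range(n_depth_contaminants):
        shift = depth_shift if i % 2 == 0 else 1.0 / depth_shift
        add(f"depthcont{i:02d}", mean_depth * shift, "depth")
    for i in range(n_taxon_contaminants):
        add(f"taxoncont{i:02d}",
            float(mean_depth * np.exp(rng.normal(0, depth_sigma))), "taxonomy")

    # the twofold rule is applied against the mean over *all* contigs; verify
    # the planted truth is recoverable under that mean before emitting
    all_mean = float(np.mean([depth[c] for c in order]))
    for c in order:
        outside = depth[c] > 2.0 * all_mean or depth[c] < all_mean / 2.0
        if kind[c] == "depth" and not outside:
            raise ValueError("planted depth contaminant falls inside the "
                             "twofold band; reduce contaminant count or raise "
                             "depth_shift")
        if kind[c] != "depth" and outside:
            raise ValueError("clean contig fell outside the twofold band; "
                             "lower depth_sigma")

    read_hits: list[TabularHit] = []
    for c in order:
        n_reads = round(depth[c] * lengths[c] / read_length)
        for i in range(n_reads):
            pident = round(float(rng.uniform(97.0, 100.0)), 2)
            start = int(rng.integers(1, max(2, lengths[c] - read_length)))
            read_hits.append(TabularHit(
                f"{c}_r{i}", c, pident, read_length, mismatch=0, gapopen=0,
                qstart=1, qend=read_length, sstart=start,
                send=start + read_length - 1, evalue=1e-40,
                bitscore=float(2 * read_length), qlen=read_length,
                slen=lengths[c]))
        # junk reads that the 95%/70% filter must discard
        for i in range(int(rng.integers(0, 3))):
            read_hits.append(TabularHit(
                f"{c}_junk{i}", c, round(float(rng.uniform(80, 94.9)), 2),
                read_length, mismatch=10, gapopen=0, qstart=1, qend=read_length,
                sstart=1, send=read_length, evalue=1e-10,
                bitscore=float(read_length), qlen=read_length, slen=lengths[c]))

    protein_hits: list[TabularHit] = []
    protein_taxa: dict[str, tuple[str, ...]] = {}
    for c in order:
        n_prot = max(2, lengths[c] // 2_000)
        taxa = []
        for i in range(n_prot):
            if kind[c] == "taxonomy":
                taxon = alien_taxon
            else:
                # mostly consensus with occasional stray affiliation, but the
                # first protein always votes consensus
                taxon = consensus_taxon if (i == 0 or rng.random() < 0.9) \
                    else alien_taxon
            taxa.append(taxon)
            plen = int(rng.integers(120, 600))
            protein_hits.append(TabularHit(
                f"{c}_p{i}", f"ref_{taxon}_{rng.integers(1_000_000)}",
                round(float(rng.uniform(50, 99)), 2), plen, mismatch=5,
                gapopen=0, qstart=1, qend=plen, sstart=1, send=plen,
                evalue=1e-30, bitscore=float(plen),
                qlen=plen, slen=plen, stitle=f"hypothetical protein [{taxon}]"))
        protein_taxa[c] = tuple(taxa)

    planted = PlantedAssembly(lengths, depth, kind, protein_taxa,
                              consensus_taxon)
    return planted, read_hits, protein_hits


# ---------------------------------------------------------------------------
# functional-annotation fixtures


def simulate_annotations(n_genomes: int,
                         pathway_defs: Mapping[str, Sequence[str]],
                         planted_completeness: Mapping[str, Mapping[str, float]] | np.ndarray,
                         seed: int) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Plant per-pathway gene complements into genome gene inventories.

    Each genome receives ``floor(completeness * |pathway genes|)`` genes of
    each pathway, sampled without replacement.  ``planted_completeness`` is
    either an (n_genomes x n_pathways) array over sorted pathway ids or a
    nested mapping genome -> pathway -> fraction.  Returns (genome -> gene-id
    set, long annotation table).
    """
    pathway_ids = sorted(pathway_defs)
    genomes = [f"genome{i:03d}" for i in range(n_genomes)]
    if isinstance(planted_completeness, np.ndarray):
        mat = np.asarray(planted_completeness, dtype=float)
        if mat.shape != (n_genomes, len(pathway_ids)):
            raise ValueError("completeness matrix shape mismatch")
        planted = {g: {p: float(mat[i, j]) for j, p in enumerate(pathway_ids)}
                   for i, g in enumerate(genomes)}
    else:
        planted = {g: dict(v) for g, v in planted_completeness.items()}
        genomes = sorted(planted)
    rng = np.random.default_rng(seed)
    genome_genes: dict[str, set[str]] = {}
    rows = []
    for g in genomes:
        genes: set[str] = set()
        for p, c in planted[g].items():
            if p not in pathway_defs:
                raise ValueError(f"unknown pathway id {p!r}")
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"completeness {c} outside [0, 1]")
            pool = list(pathway_defs[p])
            n_take = math.floor(c * len(pool))
            take = rng.choice(len(pool), size=n_take, replace=False)
            genes.update(pool[i] for i in take)
        genome_genes[g] = genes
        rows.extend({"genome": g, "gene": f"{g}_cds{k:05d}", "ko": ko}
                    for k, ko in enumerate(sorted(genes)))
    table = pd.DataFrame(rows, columns=["genome", "gene", "ko"])
    return genome_genes, table
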