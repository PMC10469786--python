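"""Pathway presence scoring, module enrichment, CAZyme consensus and group
comparisons.

A pathway is scored present in a genome when at least 80% of its required
genes are detected.  CAZyme family assignments require agreement of two
evidence strategies (an alignment search and a profile search).  Group
comparisons follow the Kruskal-Wallis + pairwise Wilcoxon/Bonferroni recipe,
with groups of 16 samples or fewer excluded.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway/module: its id, display name and required gene identifiers."""

    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has no genes")

    @property
    def size(self) -> int:
        return len(self.genes)


def load_pathway_definitions(path=None) -> dict[str, PathwayDefinition]:
    """Load pathway definitions from a TSV (pathway_id, name, gene_id).

    Without a path the packaged defaults are used: compact KEGG-orthology
    gene lists for the central and respiratory pathways and vitamin
    biosyntheses typically profiled in MAG comparisons.  The tables are data
    and are meant to be edited/extended by the user.
    """
    if path is None:
        ref = importlib.resources.files("magtaxa").joinpath(
            "data/pathway_definitions.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"pathway_id", "name", "gene_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"pathway table missing columns {sorted(missing)}")
    defs = {}
    for pid, grp in df.groupby("pathway_id", sort=True):
        genes = list(grp["gene_id"])
        if len(genes) != len(set(genes)):
            raise ValueError(f"pathway {pid!r}: duplicate gene ids")
        defs[str(pid)] = PathwayDefinition(str(pid), str(grp["name"].iloc[0]),
                                           frozenset(genes))
    return defs


@dataclass(frozen=True)
class PresenceMatrix:
    """Genome x pathway booleans plus the underlying completeness fractions."""

    presence: pd.DataFrame      # bool
    completeness: pd.DataFrame  # fraction of required genes detected
    threshold: float


def pathway_presence(genome_genes: Mapping[str, Iterable[str]],
                     defs: Mapping[str, PathwayDefinition],
                     threshold: float = 0.8) -> PresenceMatrix:
    """Score pathway presence: present iff >= ``threshold`` of the pathway's
    required genes are detected in the genome (80% by default, inclusive)."""
    if not defs:
        raise ValueError("no pathway definitions")
    genomes = sorted(genome_genes)
    pathways = sorted(defs)
    comp = pd.DataFrame(0.0, index=genomes, columns=pathways)
    for g in genomes:
        genes = set(genome_genes[g])
        for p in pathways:
            d = defs[p]
            comp.loc[g, p] = len(genes & d.genes) / d.size
    presence = comp >= threshold
    return PresenceMatrix(presence, comp, threshold)


def enriched_modules(completeness: pd.DataFrame | PresenceMatrix,
                     groups: Mapping[str, str],
                     completion_threshold: float = 0.8,
                     q_max: float = 0.01) -> pd.DataFrame:
    """Modules differentially present between genome groups.

    A module counts as present in a genome when its completeness reaches the
    completion threshold.  Per module a group x present/absent contingency
    table is tested (Fisher's exact test for two groups, chi-square for
    more); q-values are Benjamini-Hochberg, and a module is enriched iff
    q < ``q_max``.  The output also reports per-group prevalence: the percent
    of genomes of each group carrying the module.
    """
    if isinstance(completeness, PresenceMatrix):
        present = completeness.completeness >= completion_threshold
    else:
        if completeness.dtypes.apply(lambda t: t == bool).all():
            present = completeness.astype(bool)
        else:
            present = completeness >= completion_threshold
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    members = {lab: [g for g, l in groups.items()
                     if l == lab and g in present.index]
               for lab in labels}
    for lab, g in members.items():
        if not g:
            raise ValueError(f"group {lab!r} has zero genomes")
    rows = []
    for module in present.columns:
        table = np.array([
            [int(present.loc[members[lab], module].sum()),
             len(members[lab]) - int(present.loc[members[lab], module].sum())]
            for lab in labels])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            p = 1.0  # present everywhere or nowhere: no contrast
        elif len(labels) == 2:
            _, p = stats.fisher_exact(table)
        else:
            _, p, _, _ = stats.chi2_contingency(table)
        row = {"module": module, "p_value": float(p)}
        for lab in labels:
            row[f"prevalence_{lab}"] = (100.0 * present.loc[members[lab],
                                                            module].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = qvals
    out["enriched"] = out["q_value"] < q_max
    return out.set_index("module")


@dataclass(frozen=True)
class HitEvidence:
    """Dual-strategy evidence for one (gene, family) CAZyme assignment.

    Evidence A is an alignment hit (percent identity + query coverage);
    evidence B is a profile hit (e-value + model coverage).  Either side may
    be absent (None).
    """

    gene: str
    family: str
    a_pident: float | None = None
    a_coverage: float | None = None   # alignment length / query length, 0..1
    b_evalue: float | None = None
    b_coverage: float | None = None   # profile coverage of the model, 0..1

    def __post_init__(self) -> None:
        for cov in (self.a_coverage, self.b_coverage):
            if cov is not None and not (0.0 <= cov <= 1.0):
                raise ValueError("coverage fractions must lie in [0, 1]")


def cazyme_consensus(evidence: Iterable[HitEvidence],
                     min_pident_a: float = 40.0, min_cov_a: float = 0.5,
                     max_e_b: float = 1e-15, min_cov_b: float = 0.35,
                     ) -> list[tuple[str, str]]:
    """Accept (gene, family) assignments supported by *both* strategies.

    Evidence A passes with pident > 40 and coverage > 0.5; evidence B with
    e-value < 1e-15 and coverage > 0.35 (all strict).  Both must pass for the
    same (gene, family); evidence rows for the same pair are merged, so the
    two strategies may arrive as separate rows.
    """
    a_pass: set[tuple[str, str]] = set()
    b_pass: set[tuple[str, str]] = set()
    seen: list[tuple[str, str]] = []
    for ev in evidence:
        key = (ev.gene, ev.family)
        if key not in seen:
            seen.append(key)
        if (ev.a_pident is not None and ev.a_coverage is not None
                and ev.a_pident > min_pident_a and ev.a_coverage > min_cov_a):
            a_pass.add(key)
        if (ev.b_evalue is not None and ev.b_coverage is not None
                and ev.b_evalue < max_e_b and ev.b_coverage > min_cov_b):
            b_pass.add(key)
    accepted = a_pass & b_pass
    return [key for key in seen if key in accepted]


def pul_markers(annotations: pd.DataFrame,
                cazyme_column: str = "cazy_family",
                symbol_column: str = "symbol") -> pd.DataFrame:
    """Count polysaccharide-utilization-locus markers per genome.

    Returns one row per genome with the number of accepted CAZymes (genes
    with a non-null CAZy family) and of susC/susD transporter genes (by gene
    symbol, case-insensitive).
    """
    if "genome" not in annotations.columns:
        raise ValueError("annotation table needs a 'genome' column")
    if symbol_column not in annotations.columns:
        raise ValueError(f"annotation table needs a {symbol_column!r} column")
    rows = []
    for genome, grp in annotations.groupby("genome", sort=True):
        if cazyme_column in grp.columns:
            n_caz = int(grp[cazyme_column].notna().sum())
        else:
            n_caz = 0
        symbols = grp[symbol_column].astype(str).str.lower()
        n_suscd = int(symbols.isin({"susc", "susd"}).sum())
        rows.append({"genome": genome, "cazymes": n_caz, "suscd": n_suscd})
    return pd.DataFrame(rows).set_index("genome")


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis omnibus plus pairwise rank-sum tests with Bonferroni."""

    statistic: float
    p_value: float
    groups: tuple[str, ...]
    group_sizes: Mapping[str, int]
    pairwise: pd.DataFrame          # columns: group_a, group_b, p_raw, p_corrected
    excluded_groups: tuple[str, ...]
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_corrected"] < self.alpha]
        return list(zip(sig["group_a"], sig["group_b"]))


def compare_groups(values: Mapping[str, float], groups: Mapping[str, str],
                   min_group_n: int = 17, alpha: float = 0.05,
                   ) -> GroupComparison:
    """Compare a per-sample quantity between groups.

    Only groups with at least ``min_group_n`` samples (i.e. *more than 16*
    with the default) enter the tests.  The omnibus is Kruskal-Wallis; all
    eligible pairs are compared with two-sided Mann-Whitney (Wilcoxon
    rank-sum) tests -- exact null when both groups have n < 50 and no ties,
    as R's wilcox.test does -- and p-values are Bonferroni-corrected over the
    number of pairs.
    """
    by_group: dict[str, list[float]] = {}
    for sample, v in values.items():
        lab = groups.get(sample)
        if lab is not None:
            by_group.setdefault(lab, []).append(float(v))
    eligible = sorted(lab for lab, vals in by_group.items()
                      if len(vals) >= min_group_n)
    excluded = tuple(sorted(set(by_group) - set(eligible)))
    if len(eligible) < 2:
        raise ValueError(
            f"need at least two groups with n >= {min_group_n}; eligible: "
            f"{eligible}, excluded: {list(excluded)}")
    samples = [by_group[lab] for lab in eligible]
    stat, p = stats.kruskal(*samples)
    pairs = list(combinations(range(len(eligible)), 2))
    rows = []
    for i, j in pairs:
        a, b = samples[i], samples[j]
        pooled = a + b
        exact_ok = (len(a) < 50 and len(b) < 50
                    and len(set(pooled)) == len(pooled))
        method = "exact" if exact_ok else "asymptotic"
        _, p_raw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method=method)
        rows.append({"group_a": eligible[i], "group_b": eligible[j],
                     "p_raw": float(p_raw),
                     "p_corrected": min(1.0, float(p_raw) * len(pairs))})
    pairwise = pd.DataFrame(rows)
    return GroupComparison(float(stat), float(p), tuple(eligible),
                           {lab: len(by_group[lab]) for lab in eligible},
                           pairwise, excluded, alpha)
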