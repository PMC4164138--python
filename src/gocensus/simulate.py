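"""Synthetic ontologies, genome annotation sets and HGT lists with known truth.

The generator emulates the statistical structure of a proteome-wide GO
annotation corpus spanning the three superkingdoms: genomes of unequal
size, nested functional repertoires with superkingdom-specific terms,
right-skewed abundance from gene duplication, clade-restricted term loss
(genome streamlining in the Archaea-like clade), late lineage-specific
innovation concentrated in the Eukarya-like clade, and a small minority of
laterally transferred terms registered in HGT-DB-style protein lists.

Everything is deterministic given the seed in :class:`SimulationConfig`,
and the emitted files (OBO, GAF, metadata TSV, HGT lists) round-trip through
the parsers so that every downstream stage can be tested offline against
the recorded :class:`GroundTruth`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .ontology import GoGraph

_TARGET_COVERAGE = 0.70       # annotated fraction for adequate-coverage genomes
_LOW_COVERAGE = 0.35          # annotated fraction for quota'd low-quality genomes
_GAF_DATE = "20090101"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus; all distributional choices live here."""

    n_terms_total: int = 150
    ontology_depth: int = 4
    n_genomes_per_kingdom: tuple[int, int, int] = (8, 10, 6)  # (A, B, E)
    ancestral_repertoire_size: int = 30
    loss_rate_per_clade: float = 0.4
    duplication_mean: float = 1.5
    hgt_term_count: int = 5
    hgt_copy_number: int = 8
    parasite_fraction: float = 0.15
    low_coverage_fraction: float = 0.10
    multi_parent_prob: float = 0.3
    novel_split: tuple[float, float, float] = (0.1, 0.3, 0.6)  # (A, B, E)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms_total < 0 or self.ontology_depth < 0:
            raise ValueError("counts must be non-negative")
        for p in (self.loss_rate_per_clade, self.parasite_fraction,
                  self.low_coverage_fraction, self.multi_parent_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.duplication_mean < 0:
            raise ValueError("duplication_mean must be positive")
        if self.ancestral_repertoire_size > self.n_terms_total:
            raise ValueError("ancestral repertoire larger than the ontology")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests downstream."""

    species_tree: str                       # newick over all genomes
    true_venn_group: dict[str, str]         # term -> A/B/E/AB/AE/BE/ABE
    hgt_terms: set[str]
    reduced_clades: list[tuple[str, set[str]]]
    ancestral_terms: set[str]
    novel_assignments: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    parasites: list[str] = field(default_factory=list)
    low_coverage: list[str] = field(default_factory=list)
    retained_expected: list[str] = field(default_factory=list)
    unobserved_terms: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def generate_ontology(config: SimulationConfig) -> GoGraph:
    """Generate a molecular_function DAG with ``n_terms_total`` terms.

    One root, terms spread over ``ontology_depth`` levels, each non-root
    term with one parent on the level above and, with probability
    ``multi_parent_prob`` (levels >= 2), a second parent.  Deterministic
    given the seed; leaves are the terminal terms downstream stages sample.
    """
    n = config.n_terms_total
    depth = config.ontology_depth
    if n < 3:
        raise ValueError("need at least 3 terms (root plus two children)")
    if depth < 1:
        raise ValueError("ontology depth must be >= 1")
    rng = np.random.default_rng(config.seed)

    ids = [f"GO:{7000000 + i:07d}" for i in range(n)]
    graph = GoGraph()
    graph.add_term(ids[0], "molecular_function", "molecular_function")

    depth = min(depth, n - 1)
    # spread non-root terms over levels 1..depth, each level non-empty
    n_rest = n - 1
    base = n_rest // depth
    sizes = [base + (1 if i < n_rest % depth else 0) for i in range(depth)]
    levels: list[list[str]] = [[ids[0]]]
    cursor = 1
    for lv in range(1, depth + 1):
        level_ids = ids[cursor:cursor + sizes[lv - 1]]
        cursor += sizes[lv - 1]
        for tid in level_ids:
            graph.add_term(tid, f"synthetic activity {tid[-5:]}",
                           "molecular_function")
            parent = levels[lv - 1][int(rng.integers(len(levels[lv - 1])))]
            graph.add_is_a(tid, parent)
            if lv >= 2 and len(levels[lv - 1]) > 1 and \
                    rng.random() < config.multi_parent_prob:
                others = [p for p in levels[lv - 1] if p != parent]
                graph.add_is_a(tid, others[int(rng.integers(len(others)))])
        levels.append(level_ids)
    return graph


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def _pectinate(labels: list[str]) -> str:
    """Newick for a ladder tree: (x1,(x2,(x3,x4)))."""
    if len(labels) == 1:
        return labels[0]
    inner = labels[-1]
    for lab in labels[-2::-1]:
        inner = f"({lab},{inner})"
    return inner


def species_tree_newick(genomes: Mapping[str, list[str]]) -> str:
    """Fixed pectinate backbone with the Archaea-like clade branching first."""
    clades = [_pectinate(genomes[k]) for k in ("A", "B", "E") if genomes[k]]
    if len(clades) == 1:
        return clades[0] + ";"
    inner = clades[-1]
    for c in clades[-2::-1]:
        inner = f"({c},{inner})"
    return inner + ";"


def simulate_genomes(graph: GoGraph, config: SimulationConfig,
                     ) -> tuple[dict[str, AnnotationSet], pd.DataFrame,
                                dict[str, list[str]], GroundTruth]:
    """Evolve term repertoires along the fixed species tree and emit
    annotation sets, organism metadata, HGT protein lists and ground truth.

    The root genome carries an ancestral leaf-term repertoire; the
    Archaea-like clade loses each ancestral term with
    ``loss_rate_per_clade``; the remaining leaf terms are handed out as
    lineage-specific innovations (Eukarya-heavy by default, each confined
    to a clade-shaped suffix of its kingdom's tips); abundances are
    1 + Poisson(duplication_mean); ``hgt_term_count`` terms are copied
    laterally between akaryote tips at amplified copy number and recorded
    in the recipients' HGT lists; parasite and low-coverage labels are
    assigned by deterministic quota.
    """
    nA, nB, nE = config.n_genomes_per_kingdom
    if nA + nB + nE == 0:
        raise ValueError("all three kingdom genome counts are zero")
    from .ontology import terminal_mf_terms
    leaves = sorted(terminal_mf_terms(graph))
    if len(leaves) < config.ancestral_repertoire_size:
        raise ValueError("ontology has fewer leaves than the ancestral repertoire")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    genomes = {"A": [f"A{i+1:03d}" for i in range(nA)],
               "B": [f"B{i+1:03d}" for i in range(nB)],
               "E": [f"E{i+1:03d}" for i in range(nE)]}
    all_genomes = genomes["A"] + genomes["B"] + genomes["E"]
    kingdom_of = {g: k for k in genomes for g in genomes[k]}

    # ancestral repertoire and clade-level loss on the Archaea-like stem
    anc_idx = rng.choice(len(leaves), size=config.ancestral_repertoire_size,
                         replace=False)
    ancestral = sorted(leaves[i] for i in anc_idx)
    lost_A = {t for t in ancestral if rng.random() < config.loss_rate_per_clade}

    # lineage-specific innovations for the remaining leaf terms
    novel = [t for t in leaves if t not in set(ancestral)]
    novel = [novel[i] for i in rng.permutation(len(novel))]
    fA, fB, fE = config.novel_split
    n_novel = len(novel)
    cA = int(round(fA * n_novel))
    cB = int(round(fB * n_novel))
    buckets = (["A"] * cA + ["B"] * cB + ["E"] * (n_novel - cA - cB))
    presence: dict[str, set[str]] = {g: set() for g in all_genomes}
    for g in all_genomes:
        k = kingdom_of[g]
        for t in ancestral:
            if k == "A" and t in lost_A:
                continue
            presence[g].add(t)
    novel_assignments: dict[str, tuple[str, tuple[str, ...]]] = {}
    for term, kingdom in zip(novel, buckets):
        if not genomes[kingdom]:
            kingdom = next(k for k in ("E", "B", "A") if genomes[k])
        tips = genomes[kingdom]
        start = int(rng.integers(0, len(tips)))
        carriers = tuple(tips[start:])  # a nested clade of the pectinate ladder
        novel_assignments[term] = (kingdom, carriers)
        for g in carriers:
            presence[g].add(term)

    # abundances: 1 + Poisson(duplication_mean) per present (genome, term)
    abundance: dict[str, dict[str, int]] = {}
    for g in all_genomes:
        terms = sorted(presence[g])
        extra = rng.poisson(config.duplication_mean, size=len(terms))
        abundance[g] = {t: 1 + int(e) for t, e in zip(terms, extra)}

    # lifestyle and coverage quotas (deterministic counts, seeded placement)
    n_total = len(all_genomes)
    n_par = int(round(config.parasite_fraction * n_total))
    n_low = int(round(config.low_coverage_fraction * n_total))
    perm = [all_genomes[i] for i in rng.permutation(n_total)]
    parasites = sorted(perm[:n_par])
    low_cov = sorted(perm[n_par:n_par + n_low])
    lifestyles = {}
    for i, g in enumerate(parasites):
        lifestyles[g] = "parasite" if i % 2 == 0 else "facultative_parasite"
    retained_expected = [g for g in all_genomes
                         if g not in lifestyles and g not in set(low_cov)]

    # ground-truth Venn groups from pre-HGT presence among retained genomes
    true_group: dict[str, str] = {}
    unobserved: set[str] = set()
    retained_set = set(retained_expected)
    for t in leaves:
        ks = "".join(k for k in ("A", "B", "E")
                     if any(t in presence[g] for g in genomes[k]
                            if g in retained_set))
        if ks:
            true_group[t] = ks
        else:
            unobserved.add(t)

    # lateral transfers between akaryote-like tips, at amplified copy number
    hgt_terms: set[str] = set()
    hgt_transfer: list[tuple[str, str, str]] = []  # (term, donor, recipient)
    akaryote_retained = [g for g in genomes["A"] + genomes["B"]
                         if g in retained_set]
    candidates = [t for t, (k, tips) in novel_assignments.items()
                  if k in ("A", "B") and any(g in retained_set for g in tips)]
    candidates.sort()
    n_hgt = min(config.hgt_term_count, len(candidates))
    if n_hgt > 0 and len(akaryote_retained) >= 2:
        chosen = rng.choice(len(candidates), size=n_hgt, replace=False)
        for i in sorted(int(c) for c in chosen):
            term = candidates[i]
            k, tips = novel_assignments[term]
            donors = [g for g in tips if g in retained_set]
            donor = donors[int(rng.integers(len(donors)))]
            others = [g for g in akaryote_retained
                      if kingdom_of[g] != k and term not in presence[g]]
            if not others:
                others = [g for g in akaryote_retained
                          if g != donor and term not in presence[g]]
            if not others:
                continue
            recipient = others[int(rng.integers(len(others)))]
            abundance[donor][term] = config.hgt_copy_number
            abundance[recipient][term] = config.hgt_copy_number
            presence[recipient].add(term)
            hgt_terms.add(term)
            hgt_transfer.append((term, donor, recipient))

    # annotation records, HGT protein lists, metadata
    annotation_sets: dict[str, AnnotationSet] = {}
    hgt_lists: dict[str, list[str]] = {}
    meta_rows = []
    for g in all_genomes:
        records: list[tuple[str, str, str]] = []
        carriers: dict[str, list[str]] = {}
        counter = 0
        for t in sorted(abundance[g]):
            for _ in range(abundance[g][t]):
                protein = f"{g}_P{counter:05d}"
                counter += 1
                records.append((protein, t, "F"))
                carriers.setdefault(t, []).append(protein)
        target = _LOW_COVERAGE if g in set(low_cov) else _TARGET_COVERAGE
        proteome = max(counter, int(math.ceil(counter / target))) if counter else 0
        annotation_sets[g] = AnnotationSet(organism_id=g, records=records,
                                           proteome_size=proteome)
        meta_rows.append({"organism_id": g, "superkingdom": kingdom_of[g],
                          "lifestyle": lifestyles.get(g, "free_living"),
                          "proteome_size": proteome,
                          "is_type_strain": True})
    for term, _donor, recipient in hgt_transfer:
        recs = [p for p, t, _ in annotation_sets[recipient].records if t == term]
        hgt_lists.setdefault(recipient, []).extend(recs)
    for g in hgt_lists:
        hgt_lists[g] = sorted(hgt_lists[g])

    metadata = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        species_tree=species_tree_newick(genomes),
        true_venn_group=true_group,
        hgt_terms=hgt_terms,
        reduced_clades=[("A", set(lost_A))],
        ancestral_terms=set(ancestral),
        novel_assignments=novel_assignments,
        parasites=parasites,
        low_coverage=low_cov,
        retained_expected=retained_expected,
        unobserved_terms=unobserved,
    )
    return annotation_sets, metadata, hgt_lists, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_gaf(annotation_sets: Mapping[str, AnnotationSet],
              metadata: pd.DataFrame, directory,
              force: bool = False) -> dict[str, str]:
    """Write one GAF 2.1 file (17 tab-separated columns) per genome.

    Refuses to overwrite existing files unless ``force``.  Round-trips
    losslessly through :func:`gocensus.annotations.parse_gaf`.
    """
    if not annotation_sets:
        raise ValueError("no annotation sets to write")
    os.makedirs(directory, exist_ok=True)
    taxon_id = {org: 1000 + i
                for i, org in enumerate(metadata["organism_id"])}
    paths: dict[str, str] = {}
    for org in sorted(annotation_sets):
        path = os.path.join(directory, f"{org}.gaf")
        if os.path.exists(path) and not force:
            raise FileExistsError(f"refusing to overwrite {path} (use force=True)")
        aset = annotation_sets[org]
        with open(path, "w") as fh:
            fh.write("!gaf-version: 2.1\n")
            fh.write(f"!generated-by: gocensus synthetic corpus ({org})\n")
            for protein, term, aspect in aset.records:
                cols = ["SYNT", protein, protein, "", term,
                        "SYNT_REF:0000001", "IEA", "", aspect,
                        "", "", "protein",
                        f"taxon:{taxon_id.get(org, 9999)}",
                        _GAF_DATE, "SYNT", "", ""]
                fh.write("\t".join(cols) + "\n")
        paths[org] = path
    return paths


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def write_hgt_lists(hgt_lists: Mapping[str, list[str]], directory,
                    force: bool = False) -> dict[str, str]:
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for org in sorted(hgt_lists):
        path = os.path.join(directory, f"{org}.hgt.txt")
        if os.path.exists(path) and not force:
            raise FileExistsError(f"refusing to overwrite {path} (use force=True)")
        with open(path, "w") as fh:
            for protein in hgt_lists[org]:
                fh.write(protein + "\n")
        paths[org] = path
    return paths


def exclusive_clade_matrix(n_taxa: int = 15, clade_size: int = 5,
                           n_characters: int = 200, state: int = 25):
    """Character matrix in which one clade owns every informative character.

    The last ``clade_size`` taxa (named like a Eukarya-like clade) share
    ``n_characters`` characters at a high state that every other taxon
    lacks, with no conflicting characters — the textbook situation in which
    a clade should reach full bootstrap support.  Returns the view and the
    clade's taxon labels.
    """
    from .encoding import CharacterMatrixView
    if not 2 <= clade_size <= n_taxa - 2:
        raise ValueError("clade must be a non-trivial subset of the taxa")
    states = np.zeros((n_taxa, n_characters), dtype=int)
    states[n_taxa - clade_size:, :] = state
    labels = ([f"B{i+1:03d}" for i in range(n_taxa - clade_size)]
              + [f"E{i+1:03d}" for i in range(clade_size)])
    view = CharacterMatrixView(labels, [f"g{j}" for j in range(n_characters)],
                               states, "ToL")
    return view, labels[n_taxa - clade_size:]


# ---------------------------------------------------------------------------
# dataset-bookkeeping corpus
# ---------------------------------------------------------------------------

def bookkeeping_corpus(n_archaea: int = 45, n_bacteria: int = 183,
                       n_eukarya: int = 21, n_clean_terms: int = 1924,
                       n_hgt_terms: int = 115, hgt_copies: int = 6,
                       ) -> tuple[GoGraph, dict[str, AnnotationSet],
                                  pd.DataFrame, dict[str, list[str]]]:
    """A deterministic corpus sized like the 2009 free-living GOA census.

    Builds 249 retained genomes (45 Archaea, 183 Bacteria, 21 Eukarya) plus
    organisms that the screen must discard (parasites, facultative
    parasites, low-coverage genomes, non-type strains), and a term
    repertoire in which ``n_hgt_terms`` terms occur exclusively on
    horizontally transferred proteins at ``hgt_copies`` copies — so the
    enrichment test, not an assignment, decides which terms are flagged.
    """
    graph = GoGraph()
    root = "GO:8000000"
    graph.add_term(root, "molecular_function", "molecular_function")
    n_terms = n_clean_terms + n_hgt_terms
    terms = [f"GO:{8000001 + i:07d}" for i in range(n_terms)]
    for t in terms:
        graph.add_term(t, f"synthetic activity {t[-5:]}", "molecular_function")
        graph.add_is_a(t, root)
    clean_terms, hgt_terms = terms[:n_clean_terms], terms[n_clean_terms:]

    retained = ([f"A{i+1:03d}" for i in range(n_archaea)]
                + [f"B{i+1:03d}" for i in range(n_bacteria)]
                + [f"E{i+1:03d}" for i in range(n_eukarya)])
    n_ret = len(retained)
    records: dict[str, list[tuple[str, str, str]]] = {g: [] for g in retained}
    counters = {g: 0 for g in retained}

    def add(org: str, term: str) -> str:
        p = f"{org}_P{counters[org]:05d}"
        counters[org] += 1
        records[org].append((p, term, "F"))
        return p

    for j, term in enumerate(clean_terms):
        for g in {retained[j % n_ret], retained[(j * 7 + 31) % n_ret],
                  retained[(j * 13 + 101) % n_ret]}:
            add(g, term)
    hgt_lists: dict[str, list[str]] = {}
    for j, term in enumerate(hgt_terms):
        host = retained[n_archaea + (j % n_bacteria)]  # a bacterial genome
        proteins = [add(host, term) for _ in range(hgt_copies)]
        hgt_lists.setdefault(host, []).extend(proteins)

    excluded = []
    for i in range(12):
        excluded.append((f"X_par{i+1:02d}", "ABE"[i % 3], "parasite", 1.0, True))
    for i in range(6):
        excluded.append((f"X_fac{i+1:02d}", "ABE"[i % 3],
                         "facultative_parasite", 1.0, True))
    for i in range(8):
        excluded.append((f"X_low{i+1:02d}", "B", "free_living", 0.35, True))
    for i in range(4):
        excluded.append((f"X_str{i+1:02d}", "B", "free_living", 1.0, False))

    annotation_sets: dict[str, AnnotationSet] = {}
    meta_rows = []
    for g in retained:
        n_annot = len({p for p, _, _ in records[g]})
        annotation_sets[g] = AnnotationSet(g, records[g], proteome_size=n_annot)
        meta_rows.append({"organism_id": g, "superkingdom": g[0],
                          "lifestyle": "free_living",
                          "proteome_size": n_annot, "is_type_strain": True})
    for org, kingdom, lifestyle, cov, type_strain in excluded:
        recs = [(f"{org}_P{i:05d}", clean_terms[i], "F") for i in range(5)]
        proteome = int(math.ceil(5 / cov))
        annotation_sets[org] = AnnotationSet(org, recs, proteome_size=proteome)
        meta_rows.append({"organism_id": org, "superkingdom": kingdom,
                          "lifestyle": lifestyle, "proteome_size": proteome,
                          "is_type_strain": type_strain})
    metadata = pd.DataFrame(meta_rows)
    for g in hgt_lists:
        hgt_lists[g] = sorted(hgt_lists[g])
    return graph, annotation_sets, metadata, hgt_lists
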