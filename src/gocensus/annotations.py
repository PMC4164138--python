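"""GAF parsing and organism-level filtering.

Annotation records are read from GAF 2.x files (17 tab-separated columns)
via Biopython's GOA reader.  By default only molecular-function records
(aspect ``F``) are kept and ``NOT``-qualified records are dropped; duplicate
(protein, term) pairs are retained as distinct records because they carry
abundance information downstream.

Organism filtering mirrors a three-rule screen: non-type strains are
deduplicated away, (facultative) parasites are excluded because they coevolve
with hosts, and genomes whose terminal-MF annotation coverage falls below a
threshold (default 50%, inclusive) are dropped as low quality.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio.UniProt import GOA

from .ontology import GoGraph

METADATA_COLUMNS = ["organism_id", "superkingdom", "lifestyle",
                    "proteome_size", "is_type_strain"]
PARASITIC_LIFESTYLES = frozenset({"parasite", "facultative_parasite"})
GAF_COLUMNS = 17


class GafParseError(ValueError):
    """Raised on malformed GAF input; names the offending line."""


@dataclass
class AnnotationSet:
    """Per-organism GO annotations.

    ``records`` is a multiset of (protein_id, go_id, aspect) tuples;
    ``proteome_size`` is the organism's total protein count, which may exceed
    the number of annotated proteins.
    """

    organism_id: str
    records: list[tuple[str, str, str]] = field(default_factory=list)
    proteome_size: int = 0

    def __post_init__(self) -> None:
        n_annotated = len({p for p, _, _ in self.records})
        if self.proteome_size < n_annotated:
            self.proteome_size = n_annotated

    def distinct_proteins(self, terms: set[str] | None = None) -> int:
        if terms is None:
            return len({p for p, _, _ in self.records})
        return len({p for p, t, _ in self.records if t in terms})


def parse_gaf(source: str | IO[str], organism_id: str | None = None,
              aspects: frozenset[str] = frozenset({"F"}),
              proteome_size: int = 0) -> AnnotationSet:
    """Parse a GAF 2.x stream into an :class:`AnnotationSet`.

    Records whose aspect is not in ``aspects`` are skipped, as are records
    carrying a ``NOT`` qualifier.  Rows with a wrong column count raise
    :class:`GafParseError` with the line number.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = organism_id or "unknown"
    else:
        with open(source) as fh:
            text = fh.read()
        name = organism_id or str(source)

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("!"):
            continue
        ncol = line.count("\t") + 1
        if ncol != GAF_COLUMNS:
            raise GafParseError(
                f"line {lineno}: expected {GAF_COLUMNS} tab-separated columns, got {ncol}")

    records: list[tuple[str, str, str]] = []
    for rec in GOA.gafiterator(io.StringIO(text)):
        if any(q.upper().startswith("NOT") for q in rec["Qualifier"] if q):
            continue
        if rec["Aspect"] not in aspects:
            continue
        records.append((rec["DB_Object_ID"], rec["GO_ID"], rec["Aspect"]))
    return AnnotationSet(organism_id=name, records=records,
                         proteome_size=proteome_size)


def load_metadata(source: str | IO[str]) -> pd.DataFrame:
    """Read the organism metadata TSV and normalize dtypes."""
    meta = pd.read_csv(source, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    meta = meta.copy()
    meta["is_type_strain"] = meta["is_type_strain"].astype(bool)
    meta["proteome_size"] = meta["proteome_size"].astype(int)
    return meta


def coverage(annotations: AnnotationSet, terminal_terms: set[str],
             proteome_size: int | None = None) -> float:
    """Fraction of the proteome annotated to terminal MF terms.

    Counts distinct proteins carrying at least one terminal-MF annotation and
    divides by the proteome size.
    """
    size = proteome_size if proteome_size is not None else annotations.proteome_size
    if size <= 0:
        return 0.0
    cov = annotations.distinct_proteins(terminal_terms) / size
    return min(cov, 1.0)


def filter_organisms(metadata: pd.DataFrame,
                     annotation_sets: Mapping[str, AnnotationSet],
                     terminal_terms: set[str],
                     coverage_threshold: float = 0.5,
                     ) -> tuple[list[str], dict[str, float], pd.DataFrame]:
    """Apply the organism screen and report what was excluded and why.

    Rules fire in order: (1) non-type strains, (2) parasitic or facultative
    parasitic lifestyle, (3) terminal-MF coverage below the (inclusive)
    threshold.  Returns the retained organism ids (in metadata order), the
    coverage of every organism, and an exclusion log with the first rule that
    fired per organism.
    """
    if not 0.0 <= coverage_threshold <= 1.0:
        raise ValueError("coverage_threshold must be in [0, 1]")
    meta = metadata.set_index("organism_id", drop=False)
    for org in annotation_sets:
        if org not in meta.index:
            raise KeyError(f"organism {org!r} missing from metadata")

    retained: list[str] = []
    covs: dict[str, float] = {}
    log_rows: list[dict] = []
    for org in meta.index:
        if org not in annotation_sets:
            raise KeyError(f"organism {org!r} has metadata but no annotations")
        row = meta.loc[org]
        cov = coverage(annotation_sets[org], terminal_terms,
                       proteome_size=int(row["proteome_size"]))
        covs[org] = cov
        if not bool(row["is_type_strain"]):
            log_rows.append({"organism_id": org, "rule": "strain",
                             "detail": "non-type strain of its species"})
        elif row["lifestyle"] in PARASITIC_LIFESTYLES:
            log_rows.append({"organism_id": org, "rule": "lifestyle",
                             "detail": str(row["lifestyle"])})
        elif cov < coverage_threshold:
            log_rows.append({"organism_id": org, "rule": "coverage",
                             "detail": f"{cov:.4f} < {coverage_threshold}"})
        else:
            retained.append(org)
    log = pd.DataFrame(log_rows, columns=["organism_id", "rule", "detail"])
    return retained, covs, log


def drop_non_terminal(annotations: AnnotationSet, terminal_terms: set[str],
                      graph: GoGraph | None = None) -> tuple[AnnotationSet, int, int]:
    """Restrict an annotation set to terminal MF terms.

    Annotations to obsolete or non-terminal terms are dropped (never
    propagated up or down the DAG).  Returns the reduced set together with
    the number of obsolete-term and non-terminal records removed.
    """
    kept: list[tuple[str, str, str]] = []
    n_obsolete = n_nonterminal = 0
    for rec in annotations.records:
        term = rec[1]
        if term in terminal_terms:
            kept.append(rec)
        elif graph is not None and term in graph and graph.is_obsolete(term):
            n_obsolete += 1
        else:
            n_nonterminal += 1
    reduced = AnnotationSet(organism_id=annotations.organism_id, records=kept,
                            proteome_size=annotations.proteome_size)
    return reduced, n_obsolete, n_nonterminal


def load_hgt_list(source: str | IO[str]) -> list[str]:
    """Read an HGT-DB-style export: one protein id per line."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def join_htp_records(annotation_sets: Mapping[str, AnnotationSet],
                     hgt_lists: Mapping[str, Iterable[str]],
                     ) -> list[tuple[str, str, str]]:
    """Join per-genome HTP protein lists to their GO annotation records.

    Returns (organism_id, protein_id, go_id) for every annotation record
    whose protein appears on that organism's horizontally-transferred list.
    """
    out: list[tuple[str, str, str]] = []
    for org in sorted(hgt_lists):
        if org not in annotation_sets:
            continue
        htp = set(hgt_lists[org])
        for protein, term, _aspect in annotation_sets[org].records:
            if protein in htp:
                out.append((org, protein, term))
    return out
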