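"""Genome x term abundance census and hypergeometric HGT screening.

The census counts, for every retained genome, how many annotation records
map to each terminal molecular-function term (a protein annotated twice to a
term counts twice — abundance, not presence).  Terms enriched among
horizontally transferred proteins are then flagged with an upper-tail
hypergeometric test, corrected with Benjamini–Hochberg, and excluded from
the matrix before any phylogenetic encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationSet


@dataclass
class CensusMatrix:
    """Abundance table ``data`` (genomes x terms, non-negative ints) with a
    per-genome superkingdom label (``A``, ``B`` or ``E``)."""

    data: pd.DataFrame
    superkingdom: pd.Series

    def __post_init__(self) -> None:
        self.data = self.data.astype(int)
        if (self.data.to_numpy() < 0).any():
            raise ValueError("census abundances must be non-negative")
        self.superkingdom = self.superkingdom.reindex(self.data.index)
        if self.superkingdom.isna().any():
            missing = self.superkingdom[self.superkingdom.isna()].index.tolist()
            raise ValueError(f"genomes without superkingdom label: {missing}")
        bad = set(self.superkingdom.unique()) - {"A", "B", "E"}
        if bad:
            raise ValueError(f"unknown superkingdom labels: {sorted(bad)}")

    @property
    def genomes(self) -> list[str]:
        return list(self.data.index)

    @property
    def terms(self) -> list[str]:
        return list(self.data.columns)

    @property
    def g_max(self) -> int:
        if self.data.size == 0:
            return 0
        return int(self.data.to_numpy().max())

    @property
    def total_annotations(self) -> int:
        return int(self.data.to_numpy().sum())

    def to_tsv(self, path_or_stream) -> None:
        df = self.data.copy()
        df.insert(0, "superkingdom", self.superkingdom)
        df.to_csv(path_or_stream, sep="\t", index_label="organism_id")

    @classmethod
    def from_tsv(cls, source: str | IO[str]) -> "CensusMatrix":
        df = pd.read_csv(source, sep="\t", index_col="organism_id")
        sk = df.pop("superkingdom")
        return cls(data=df, superkingdom=sk)

    def to_mtx(self, path_or_stream) -> None:
        """Sparse triplet (MatrixMarket) export of the abundance grid."""
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix
        mmwrite(path_or_stream, coo_matrix(self.data.to_numpy()))


@dataclass
class HgtTestResult:
    term: str
    k: int        # HTP-borne records of this term
    n_htp: int    # all HTP-borne records
    K: int        # all records of this term
    N: int        # all records
    p_raw: float
    p_adj: float
    flagged: bool


def build_census(annotation_sets: Mapping[str, AnnotationSet],
                 terminal_terms: set[str],
                 retained: Sequence[str],
                 metadata: pd.DataFrame) -> CensusMatrix:
    """Count terminal-MF annotation records per (genome, term).

    Genome order follows ``retained``; term order is lexicographic.  Terms
    with zero counts everywhere are dropped.  Superkingdom labels are taken
    from ``metadata``.
    """
    if len(retained) == 0:
        raise ValueError("no retained organisms: cannot build a census")
    missing = [o for o in retained if o not in annotation_sets]
    if missing:
        raise KeyError(f"retained organisms without annotations: {missing}")

    orgs: list[str] = []
    terms_col: list[str] = []
    for org in retained:
        for _protein, term, _aspect in annotation_sets[org].records:
            if term in terminal_terms:
                orgs.append(org)
                terms_col.append(term)
    if not orgs:
        raise ValueError("no terminal-MF annotations among retained organisms")
    counts = (pd.DataFrame({"organism_id": orgs, "term": terms_col})
              .groupby(["organism_id", "term"]).size().unstack(fill_value=0))
    counts = counts.reindex(index=list(retained), fill_value=0)
    counts = counts[sorted(counts.columns)]
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    sk = metadata.set_index("organism_id")["superkingdom"]
    return CensusMatrix(data=counts, superkingdom=sk.reindex(counts.index))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if not (k <= n <= N and K <= N):
        raise ValueError(f"require 0 <= k <= n <= N and K <= N "
                         f"(got k={k}, K={K}, n={n}, N={N})")
    # sf(k-1) = P(X >= k); exact within float precision
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def flag_hgt_terms(census: CensusMatrix,
                   htp_records: Iterable[tuple[str, str, str]],
                   alpha: float = 0.05,
                   method: str = "fdr_bh") -> list[HgtTestResult]:
    """Test every census term for enrichment among HTP-borne annotations.

    The sampling frame is annotation records: from the N records in the
    census, n are HTP-borne; a term with K records overall and k of them on
    HTPs is scored by the upper-tail hypergeometric probability of observing
    at least k.  P-values are corrected across all tested terms
    (Benjamini–Hochberg by default) and a term is flagged when
    ``p_adj < alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    term_set = set(census.terms)
    genome_set = set(census.genomes)
    N = census.total_annotations
    col_sums = census.data.sum(axis=0)

    k_by_term: dict[str, int] = {t: 0 for t in census.terms}
    n_htp = 0
    for org, _protein, term in htp_records:
        if org not in genome_set:
            raise KeyError(f"HTP record references genome {org!r} absent from census")
        if term in term_set:
            k_by_term[term] += 1
            n_htp += 1

    terms = census.terms
    if n_htp == 0:
        return [HgtTestResult(t, 0, 0, int(col_sums[t]), N, 1.0, 1.0, False)
                for t in terms]

    p_raw = np.array([hypergeom_upper_tail(k_by_term[t], int(col_sums[t]), n_htp, N)
                      for t in terms])
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method=method)
    flagged = p_adj < alpha
    return [HgtTestResult(t, k_by_term[t], n_htp, int(col_sums[t]), N,
                          float(p_raw[i]), float(p_adj[i]), bool(flagged[i]))
            for i, t in enumerate(terms)]


def exclude_terms(census: CensusMatrix, flagged: Iterable[str]) -> CensusMatrix:
    """Drop flagged term columns globally; genome rows are untouched."""
    flagged = set(flagged)
    unknown = flagged - set(census.terms)
    if unknown:
        raise KeyError(f"flagged terms not in census: {sorted(unknown)}")
    keep = [t for t in census.terms if t not in flagged]
    return CensusMatrix(data=census.data[keep].copy(),
                        superkingdom=census.superkingdom.copy())


def hgt_results_to_frame(results: Sequence[HgtTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["term", "k", "n_htp", "K", "N",
                                 "p_raw", "p_adj", "flagged"])
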