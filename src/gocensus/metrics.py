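"""Evolutionary statistics read off the census and the rooted trees.

* ``nd`` (node distance): for each tip of the rooted tree of functions, the
  number of internal nodes strictly between the tip and the root, normalized
  to [0, 1].  It serves as a relative-age proxy: 0 = most ancient
  (basal-most), 1 = most recent.  The default normalization divides by the
  maximum tip-to-root node count, which guarantees the most derived tip sits
  exactly at 1; dividing by the total taxon count (the literal alternative)
  is available behind ``normalization="taxon_count"``.
* ``f`` (distribution index): fraction of sampled genomes encoding a term.
* Venn taxonomic groups: which superkingdoms (A, B, E) a term occurs in,
  giving the seven groups A, B, E, AB, AE, BE, ABE.
* Group appearance: per-group nd minima, quartiles and Tukey 1.5xIQR
  outliers; the appearance order of groups sorts by minimum nd after
  outlier exclusion (an early laterally-acquired term should not set its
  group's appearance time).
* Persistence metrics per genome: economy (distinct terms), flexibility
  (total redundant term count) and robustness (their ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .census import CensusMatrix
from .parsimony import RootedTree

VENN_GROUPS = ("A", "B", "E", "AB", "AE", "BE", "ABE")


def node_distance(tof: RootedTree,
                  normalization: Literal["max_depth", "taxon_count"] = "max_depth",
                  ) -> dict[str, float]:
    """Relative age nd of every tip of a rooted tree.

    Raw distance counts internal nodes strictly between the tip and the
    root; a tip attached directly to the root has raw distance 0.
    """
    tree = tof.tree
    if not tree.is_rooted:
        raise ValueError("node_distance requires a rooted tree")
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("need at least 2 tips")
    raw: dict[str, int] = {}
    for leaf in leaves:
        depth = 0
        node = leaf.parent_node
        while node is not None and node.parent_node is not None:
            depth += 1
            node = node.parent_node
        raw[leaf.taxon.label] = depth
    if normalization == "max_depth":
        denom = max(raw.values())
    elif normalization == "taxon_count":
        denom = len(leaves)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        return {t: 0.0 for t in raw}
    return {t: d / denom for t, d in raw.items()}


def distribution_index(census: CensusMatrix,
                       subset: Sequence[str] | None = None) -> pd.Series:
    """f(term) = genomes (of the subset) with the term, over subset size."""
    if subset is None:
        subset = census.genomes
    subset = list(subset)
    if not subset:
        raise ValueError("empty genome subset")
    missing = set(subset) - set(census.genomes)
    if missing:
        raise KeyError(f"genomes not in census: {sorted(missing)}")
    sub = census.data.loc[subset]
    return (sub > 0).sum(axis=0) / len(subset)


def venn_groups(census: CensusMatrix) -> tuple[pd.Series, dict[str, int]]:
    """Assign each term its Venn taxonomic group and tally group sizes."""
    present = census.data > 0
    if (present.sum(axis=0) == 0).any():
        empty = present.columns[present.sum(axis=0) == 0].tolist()
        raise ValueError(f"terms with no presence in any genome: {empty}")
    groups = {}
    sk = census.superkingdom
    for kingdom in ("A", "B", "E"):
        rows = sk[sk == kingdom].index
        groups[kingdom] = present.loc[rows].any(axis=0) if len(rows) else \
            pd.Series(False, index=present.columns)
    label = pd.Series("", index=present.columns, dtype=object)
    for kingdom in ("A", "B", "E"):  # concatenate in canonical A,B,E order
        label[groups[kingdom]] += kingdom
    sizes = {g: int((label == g).sum()) for g in VENN_GROUPS}
    return label, sizes


def term_evo_records(census: CensusMatrix, nd: Mapping[str, float]) -> pd.DataFrame:
    """Per-term table: nd, global and per-superkingdom f, Venn group."""
    f_global = distribution_index(census)
    label, _sizes = venn_groups(census)
    sk = census.superkingdom
    cols = {"term": census.terms,
            "nd": [nd.get(t, np.nan) for t in census.terms],
            "f_global": f_global.values,
            "venn_group": label.values}
    for kingdom in ("A", "B", "E"):
        rows = sk[sk == kingdom].index.tolist()
        if rows:
            cols[f"f_{kingdom}"] = distribution_index(census, rows).values
        else:
            cols[f"f_{kingdom}"] = np.nan
    return pd.DataFrame(cols)


@dataclass
class GroupSummary:
    group: str
    n_terms: int
    min_nd: float
    q1: float
    median: float
    q3: float
    max_nd: float
    outliers: list[tuple[str, float]]
    min_nd_no_outliers: float


def _tukey_outliers(values: np.ndarray) -> np.ndarray:
    """Boolean mask of 1.5xIQR outliers (linear-interpolation quartiles)."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (values < lo) | (values > hi)


def group_appearance(records: pd.DataFrame,
                     ) -> tuple[list[GroupSummary], list[str], list[str]]:
    """Summarize nd per Venn group and derive the group appearance order.

    Returns per-group summaries plus two appearance orders (groups sorted
    by minimum nd): one ignoring outliers (the headline order) and one on
    the raw minima.  Empty groups are omitted.
    """
    if records["nd"].isna().any():
        raise ValueError("every term needs an nd value")
    summaries: list[GroupSummary] = []
    for group in VENN_GROUPS:
        sub = records[records["venn_group"] == group]
        if sub.empty:
            continue
        vals = sub["nd"].to_numpy(dtype=float)
        mask = _tukey_outliers(vals)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        kept = vals[~mask]
        min_no_out = float(kept.min()) if kept.size else float(vals.min())
        summaries.append(GroupSummary(
            group=group, n_terms=len(sub), min_nd=float(vals.min()),
            q1=float(q1), median=float(med), q3=float(q3),
            max_nd=float(vals.max()),
            outliers=[(t, float(v)) for t, v in
                      zip(sub["term"][mask], vals[mask])],
            min_nd_no_outliers=min_no_out))
    order_no_out = [s.group for s in
                    sorted(summaries, key=lambda s: (s.min_nd_no_outliers, s.group))]
    order_raw = [s.group for s in
                 sorted(summaries, key=lambda s: (s.min_nd, s.group))]
    return summaries, order_no_out, order_raw


def persistence_metrics(census: CensusMatrix) -> pd.DataFrame:
    """Economy, flexibility and robustness per genome.

    economy = number of distinct terms present; flexibility = total
    (redundant) term count; robustness = flexibility / economy.  Genomes
    with zero economy get NaN robustness and a flag.
    """
    if census.data.size == 0:
        raise ValueError("empty census")
    economy = (census.data > 0).sum(axis=1)
    flexibility = census.data.sum(axis=1)
    robustness = flexibility.where(economy > 0) / economy.where(economy > 0)
    return pd.DataFrame({
        "organism_id": census.genomes,
        "superkingdom": census.superkingdom.values,
        "economy": economy.values,
        "flexibility": flexibility.values,
        "robustness": robustness.values,
        "robustness_undefined": (economy == 0).values,
    })


def export_scatter_tables(records: pd.DataFrame,
                          summaries: Sequence[GroupSummary],
                          persistence: pd.DataFrame,
                          directory) -> dict[str, str]:
    """Write the nd-vs-f, boxplot and persistence tables as TSV files.

    Output is deterministically ordered so reruns are byte-identical.
    """
    import os
    os.makedirs(directory, exist_ok=True)
    paths = {}

    nd_f = records.sort_values("term").reset_index(drop=True)
    paths["nd_f"] = os.path.join(directory, "nd_f.tsv")
    nd_f.to_csv(paths["nd_f"], sep="\t", index=False, float_format="%.6f")

    rows = []
    for s in summaries:
        rows.append({"group": s.group, "n_terms": s.n_terms,
                     "min_nd": s.min_nd, "q1": s.q1, "median": s.median,
                     "q3": s.q3, "max_nd": s.max_nd,
                     "min_nd_no_outliers": s.min_nd_no_outliers,
                     "outliers": ";".join(f"{t}:{v:.6f}"
                                          for t, v in sorted(s.outliers))})
    paths["groups"] = os.path.join(directory, "groups.tsv")
    pd.DataFrame(rows).to_csv(paths["groups"], sep="\t", index=False,
                              float_format="%.6f")

    paths["persistence"] = os.path.join(directory, "persistence.tsv")
    persistence.sort_values("organism_id").to_csv(
        paths["persistence"], sep="\t", index=False, float_format="%.6f")
    return paths
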