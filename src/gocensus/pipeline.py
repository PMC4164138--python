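"""End-to-end orchestration: annotations -> census -> trees -> metrics.

The pipeline runs the stages in the method's canonical order — organism
filtering, abundance census, HGT-term exclusion, 32-state encoding, maximum
parsimony with dual ancestral polarity (ToF rooted on the all-V ancestor,
ToL on the all-0 ancestor), bootstrap, then the evolutionary metrics — and
records every exclusion and tie in an audit manifest.  Each stage reads its
inputs from files written by the previous stage, so any stage can be rerun
alone, and one seed controls synthesis, search and bootstrap.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import (filter_organisms, join_htp_records, load_hgt_list,
                          load_metadata, parse_gaf)
from .census import (CensusMatrix, build_census, exclude_terms,
                     flag_hgt_terms, hgt_results_to_frame)
from .encoding import encode, orient, write_nexus
from .metrics import (export_scatter_tables, group_appearance, node_distance,
                      persistence_metrics, term_evo_records, venn_groups)
from .ontology import parse_obo, terminal_mf_terms, write_obo
from .parsimony import ParsimonyModel, write_newick
from .simulate import (SimulationConfig, simulate_genomes, generate_ontology,
                       write_gaf, write_hgt_lists, write_metadata)

ALL_STAGES = ("inputs", "filter", "census", "hgt", "encode", "trees", "metrics")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One configuration drives the whole analysis reproducibly."""

    # exactly one input mode: real files, or a synthetic corpus
    obo_path: str | None = None
    gaf_dir: str | None = None
    metadata_path: str | None = None
    hgt_dir: str | None = None
    synthetic: SimulationConfig | None = None

    coverage_threshold: float = 0.5
    alpha: float = 0.05
    cost_kind: str = "ordered"
    n_starts: int = 10
    use_spr: bool = True
    n_bootstrap: int = 1000
    bootstrap_starts: int = 2
    nd_normalization: str = "max_depth"
    output_dir: str = "gocensus_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None and not isinstance(d["synthetic"],
                                                             SimulationConfig):
            syn = dict(d["synthetic"])
            for key in ("n_genomes_per_kingdom", "novel_split"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = SimulationConfig(**syn)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # identical analyses in different dirs match
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate(config: PipelineConfig) -> list[str]:
    """Return the list of problems that would prevent :func:`run`."""
    problems: list[str] = []
    real = [config.obo_path, config.gaf_dir, config.metadata_path]
    has_real = any(p is not None for p in real)
    has_syn = config.synthetic is not None
    if has_real and has_syn:
        problems.append("both real input paths and a synthetic config given; "
                        "choose one")
    if not has_real and not has_syn:
        problems.append("no inputs: give obo/gaf/metadata paths or a "
                        "synthetic config")
    if has_real and not all(p is not None for p in real):
        problems.append("real mode needs obo_path, gaf_dir and metadata_path")
    if not 0.0 <= config.coverage_threshold <= 1.0:
        problems.append(f"coverage_threshold {config.coverage_threshold} "
                        "outside [0, 1]")
    if not 0.0 < config.alpha < 1.0:
        problems.append(f"alpha {config.alpha} outside (0, 1)")
    if config.cost_kind not in ("ordered", "unordered"):
        problems.append(f"unknown cost model {config.cost_kind!r}")
    if config.nd_normalization not in ("max_depth", "taxon_count"):
        problems.append(f"unknown nd normalization {config.nd_normalization!r}")
    if config.n_bootstrap < 0 or config.n_starts < 1:
        problems.append("n_bootstrap must be >= 0 and n_starts >= 1")
    return problems


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Runner:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = config.output_dir
        os.makedirs(self.out, exist_ok=True)
        self.artifacts: dict[str, str] = {}
        self.warnings: list[str] = []
        self.counts: dict[str, int] = {}

    def path(self, name: str) -> str:
        return os.path.join(self.out, name)

    def record(self, key: str, name: str) -> str:
        self.artifacts[key] = name
        return self.path(name)

    # -- stages -----------------------------------------------------------
    def stage_inputs(self) -> None:
        cfg = self.config
        if cfg.synthetic is None:
            return  # real mode: inputs already on disk
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        graph = generate_ontology(syn)
        sets, metadata, hgt_lists, truth = simulate_genomes(graph, syn)
        indir = self.path("inputs")
        os.makedirs(indir, exist_ok=True)
        write_obo(graph, os.path.join(indir, "ontology.obo"))
        write_gaf(sets, metadata, os.path.join(indir, "gaf"), force=True)
        write_metadata(metadata, os.path.join(indir, "metadata.tsv"))
        write_hgt_lists(hgt_lists, os.path.join(indir, "hgt"), force=True)
        with open(os.path.join(indir, "ground_truth.json"), "w") as fh:
            json.dump({"species_tree": truth.species_tree,
                       "true_venn_group": truth.true_venn_group,
                       "hgt_terms": sorted(truth.hgt_terms),
                       "ancestral_terms": sorted(truth.ancestral_terms),
                       "reduced_clades": [[c, sorted(s)] for c, s in
                                          truth.reduced_clades]},
                      fh, indent=1, sort_keys=True)
        self.artifacts["inputs"] = "inputs"

    def _input_paths(self) -> tuple[str, str, str, str | None]:
        cfg = self.config
        if cfg.synthetic is not None:
            indir = self.path("inputs")
            return (os.path.join(indir, "ontology.obo"),
                    os.path.join(indir, "gaf"),
                    os.path.join(indir, "metadata.tsv"),
                    os.path.join(indir, "hgt"))
        return cfg.obo_path, cfg.gaf_dir, cfg.metadata_path, cfg.hgt_dir

    def stage_filter(self) -> None:
        obo, gaf_dir, meta_path, _ = self._input_paths()
        graph = parse_obo(obo)
        terminal = terminal_mf_terms(graph)
        metadata = load_metadata(meta_path)
        sets = {}
        for fn in sorted(os.listdir(gaf_dir)):
            if fn.endswith(".gaf"):
                org = fn[:-4]
                sets[org] = parse_gaf(os.path.join(gaf_dir, fn),
                                      organism_id=org)
        retained, covs, log = filter_organisms(
            metadata, sets, terminal,
            coverage_threshold=self.config.coverage_threshold)
        log.to_csv(self.record("exclusions", "exclusions.tsv"),
                   sep="\t", index=False)
        pd.DataFrame({"organism_id": list(covs),
                      "coverage": [covs[o] for o in covs],
                      "retained": [o in set(retained) for o in covs]}
                     ).to_csv(self.record("coverage", "coverage.tsv"),
                              sep="\t", index=False, float_format="%.6f")
        with open(self.record("retained", "retained.txt"), "w") as fh:
            fh.write("\n".join(retained) + "\n")
        self.counts["n_retained"] = len(retained)
        self.counts["n_excluded"] = len(log)
        self._terminal = terminal
        self._metadata = metadata
        self._sets = sets
        self._retained = retained

    def stage_census(self) -> None:
        census = build_census(self._sets, self._terminal, self._retained,
                              self._metadata)
        census.to_tsv(self.record("census", "census.tsv"))
        self.counts["n_terms_detected"] = len(census.terms)

    def stage_hgt(self) -> None:
        census = CensusMatrix.from_tsv(self.path("census.tsv"))
        _, _, _, hgt_dir = self._input_paths()
        hgt_lists = {}
        if hgt_dir is not None and os.path.isdir(hgt_dir):
            for fn in sorted(os.listdir(hgt_dir)):
                if fn.endswith(".hgt.txt"):
                    org = fn[:-len(".hgt.txt")]
                    if org in census.data.index:
                        hgt_lists[org] = load_hgt_list(os.path.join(hgt_dir, fn))
        htp = join_htp_records(self._sets, hgt_lists)
        results = flag_hgt_terms(census, htp, alpha=self.config.alpha)
        hgt_results_to_frame(results).to_csv(
            self.record("hgt_flags", "hgt_flags.tsv"), sep="\t", index=False,
            float_format="%.6g")
        flagged = [r.term for r in results if r.flagged]
        final = exclude_terms(census, flagged)
        if len(final.terms) == 0:
            raise PipelineError("hgt", "every term was flagged; nothing left")
        final.to_tsv(self.record("census_final", "census_final.tsv"))
        self.counts["n_terms_flagged"] = len(flagged)
        self.counts["n_terms_final"] = len(final.terms)

    def stage_encode(self) -> None:
        census = CensusMatrix.from_tsv(self.path("census_final.tsv"))
        encoded = encode(census)
        encoded.to_tsv(self.record("encoded", "encoded.tsv"))
        for target, polarity, name in (("ToF", "max", "tof.nex"),
                                       ("ToL", "min", "tol.nex")):
            view = orient(encoded, target)
            with open(self.record(name.split(".")[0] + "_nexus", name), "w") as fh:
                fh.write(write_nexus(view, polarity))
        self.counts["g_max"] = census.g_max

    def stage_trees(self) -> None:
        cfg = self.config
        census = CensusMatrix.from_tsv(self.path("census_final.tsv"))
        encoded = encode(census)
        ss = np.random.SeedSequence([cfg.seed, 2])
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)]
        summaries = []
        self._tree_results = {}
        for target, anc, name, seed in (("ToF", 31, "tof", seeds[0]),
                                        ("ToL", 0, "tol", seeds[1])):
            model = ParsimonyModel(orient(encoded, target), cost=cfg.cost_kind,
                                   n_starts=cfg.n_starts, use_spr=cfg.use_spr)
            res = model.fit(seed=seed, ancestral_state=anc,
                            n_bootstrap=cfg.n_bootstrap,
                            bootstrap_starts=cfg.bootstrap_starts)
            with open(self.record(name + "_tree", name + ".nwk"), "w") as fh:
                fh.write(write_newick(res.tree))
            summaries.append(res.summary())
            if res.tree.root_tie:
                self.warnings.append(f"{target}: Lundberg root placement tied")
            if res.search.tied:
                self.warnings.append(
                    f"{target}: {len(res.search.topologies)} equally "
                    "parsimonious topologies; canonical tree reported")
            self.counts[f"{name}_length"] = res.best_length
            self._tree_results[target] = res
        with open(self.record("tree_summary", "trees_summary.txt"), "w") as fh:
            fh.write("\n\n".join(summaries) + "\n")

    def stage_metrics(self) -> None:
        cfg = self.config
        census = CensusMatrix.from_tsv(self.path("census_final.tsv"))
        if hasattr(self, "_tree_results"):
            tof = self._tree_results["ToF"].tree
        else:  # rerun in isolation: reload the tree written by 'trees'
            import dendropy

            from .parsimony import RootedTree
            dtree = dendropy.Tree.get(path=self.path("tof.nwk"),
                                      schema="newick",
                                      preserve_underscores=True)
            dtree.is_rooted = True
            tof = RootedTree(tree=dtree,
                             taxa=tuple(sorted(census.terms)), length=0)
        nd = node_distance(tof, normalization=cfg.nd_normalization)
        records = term_evo_records(census, nd)
        _, sizes = venn_groups(census)
        pd.DataFrame({"group": list(sizes), "n_terms": list(sizes.values())}
                     ).to_csv(self.record("venn", "venn.tsv"),
                              sep="\t", index=False)
        summaries, order, order_raw = group_appearance(records)
        persistence = persistence_metrics(census)
        paths = export_scatter_tables(records, summaries, persistence, self.out)
        for key, p in paths.items():
            self.artifacts[key] = os.path.basename(p)
        with open(self.record("appearance", "appearance_order.txt"), "w") as fh:
            fh.write("appearance_order_no_outliers\t" + ",".join(order) + "\n")
            fh.write("appearance_order_raw\t" + ",".join(order_raw) + "\n")

    # -- driver -----------------------------------------------------------
    def run(self, stages=None) -> dict:
        cfg = self.config
        problems = validate(cfg)
        if problems:
            raise PipelineError("validate", "; ".join(problems))
        stages = list(stages or ALL_STAGES)
        fns = {"inputs": self.stage_inputs, "filter": self.stage_filter,
               "census": self.stage_census, "hgt": self.stage_hgt,
               "encode": self.stage_encode, "trees": self.stage_trees,
               "metrics": self.stage_metrics}
        # these stages need the in-memory products of 'filter'
        if any(s in stages for s in ("census", "hgt", "trees")):
            for dep in ("inputs", "filter"):
                if dep not in stages:
                    stages.insert(0, dep)
        order = [s for s in ALL_STAGES if s in stages]
        for stage in order:
            try:
                fns[stage]()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "stages": order,
            "counts": self.counts,
            "warnings": sorted(self.warnings),
            "errors": 0,
            "artifacts": {},
        }
        for key in sorted(self.artifacts):
            rel = self.artifacts[key]
            full = self.path(rel)
            if os.path.isfile(full):
                manifest["artifacts"][key] = {"path": rel,
                                              "sha256": _sha256(full)}
            else:
                manifest["artifacts"][key] = {"path": rel, "sha256": "dir"}
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


def run(config: PipelineConfig, stages=None) -> dict:
    """Run the pipeline (or a suffix of it); returns the manifest."""
    return _Runner(config).run(stages)
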