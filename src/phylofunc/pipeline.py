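"""Whole-run orchestration: simulate/read -> QC -> diversity -> gene
inference -> QC -> association -> summary, with one config, one seed and
a manifest of everything produced.

The stage order mirrors the analysis narrative: community composition
first, its ecology, then the inferred functional profile, and finally
the association of both feature kinds with the metadata — so the
"fraction of functional features vs fraction of clades significant"
contrast is a first-class output of every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import io as pfio
from .association import BoostedLinearAssociation
from .config import RunConfig
from .containers import FeatureTable, MetadataTable, ValidationError, align
from .ecology import alpha_diversity
from .inference import GeneContentInferrer
from .phylogeny import read_annotated_tree
from .qc import QCPipeline

logger = logging.getLogger(__name__)


@dataclass
class StageRecord:
    name: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    started: float
    finished: float


@dataclass
class RunManifest:
    """Ordered record of stages, file digests and the config snapshot."""

    config: RunConfig
    stages: list[StageRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.to_dict(),
                "stages": [
                    {
                        "name": s.name,
                        "inputs": s.inputs,
                        "outputs": s.outputs,
                        "started": s.started,
                        "finished": s.finished,
                    }
                    for s in self.stages
                ],
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def round_half_up(value: float, digits: int = 1) -> float:
    """Half-away-from-zero rounding for reported percentages."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def report_summary(
    results_by_kind: dict[str, pd.DataFrame],
    tested_by_kind: dict[str, int],
    q_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per feature kind: features tested, features with min q below the
    threshold, and the percentage to one decimal."""
    if not results_by_kind:
        raise ValidationError("no result tables to summarize")
    rows = []
    for kind, results in results_by_kind.items():
        n_tested = tested_by_kind[kind]
        if len(results):
            n_sig = int(
                results.loc[results["q"] < q_threshold, "feature"].nunique()
            )
        else:
            n_sig = 0
        pct = round_half_up(100.0 * n_sig / n_tested, 1) if n_tested else float("nan")
        rows.append(
            {
                "feature_kind": kind,
                "n_features_tested": n_tested,
                "n_significant": n_sig,
                "percent_significant": pct,
            }
        )
    return pd.DataFrame(rows)


def run_all(
    config: RunConfig,
    out_dir: str | Path,
    *,
    features_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    metadata_types: dict[str, str] | None = None,
    tree_path: str | Path | None = None,
    genome_ko_path: str | Path | None = None,
    taxonomy: dict | None = None,
    gene_set_map_path: str | Path | None = None,
    preset: str | None = None,
    n_samples: int = 200,
    n_features: int = 50,
) -> RunManifest:
    """Execute the full pipeline into ``out_dir``; returns the manifest.

    Either pass input paths, or a synthetic ``preset`` (``assoc-null``,
    ``assoc-planted``, ``inference-toy``) generated from the config
    seed.  Input files are validated up front: a missing or unreadable
    input fails the run before any stage executes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config)
    for p in (features_path, metadata_path, tree_path, genome_ko_path,
              gene_set_map_path):
        if p is not None and not Path(p).is_file():
            raise ValidationError(f"input file not found: {p}")

    def stage(name, inputs, fn):
        t0 = time.time()
        outputs = fn()
        manifest.stages.append(
            StageRecord(
                name=name,
                inputs={str(k): file_digest(k) for k in inputs if k},
                outputs={str(p): file_digest(p) for p in outputs},
                started=t0,
                finished=time.time(),
            )
        )

    state: dict = {}

    def load():
        if preset is not None:
            from . import synth

            meta = synth.generate_metadata(n_samples, seed=config.seed)
            ref = synth.generate_annotated_tree(n_features, 40, seed=config.seed)
            leaf_ids = ref.phylogeny.leaf_names
            effects = []
            if preset == "assoc-planted":
                # plant on the median-baseline phylotype so the effect sits
                # above the low-abundance floor
                probe, _ = synth.generate_communities(
                    meta, n_features, seed=config.seed, feature_ids=leaf_ids
                )
                med = probe.data.mean().sort_values().index[n_features // 2]
                effects = [synth.PlantedEffect(med, "disease", 0.3, "CD")]
            elif preset not in ("assoc-null", "inference-toy"):
                raise ValidationError(f"unknown preset {preset!r}")
            # phylotypes are the reference-tree leaves, so the same table
            # feeds both the taxon-level association and gene inference
            feats, truth = synth.generate_communities(
                meta, n_features, effects, seed=config.seed, feature_ids=leaf_ids
            )
            state["reference"] = ref
            state["features"], state["meta"] = feats, meta
            state["truth"] = truth
            pfio.write_feature_table(feats, out / "features.tsv", config=config)
            pfio.write_metadata(meta, out / "metadata.tsv", config=config)
            (out / "tree.nwk").write_text(ref.newick)
            from .phylogeny import write_genome_ko

            write_genome_ko(ref.phylogeny.ko_table, out / "genome_ko.tsv")
            pfio.write_table(truth.to_frame(), out / "truth.tsv",
                             index_label="row", config=config)
            return [out / "features.tsv", out / "metadata.tsv", out / "tree.nwk",
                    out / "genome_ko.tsv", out / "truth.tsv"]
        state["features"] = pfio.read_feature_table(features_path)
        if metadata_types is None:
            raise ValidationError("metadata_types required when reading metadata")
        state["meta"] = pfio.read_metadata(metadata_path, metadata_types)
        if tree_path is not None:
            state["phylogeny"] = read_annotated_tree(tree_path, genome_ko_path)
        return []

    stage("load", [features_path, metadata_path], load)

    def qc_taxa():
        feats, meta = align(state["features"], state["meta"])
        qc = QCPipeline.from_config(config)
        state["features_qc"], state["meta_qc"] = qc.fit_transform(feats, meta)
        manifest.warnings.extend(qc.report_.warnings)
        pfio.write_table(qc.report_.to_frame(), out / "qc_report_taxa.tsv",
                         index_label="row", config=config)
        pfio.write_feature_table(state["features_qc"], out / "features_qc.tsv",
                                 config=config)
        return [out / "qc_report_taxa.tsv", out / "features_qc.tsv"]

    stage("qc_taxa", [], qc_taxa)

    def diversity():
        div = alpha_diversity(state["features"])
        pfio.write_table(div, out / "diversity.tsv", index_label="sample",
                         config=config)
        state["diversity"] = div
        return [out / "diversity.tsv"]

    stage("diversity", [], diversity)

    have_tree = preset is not None or tree_path is not None

    if have_tree:

        def infer():
            if preset is not None:
                ref = state["reference"]
                inferrer = GeneContentInferrer().fit(ref.phylogeny)
                taxa = state["features"]
            else:
                inferrer = GeneContentInferrer().fit(state["phylogeny"], taxonomy)
                taxa = state["features"]
            ko = inferrer.transform(taxa)
            state["ko_table"] = ko
            pfio.write_feature_table(ko, out / "ko_table.tsv", config=config)
            pfio.write_table(inferrer.mapping_.to_frame(), out / "clade_mapping.tsv",
                             index_label="row", config=config)
            return [out / "ko_table.tsv", out / "clade_mapping.tsv"]

        stage("infer_genes", [tree_path, genome_ko_path], infer)

        def qc_genes():
            ko, meta = align(state["ko_table"], state["meta"])
            qc = QCPipeline.from_config(config)
            state["ko_qc"], _ = qc.fit_transform(ko, meta)
            pfio.write_table(qc.report_.to_frame(), out / "qc_report_genes.tsv",
                             index_label="row", config=config)
            return [out / "qc_report_genes.tsv"]

        stage("qc_genes", [], qc_genes)

    def associate():
        results_by_kind: dict[str, pd.DataFrame] = {}
        tested: dict[str, int] = {}
        tables = [("taxon", state["features_qc"])]
        if "ko_qc" in state:
            tables.append(("gene", state["ko_qc"]))
        outputs = []
        for kind, table in tables:
            est = BoostedLinearAssociation(config=config).fit(table, state["meta_qc"])
            results_by_kind[kind] = est.results_
            tested[kind] = int(est.summary_["n_features_tested"].iloc[0])
            path = out / f"associations_{kind}.tsv"
            pfio.write_table(est.results_, path, index_label="row", config=config)
            outputs.append(path)
        summary = report_summary(results_by_kind, tested, config.q_threshold)
        pfio.write_table(summary, out / "summary.tsv", index_label="row",
                         config=config)
        state["summary"] = summary
        return outputs + [out / "summary.tsv"]

    stage("associate", [], associate)

    manifest.write(out / "manifest.json")
    logger.info("run complete: %d stages", len(manifest.stages))
    return manifest
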