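"""End-to-end orchestration with file handoff between stages.

Every stage reads its inputs from files and writes its outputs to files so
stages can run independently (and be replaced in tests); ``run_all`` wires
them together and emits a run manifest, the funnel trace and the final
target report.  All JSON bodies are deterministic (sorted keys, no
timestamps), so a fixed config + master seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import ClusterModel, cluster_layer, pca_qc
from .core import (
    DrugTargetTable,
    GeneSetCollection,
    IdMap,
    Layer,
    OmicsFunnelError,
    OmicsMatrix,
    PipelineConfig,
)
from .differential import DifferentialResult, prepare_layer, run_de_layer
from .enrichment import enrich_list, map_to_genes, multi_list_links
from .io import (
    logger,
    read_drug_table,
    read_gmt,
    read_idmap,
    read_matrix,
    write_json,
)
from .prioritize import LAYERS, build_report, overlap_pathways, run_funnel, venn_counts
from .simulate import SimulationTruth, truth_recovery_report


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str]
    stages: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "input_digests": self.input_digests,
            "stages": self.stages,
        }


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class InputPaths:
    rna: Path
    protein: Path
    phospho: Path
    sample_sheet: Path
    gene_sets: Path
    idmap: Path
    drug_table: Path

    @classmethod
    def from_dir(cls, d: str | Path) -> "InputPaths":
        d = Path(d)
        return cls(
            rna=d / "rna_counts.tsv",
            protein=d / "protein_log2.tsv",
            phospho=d / "phospho_log2.tsv",
            sample_sheet=d / "sample_sheet.tsv",
            gene_sets=d / "gene_sets.gmt",
            idmap=d / "idmap.tsv",
            drug_table=d / "drug_table.tsv",
        )

    def as_dict(self) -> dict[str, Path]:
        return {
            "rna": self.rna,
            "protein": self.protein,
            "phospho": self.phospho,
            "sample_sheet": self.sample_sheet,
            "gene_sets": self.gene_sets,
            "idmap": self.idmap,
            "drug_table": self.drug_table,
        }


def load_inputs(paths: InputPaths):
    matrices = {
        Layer.RNA: read_matrix(paths.rna, Layer.RNA, paths.sample_sheet),
        Layer.PROTEIN: read_matrix(paths.protein, Layer.PROTEIN, paths.sample_sheet),
        Layer.PHOSPHO: read_matrix(paths.phospho, Layer.PHOSPHO, paths.sample_sheet),
    }
    collection = read_gmt(paths.gene_sets)
    idmap = read_idmap(paths.idmap)
    drugs = read_drug_table(paths.drug_table)
    return matrices, collection, idmap, drugs


def run_all(
    paths: InputPaths,
    design,
    cfg: PipelineConfig,
    out_dir: str | Path,
    truth: SimulationTruth | None = None,
    pairwise: bool = True,
) -> dict:
    """Run every stage on the given inputs and write all outputs.

    Returns the final report dict.  ``truth`` (from a simulated fixture)
    adds recovery metrics to the report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg.to_dict(),
        seed=cfg.seed,
        version=__version__,
        input_digests={k: file_digest(p) for k, p in paths.as_dict().items()},
    )

    matrices, collection, idmap, drugs = load_inputs(paths)
    manifest.stages["load"] = True

    # QC: per-layer PCA scores and shared-feature Venn regions
    qc = {}
    for layer, m in matrices.items():
        pca = pca_qc(m)
        pca.scores.to_csv(out / f"pca_{layer.value}.tsv", sep="\t")
        qc[layer.value] = {
            "variance_explained": list(pca.variance_explained),
            "n_features": m.n_features,
            "n_samples": m.n_samples,
        }
    gene_sets_by_layer = {
        layer.value: map_to_genes(m.feature_ids, layer, idmap).genes
        for layer, m in matrices.items()
    }
    venn = venn_counts(gene_sets_by_layer)
    write_json({"qc": qc, "venn_genes": venn}, out / "qc.json")
    manifest.stages["qc"] = True

    # stage D: per-layer differential calling
    de: dict[Layer, DifferentialResult] = {}
    for layer, m in matrices.items():
        norm = prepare_layer(m)
        res = run_de_layer(norm, design, cfg, pairwise=pairwise)
        res.to_tsv(out / f"de_{layer.value}.tsv")
        de[layer] = res
    manifest.stages["differential"] = True

    # stage C: trend clustering of the differential features
    clusters: dict[Layer, ClusterModel] = {}
    for layer in LAYERS:
        cm = cluster_layer(de[layer], design, cfg)
        cm.write_tsv(
            out / f"centroids_{layer.value}.tsv",
            out / f"memberships_{layer.value}.tsv",
            out / f"trend_labels_{layer.value}.tsv",
        )
        clusters[layer] = cm
    manifest.stages["clustering"] = True

    # enrichment: per trend-direction union lists (and per-cluster tables)
    enr_by_dir: dict[str, dict[Layer, list]] = {"up": {}, "down": {}}
    links_lists: dict[str, set[str]] = {}
    for layer in LAYERS:
        universe = gene_sets_by_layer[layer.value]
        cores = clusters[layer].core_members
        for k, feats in cores.items():
            genes = map_to_genes(feats, layer, idmap).genes
            res = enrich_list(genes, collection, universe, cfg,
                              list_name=f"{layer.value}_c{k}", layer=layer)
            res.to_tsv(out / f"enrichment_{layer.value}_cluster{k}.tsv")
        for direction in ("up", "down"):
            feats = clusters[layer].core_features_with_label(direction)
            genes = map_to_genes(feats, layer, idmap).genes
            res = enrich_list(genes, collection, universe, cfg,
                              list_name=f"{layer.value}_{direction}", layer=layer)
            res.to_tsv(out / f"enrichment_{layer.value}_{direction}.tsv")
            enr_by_dir[direction][layer] = [res]
            if direction == "up":
                links_lists[layer.value] = genes
    links = multi_list_links(links_lists, collection)
    links.to_edge_frame().to_csv(out / "links_up.tsv", sep="\t", index=False)
    manifest.stages["enrichment"] = True

    # stage P + funnel for both directions (drug screen on "up" only)
    reports = {}
    for direction in ("up", "down"):
        integrated = overlap_pathways(enr_by_dir[direction], cfg)
        rows = [
            "\t".join(
                [
                    ip.set_id,
                    f"{ip.p_rna:.6g}",
                    f"{ip.p_protein:.6g}",
                    f"{ip.p_phospho:.6g}",
                    f"{ip.weighted_p:.6g}",
                    str(ip.rank),
                ]
            )
            for ip in integrated
        ]
        header = "set_id\tp_rna\tp_protein\tp_phospho\tweighted_p\trank"
        (out / f"integrated_pathways_{direction}.tsv").write_text(
            "\n".join([header, *rows]) + "\n"
        )
        trace = run_funnel(de, clusters, integrated, collection, idmap, drugs,
                           cfg, direction=direction)
        write_json(trace.to_dict(), out / f"funnel_trace_{direction}.json")
        report = build_report(trace, cfg, truth=truth)
        write_json(report, out / f"report_{direction}.json")
        reports[direction] = report
    manifest.stages["prioritization"] = True

    write_json(manifest.to_dict(), out / "manifest.json")
    logger.info(
        "run complete: |T| = %d (up direction)",
        reports["up"]["funnel"]["T"],
    )
    return reports["up"]
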