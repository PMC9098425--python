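"""Cross-omics integration and druggable phospho-target prioritization.

The funnel narrows candidates in six named stages:

  D  differential features per layer (BH-adjusted omnibus ANOVA);
  C  features in consistently-trending core clusters;
  P  pathways enriched (adjusted p < alpha) in all three layers,
     re-ranked by the weighted p-value W = p_rna · p_prot · p_phos;
  F  genes of the top-K pathways that appear in at least one layer's C;
  f  the subset of F with a significant phospho change in the funnel
     direction;
  T  the subset of f with a drug-table entry passing the modality and
     approval filters.

Every surviving candidate carries a full provenance chain (clusters,
pathways, phosphosites, drug rows) into the final ranked report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .core import (
    Approval,
    DrugTargetTable,
    GeneSetCollection,
    IdMap,
    Layer,
    Modality,
    OmicsFunnelError,
    PipelineConfig,
    ValidationError,
)
from .differential import DifferentialResult
from .enrichment import EnrichmentResult, map_to_genes
from .io import logger

__all__ = [
    "IntegratedPathway",
    "FunnelTrace",
    "venn_counts",
    "overlap_pathways",
    "run_funnel",
    "screen_drugs",
    "build_report",
]

LAYERS = (Layer.RNA, Layer.PROTEIN, Layer.PHOSPHO)


# --------------------------------------------------------------------------
# Venn counts

def venn_counts(named_sets: dict[str, set]) -> dict[str, int]:
    """Exclusive region cardinalities of up to six named sets.

    Returns one entry per non-empty combination of set names (joined with
    ``&`` in sorted order): the number of elements belonging to exactly
    those sets.  The all-shared region is the key joining every name.
    """
    names = sorted(named_sets)
    if len(names) < 2:
        raise ValidationError("venn_counts needs >= 2 sets")
    if len(names) > 6:
        raise ValidationError("venn_counts supports at most 6 sets")
    sets = {n: set(named_sets[n]) for n in names}
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


# --------------------------------------------------------------------------
# pathway intersection and weighted p

@dataclass(frozen=True)
class IntegratedPathway:
    set_id: str
    p_rna: float
    p_protein: float
    p_phospho: float
    weighted_p: float
    rank: int

    def per_layer_p(self) -> dict[str, float]:
        return {"rna": self.p_rna, "protein": self.p_protein, "phospho": self.p_phospho}


def overlap_pathways(
    enrichments: dict[Layer, list[EnrichmentResult]],
    cfg: PipelineConfig,
) -> list[IntegratedPathway]:
    """Pathways significant in all three layers, ranked by weighted p.

    A pathway is admitted when its BH-adjusted p falls below alpha in at
    least one enrichment result of every layer; its weighted p-value
    W = p_rna · p_prot · p_phos uses the per-layer minimum *raw* p (when a
    layer contributes several lists, the best-enriched one represents it).
    Ties in W break lexicographically on set id.
    """
    for layer in LAYERS:
        if layer not in enrichments or not enrichments[layer]:
            raise ValidationError(f"missing enrichment results for layer {layer.value}")
    sig_per_layer: dict[Layer, set[str]] = {}
    minp_per_layer: dict[Layer, dict[str, float]] = {}
    for layer in LAYERS:
        sig: set[str] = set()
        minp: dict[str, float] = {}
        for res in enrichments[layer]:
            sig |= set(res.significant)
            for sid, p in res.table["p"].items():
                minp[sid] = min(minp.get(sid, 1.0), float(p))
        sig_per_layer[layer] = sig
        minp_per_layer[layer] = minp
    shared = set.intersection(*(sig_per_layer[l] for l in LAYERS))
    if not shared:
        logger.warning("no pathway is significant in all three layers")
    rows = []
    for sid in shared:
        ps = {l: minp_per_layer[l][sid] for l in LAYERS}
        w = ps[Layer.RNA] * ps[Layer.PROTEIN] * ps[Layer.PHOSPHO]
        rows.append((w, sid, ps))
    rows.sort(key=lambda r: (r[0], r[1]))
    return [
        IntegratedPathway(
            set_id=sid,
            p_rna=ps[Layer.RNA],
            p_protein=ps[Layer.PROTEIN],
            p_phospho=ps[Layer.PHOSPHO],
            weighted_p=w,
            rank=i + 1,
        )
        for i, (w, sid, ps) in enumerate(rows)
    ]


# --------------------------------------------------------------------------
# drug screen

def screen_drugs(
    genes,
    drugs: DrugTargetTable,
    direction: str,
    cfg: PipelineConfig,
) -> dict[str, list[dict]]:
    """Keep genes with a drug row matching the trend direction.

    Upregulated candidates need an inhibitor; downregulated ones an
    activator.  With ``cfg.approved_only`` only approved drugs count.
    Returns gene → matching drug rows (as dicts).
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    want = Modality.INHIBITOR if direction == "up" else Modality.ACTIVATOR
    out: dict[str, list[dict]] = {}
    for g in sorted(set(genes)):
        hits = [
            {"drug": r.drug, "modality": r.modality.value, "approval": r.approval.value}
            for r in drugs.rows_for_gene(g)
            if r.modality is want
            and (not cfg.approved_only or r.approval is Approval.APPROVED)
        ]
        if hits:
            out[g] = sorted(hits, key=lambda h: h["drug"])
    return out


# --------------------------------------------------------------------------
# the funnel

@dataclass
class FunnelTrace:
    """The six named stages of one funnel run plus per-candidate provenance."""

    direction: str
    D: dict[str, list[str]]  # layer -> differential features
    C: dict[str, list[str]]  # layer -> core features of direction-trending clusters
    C_genes: dict[str, list[str]]  # layer -> genes of C
    integrated: list[IntegratedPathway]
    P: list[str]  # pathways significant in all three layers (= integrated ids)
    top_pathways: list[str]  # top-K by weighted p
    F: list[str]  # genes
    f: list[str]  # genes
    T: list[str]  # genes
    provenance: dict[str, dict]  # gene -> chain
    config_digest: str

    def cardinalities(self) -> dict[str, int]:
        return {
            "D_rna": len(self.D["rna"]),
            "D_protein": len(self.D["protein"]),
            "D_phospho": len(self.D["phospho"]),
            "C_rna": len(self.C["rna"]),
            "C_protein": len(self.C["protein"]),
            "C_phospho": len(self.C["phospho"]),
            "P": len(self.P),
            "top_pathways": len(self.top_pathways),
            "F": len(self.F),
            "f": len(self.f),
            "T": len(self.T),
        }

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "config_digest": self.config_digest,
            "D": self.D,
            "C": self.C,
            "C_genes": self.C_genes,
            "P": self.P,
            "integrated": [
                {
                    "set_id": ip.set_id,
                    "p_rna": ip.p_rna,
                    "p_protein": ip.p_protein,
                    "p_phospho": ip.p_phospho,
                    "weighted_p": ip.weighted_p,
                    "rank": ip.rank,
                }
                for ip in self.integrated
            ],
            "top_pathways": self.top_pathways,
            "F": self.F,
            "f": self.f,
            "T": self.T,
            "provenance": self.provenance,
            "cardinalities": self.cardinalities(),
        }


def run_funnel(
    de: dict[Layer, DifferentialResult],
    clusters: dict[Layer, ClusterModel],
    integrated: list[IntegratedPathway],
    collection: GeneSetCollection,
    idmap: IdMap,
    drugs: DrugTargetTable,
    cfg: PipelineConfig,
    direction: str = "up",
    screen: bool | None = None,
) -> FunnelTrace:
    """Execute stages D→C→P→F→f→T for one trend direction.

    All upstream artifacts must come from the same configuration (their
    config digests are checked).  ``screen`` defaults to True for the up
    direction and False for down (activating a downregulated target is
    rarely a viable repurposing strategy, so the down branch reports
    pathways and features but screens no drugs unless asked).
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    if screen is None:
        screen = direction == "up"
    digest = cfg.digest()
    for layer in LAYERS:
        if layer not in de or layer not in clusters:
            raise ValidationError(f"missing upstream results for layer {layer.value}")
        for got in (de[layer].config_digest, clusters[layer].config_digest):
            if got != digest:
                raise OmicsFunnelError(
                    f"config digest mismatch for layer {layer.value}: "
                    f"{got} != {digest}"
                )

    D = {l.value: sorted(de[l].significant) for l in LAYERS}
    C = {l.value: sorted(clusters[l].core_features_with_label(direction)) for l in LAYERS}
    C_genes = {
        l.value: sorted(map_to_genes(C[l.value], l, idmap).genes) for l in LAYERS
    }
    union_C_genes: set[str] = set()
    for l in LAYERS:
        union_C_genes |= set(C_genes[l.value])

    P = [ip.set_id for ip in integrated]
    top = [ip.set_id for ip in integrated[: cfg.top_k_pathways]]

    top_genes: set[str] = set()
    gene_pathways: dict[str, list[str]] = {}
    for sid in top:
        for g in collection.members(sid):
            top_genes.add(g)
            gene_pathways.setdefault(g, []).append(sid)

    F = sorted(top_genes & union_C_genes)

    # gene-level phospho significance in the funnel direction
    want_dir = 1 if direction == "up" else -1
    pho = de[Layer.PHOSPHO]
    ptab = pho.table
    sig_pho = ptab[(ptab["adj_p"] < cfg.alpha) & (ptab["direction"] == want_dir)]
    ctrl, last = pho.design.groups[0], pho.design.groups[-1]
    pho_by_gene: dict[str, list[dict]] = {}
    for feat, row in sig_pho.iterrows():
        g = idmap.get(Layer.PHOSPHO, feat)
        if g is None:
            continue
        pho_by_gene.setdefault(g, []).append(
            {
                "feature_id": feat,
                "adj_p": float(row["adj_p"]),
                "delta": float(row[f"mean_{last}"] - row[f"mean_{ctrl}"]),
            }
        )
    f_set = sorted(g for g in F if g in pho_by_gene)

    drug_hits = screen_drugs(f_set, drugs, direction, cfg) if screen else {}
    T = sorted(drug_hits)

    provenance: dict[str, dict] = {}
    for g in T:
        chain = {
            "clusters": {
                l.value: sorted(
                    int(k)
                    for k in clusters[l].clusters_with_label(direction)
                    if any(
                        idmap.get(l, feat) == g
                        for feat in clusters[l].core_members[k]
                    )
                )
                for l in LAYERS
            },
            "pathways": sorted(gene_pathways.get(g, [])),
            "phospho_features": sorted(
                pho_by_gene[g], key=lambda d: d["feature_id"]
            ),
            "drugs": drug_hits[g],
        }
        provenance[g] = chain

    return FunnelTrace(
        direction=direction,
        D=D,
        C=C,
        C_genes=C_genes,
        integrated=integrated,
        P=sorted(P),
        top_pathways=top,
        F=F,
        f=f_set,
        T=T,
        provenance=provenance,
        config_digest=digest,
    )


# --------------------------------------------------------------------------
# report

def build_report(
    trace: FunnelTrace,
    cfg: PipelineConfig,
    truth=None,
    deviations: list[str] | None = None,
) -> dict:
    """Deterministic JSON-ready run report with the ranked candidate list.

    Candidates sort by (best weighted p among containing pathways
    ascending, |phospho effect| descending, gene lexicographic).  With a
    simulation truth attached, recovery metrics are included.
    """
    w_by_set = {ip.set_id: ip.weighted_p for ip in trace.integrated}
    candidates = []
    for g in trace.T:
        chain = trace.provenance[g]
        ws = [w_by_set[s] for s in chain["pathways"] if s in w_by_set]
        best_w = min(ws) if ws else 1.0
        deltas = [d["delta"] for d in chain["phospho_features"]]
        effect = max(deltas, key=abs) if deltas else 0.0
        candidates.append(
            {
                "gene": g,
                "best_weighted_p": best_w,
                "phospho_effect": effect,
                "drugs": chain["drugs"],
                "pathways": chain["pathways"],
                "phospho_features": chain["phospho_features"],
                "clusters": chain["clusters"],
            }
        )
    candidates.sort(
        key=lambda c: (c["best_weighted_p"], -abs(c["phospho_effect"]), c["gene"])
    )
    report = {
        "config": cfg.to_dict(),
        "config_digest": trace.config_digest,
        "direction": trace.direction,
        "funnel": trace.cardinalities(),
        "candidates": candidates,
        "deviations": sorted(deviations or [
            "rna differential calling uses one-way ANOVA on log2-CPM in place of "
            "pairwise negative-binomial contrasts",
            "D is the omnibus BH-adjusted call set, not a union of pairwise calls",
            "protein/phospho matrices are median-centered per sample before testing",
        ]),
    }
    if truth is not None:
        from .simulate import truth_recovery_report

        report["recovery"] = truth_recovery_report(truth, trace)
    return report
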