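"""Gene-set over-representation analysis and multi-list overlap links.

Feature lists (cluster cores, trend unions) are mapped to gene symbols and
tested one-sidedly for over-representation against a user-supplied gene-set
collection with the hypergeometric upper tail; the universe is the set of
all genes quantified in the layer.  BH adjustment runs within each list
across the retained sets.  The multi-list link computation reports which
genes recur across lists and which cross-list gene pairs share a gene-set
annotation — the textual equivalent of a multi-omics chord diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GeneSetCollection,
    IdMap,
    Layer,
    PipelineConfig,
    ValidationError,
    _as_layer,
)
from .differential import bh_adjust
from .io import logger

__all__ = [
    "MappedGenes",
    "EnrichmentResult",
    "LinkSets",
    "map_to_genes",
    "ora_hypergeometric",
    "enrich_list",
    "multi_list_links",
]


@dataclass
class MappedGenes:
    genes: set[str]
    uncovered: list[str]
    coverage: float


def map_to_genes(features, layer: Layer | str, idmap: IdMap) -> MappedGenes:
    """Collapse layer feature ids to a de-duplicated gene symbol set.

    Several features (e.g. phosphosites) may map to one gene; features the
    id map does not cover are collected and reported, not fatal.
    """
    layer = _as_layer(layer)
    features = list(features)
    genes: set[str] = set()
    uncovered: list[str] = []
    for f in features:
        g = idmap.get(layer, f)
        if g is None:
            uncovered.append(f)
        else:
            genes.add(g)
    coverage = 1.0 if not features else 1.0 - len(uncovered) / len(features)
    return MappedGenes(genes, uncovered, coverage)


def ora_hypergeometric(list_genes, set_genes, universe_genes) -> tuple[int, int, int, int, float]:
    """One-sided over-representation p for one gene set.

    Returns (k, K, n, N, p) where N is the universe size, K the set's
    annotated genes in the universe, n the list size, k the overlap, and
    p = P(X ≥ k) for X ~ Hypergeometric(N, K, n).
    """
    universe = set(universe_genes)
    if not universe:
        raise ValidationError("empty universe")
    lst = set(list_genes)
    if not lst <= universe:
        raise ValidationError("gene list is not a subset of the universe")
    st = set(set_genes) & universe
    k = len(lst & st)
    K, n, N = len(st), len(lst), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(max(p, 0.0), 1.0)


@dataclass
class EnrichmentResult:
    """Per-set ORA results for one gene list.

    ``table`` is indexed by set id with columns k, K, n, N, p, adj_p and
    the overlapping gene symbols; significant = adj_p < alpha.
    """

    list_name: str
    layer: Layer | None
    table: pd.DataFrame
    universe_size: int
    alpha: float
    config_digest: str = ""

    @property
    def significant(self) -> list[str]:
        t = self.table
        return list(t.index[t["adj_p"] < self.alpha])

    def raw_p(self, set_id: str) -> float:
        return float(self.table.loc[set_id, "p"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "set_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, list_name, alpha, config_digest="", layer=None
                 ) -> "EnrichmentResult":
        df = pd.read_csv(path, sep="\t", dtype={"set_id": str})
        df = df.set_index("set_id")
        df.index.name = None
        universe = int(df["N"].iloc[0]) if len(df) else 0
        return cls(list_name, layer, df, universe, alpha, config_digest)


def enrich_list(
    list_genes,
    collection: GeneSetCollection,
    universe_genes,
    cfg: PipelineConfig,
    list_name: str = "list",
    layer: Layer | None = None,
) -> EnrichmentResult:
    """ORA of one gene list against every retained set of the collection.

    Sets are intersected with the universe first and kept only when their
    annotated size K satisfies min_set_size ≤ K ≤ max_set_size; BH runs
    across the retained sets.  An empty retained collection yields an
    empty result with a warning.
    """
    universe = set(universe_genes)
    lst = set(list_genes) & universe
    rows = []
    for sid in sorted(collection.ids()):
        members = set(collection.members(sid)) & universe
        K = len(members)
        if K < cfg.min_set_size or K > cfg.max_set_size:
            continue
        k = len(lst & members)
        p = float(stats.hypergeom.sf(k - 1, len(universe), K, len(lst)))
        rows.append(
            {
                "set_id": sid,
                "description": collection.description(sid),
                "k": k,
                "K": K,
                "n": len(lst),
                "N": len(universe),
                "p": min(max(p, 0.0), 1.0),
                "genes": ",".join(sorted(lst & members)),
            }
        )
    if not rows:
        logger.warning("%s: no gene sets retained after size filtering", list_name)
        table = pd.DataFrame(
            columns=["description", "k", "K", "n", "N", "p", "adj_p", "genes"]
        )
        return EnrichmentResult(list_name, layer, table, len(universe), cfg.alpha,
                                cfg.digest())
    table = pd.DataFrame(rows).set_index("set_id")
    table.index.name = None
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table = table[["description", "k", "K", "n", "N", "p", "adj_p", "genes"]]
    return EnrichmentResult(list_name, layer, table, len(universe), cfg.alpha,
                            cfg.digest())


@dataclass
class LinkSets:
    """Cross-list connections of the multi-omics meta-analysis.

    ``same_feature``: gene → the (≥ 2) lists containing it.
    ``shared_term``: unordered cross-list gene pairs annotated to ≥ 1
    common gene set, with the witnessing set ids.
    """

    same_feature: dict[str, tuple[str, ...]]
    shared_term: dict[tuple[str, str], tuple[str, ...]]

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        for gene, lists in sorted(self.same_feature.items()):
            for a, b in _pairs(sorted(lists)):
                rows.append(
                    {"type": "same_feature", "a": gene, "b": gene,
                     "list_a": a, "list_b": b, "sets": ""}
                )
        for (g1, g2), sets in sorted(self.shared_term.items()):
            rows.append(
                {"type": "shared_term", "a": g1, "b": g2,
                 "list_a": "", "list_b": "", "sets": ",".join(sets)}
            )
        return pd.DataFrame(rows, columns=["type", "a", "b", "list_a", "list_b", "sets"])


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def multi_list_links(lists: dict[str, set[str]], collection: GeneSetCollection) -> LinkSets:
    """Same-feature and shared-term links between ≥ 2 named gene lists."""
    if len(lists) < 2:
        raise ValidationError("multi_list_links needs >= 2 lists")
    names = sorted(lists)
    same: dict[str, tuple[str, ...]] = {}
    all_genes: set[str] = set()
    for n in names:
        all_genes |= set(lists[n])
    for g in sorted(all_genes):
        containing = tuple(n for n in names if g in lists[n])
        if len(containing) >= 2:
            same[g] = containing
    annotation: dict[str, set[str]] = {
        g: collection.sets_containing(g) for g in sorted(all_genes)
    }
    shared: dict[tuple[str, str], tuple[str, ...]] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            for g1 in sorted(lists[na]):
                for g2 in sorted(lists[nb]):
                    if g1 == g2:
                        continue
                    common = annotation[g1] & annotation[g2]
                    if common:
                        key = tuple(sorted((g1, g2)))
                        if key not in shared:
                            shared[key] = tuple(sorted(common))
    return LinkSets(same, shared)
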