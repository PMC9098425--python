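"""Funnel, pathway intersection, drug screen and report — oracle fixtures."""

from __future__ import annotations

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from omicsfunnel import (
    DEFAULT_DESIGN,
    DrugRow,
    DrugTargetTable,
    GeneSetCollection,
    IdMap,
    Layer,
    PipelineConfig,
    ValidationError,
    build_report,
    overlap_pathways,
    run_funnel,
    screen_drugs,
    venn_counts,
)
from omicsfunnel.clustering import ClusterModel, TrendLabel
from omicsfunnel.core import Approval, Modality, OmicsFunnelError
from omicsfunnel.differential import DifferentialResult
from omicsfunnel.enrichment import EnrichmentResult
from omicsfunnel.prioritize import IntegratedPathway, LAYERS


class TestVennCounts:
    def test_worked_example(self):
        out = venn_counts({"A": {"a", "b", "c"}, "B": {"b", "c", "d"},
                           "C": {"c", "e"}})
        assert out["A&B&C"] == 1  # {c}
        assert out["A&B"] == 1    # {b}
        assert out["A"] == 1      # {a}
        assert out["C"] == 1      # {e}

    def test_identical_sets_all_shared(self):
        out = venn_counts({"X": {1, 2}, "Y": {1, 2}})
        assert out["X&Y"] == 2 and out["X"] == 0 and out["Y"] == 0

    def test_disjoint_sets(self):
        out = venn_counts({"X": {1}, "Y": {2}})
        assert out["X&Y"] == 0 and out["X"] == 1 and out["Y"] == 1

    def test_too_many_sets_guarded(self):
        with pytest.raises(ValidationError):
            venn_counts({str(i): {i} for i in range(7)})

    def test_brute_force_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            names = ["A", "B", "C", "D"]
            sets = {n: set(rng.integers(0, 12, rng.integers(0, 10)).tolist())
                    for n in names}
            out = venn_counts(sets)
            for r in range(1, 5):
                for combo in itertools.combinations(names, r):
                    expected = set(range(12))
                    for n in names:
                        if n in combo:
                            expected &= sets[n]
                    for n in names:
                        if n not in combo:
                            expected -= sets[n]
                    assert out["&".join(combo)] == len(expected)


def _enrichment(layer, rows, cfg, name="x"):
    table = pd.DataFrame(rows).set_index("set_id")
    table.index.name = None
    return EnrichmentResult(name, layer, table, 100, cfg.alpha, cfg.digest())


class TestOverlapPathways:
    def _res(self, layer, cfg, sig_sets, raw_p):
        rows = [{"set_id": s, "k": 5, "K": 10, "n": 20, "N": 100,
                 "p": raw_p[s], "adj_p": 0.01 if s in sig_sets else 0.9,
                 "genes": ""} for s in raw_p]
        return _enrichment(layer, rows, cfg)

    def test_intersection_and_product(self, cfg):
        raw = {"a": 1e-3, "b": 1e-2, "c": 1e-4}
        enr = {
            Layer.RNA: [self._res(Layer.RNA, cfg, {"a", "b", "c"}, raw)],
            Layer.PROTEIN: [self._res(Layer.PROTEIN, cfg, {"b", "c"}, raw)],
            Layer.PHOSPHO: [self._res(Layer.PHOSPHO, cfg, {"c", "b"}, raw)],
        }
        out = overlap_pathways(enr, cfg)
        assert [ip.set_id for ip in out] == ["c", "b"]  # sorted by W
        c = out[0]
        assert c.weighted_p == pytest.approx((1e-4) ** 3)

    def test_weighted_p_layer_permutation_invariant(self, cfg):
        raw = {"s": 1e-3, "t": 1e-2}
        results = {
            Layer.RNA: self._res(Layer.RNA, cfg, {"s", "t"}, {"s": 1e-3, "t": 1e-2}),
            Layer.PROTEIN: self._res(Layer.PROTEIN, cfg, {"s", "t"},
                                     {"s": 1e-2, "t": 1e-4}),
            Layer.PHOSPHO: self._res(Layer.PHOSPHO, cfg, {"s", "t"},
                                     {"s": 1e-4, "t": 1e-3}),
        }
        base = None
        for perm in itertools.permutations(LAYERS):
            enr = {lay: [results[src]] for lay, src in zip(LAYERS, perm)}
            out = overlap_pathways(enr, cfg)
            ws = sorted(ip.weighted_p for ip in out)
            if base is None:
                base = ws
            assert np.allclose(ws, base)

    def test_min_raw_p_over_multiple_lists(self, cfg):
        raw_hi = {"s": 0.5}
        raw_lo = {"s": 1e-3}
        enr = {
            Layer.RNA: [self._res(Layer.RNA, cfg, {"s"}, raw_hi),
                        self._res(Layer.RNA, cfg, set(), raw_lo)],
            Layer.PROTEIN: [self._res(Layer.PROTEIN, cfg, {"s"}, {"s": 0.1})],
            Layer.PHOSPHO: [self._res(Layer.PHOSPHO, cfg, {"s"}, {"s": 0.2})],
        }
        out = overlap_pathways(enr, cfg)
        assert out[0].weighted_p == pytest.approx(1e-3 * 0.1 * 0.2)

    def test_empty_intersection_is_empty_not_error(self, cfg):
        enr = {
            Layer.RNA: [self._res(Layer.RNA, cfg, {"a"}, {"a": 0.01})],
            Layer.PROTEIN: [self._res(Layer.PROTEIN, cfg, set(), {"a": 0.5})],
            Layer.PHOSPHO: [self._res(Layer.PHOSPHO, cfg, {"a"}, {"a": 0.01})],
        }
        assert overlap_pathways(enr, cfg) == []


class TestScreenDrugs:
    def _table(self):
        return DrugTargetTable((
            DrugRow("EGFR", "gefitinib", Modality.INHIBITOR, Approval.APPROVED),
            DrugRow("SYK", "fostamatinib", Modality.INHIBITOR, Approval.APPROVED),
            DrugRow("AKT1", "cmpdX", Modality.INHIBITOR, Approval.INVESTIGATIONAL),
            DrugRow("PPARG", "agonistY", Modality.ACTIVATOR, Approval.APPROVED),
        ))

    def test_up_keeps_inhibitors(self, cfg):
        out = screen_drugs({"EGFR", "PPARG"}, self._table(), "up", cfg)
        assert set(out) == {"EGFR"}
        assert out["EGFR"][0]["drug"] == "gefitinib"

    def test_down_keeps_activators(self, cfg):
        out = screen_drugs({"EGFR", "PPARG"}, self._table(), "down", cfg)
        assert set(out) == {"PPARG"}

    def test_approval_filter_configurable(self):
        strict = PipelineConfig(approved_only=True)
        loose = PipelineConfig(approved_only=False)
        assert "AKT1" not in screen_drugs({"AKT1"}, self._table(), "up", strict)
        assert "AKT1" in screen_drugs({"AKT1"}, self._table(), "up", loose)

    def test_absent_gene_dropped(self, cfg):
        assert screen_drugs({"NOPE"}, self._table(), "up", cfg) == {}


# --------------------------------------------------------------------------
# hand-built micro-fixture: 1 active pathway of 5 up genes, 2 of them
# phospho-significant-up, 1 of those with an approved inhibitor

GENES = ["A", "B", "C", "D", "E"]


def _micro_de(cfg):
    design = DEFAULT_DESIGN
    out = {}
    for layer in LAYERS:
        if layer is Layer.PHOSPHO:
            feats = [f"{g}_S1" for g in GENES] + ["E_S2"]
            adj = [0.01, 0.02, 0.50, 0.20, 0.01, 0.9]
            direction = [1, 1, 1, 1, -1, 1]
        else:
            suffix = "_mrna" if layer is Layer.RNA else "_prot"
            feats = [g + suffix for g in GENES]
            adj = [0.001] * 5
            direction = [1] * 5
        rows = {
            **{f"mean_{g}": np.linspace(0, 2, len(feats))
               for g in design.groups},
            "F": 10.0, "p": 0.001, "adj_p": adj, "direction": direction,
        }
        table = pd.DataFrame(rows, index=feats)
        for i, g in enumerate(design.groups):
            # increasing means so direction/delta columns are coherent
            table[f"mean_{g}"] = [float(i) * d for d in direction]
        out[layer] = DifferentialResult(layer, design, table, [],
                                        cfg.digest(), cfg.alpha)
    return out


def _micro_clusters(cfg):
    design = DEFAULT_DESIGN
    out = {}
    for layer in LAYERS:
        if layer is Layer.PHOSPHO:
            feats = [f"{g}_S1" for g in GENES] + ["E_S2"]
        else:
            suffix = "_mrna" if layer is Layer.RNA else "_prot"
            feats = [g + suffix for g in GENES]
        u = np.zeros((len(feats), 2))
        u[:, 0] = 1.0  # everything core member of the up cluster
        out[layer] = ClusterModel(
            layer=layer, design=design,
            profiles=pd.DataFrame(index=feats, columns=list(design.groups)),
            K=2, fuzzifier=cfg.fuzzifier,
            centroids=np.vstack([np.linspace(-1, 1, 5), np.linspace(1, -1, 5)]),
            memberships=pd.DataFrame(u, index=feats, columns=["c0", "c1"]),
            objective=0.0, n_iter=1, seed=cfg.seed,
            trend_labels=[TrendLabel("up", 1.0, 2.0),
                          TrendLabel("down", -1.0, -2.0)],
            membership_cutoff=cfg.membership_cutoff,
            dropped=[], config_digest=cfg.digest(),
        )
    return out


def _micro_world():
    collection = GeneSetCollection({
        "PW_A": ("active", tuple(GENES + ["Z"])),
    })
    mapping = {}
    for g in GENES:
        mapping[(Layer.RNA, f"{g}_mrna")] = g
        mapping[(Layer.PROTEIN, f"{g}_prot")] = g
        mapping[(Layer.PHOSPHO, f"{g}_S1")] = g
    mapping[(Layer.PHOSPHO, "E_S2")] = "E"
    idmap = IdMap(mapping)
    drugs = DrugTargetTable((
        DrugRow("A", "inhibA", Modality.INHIBITOR, Approval.APPROVED),
        DrugRow("B", "actB", Modality.ACTIVATOR, Approval.APPROVED),
        DrugRow("C", "inhibC", Modality.INHIBITOR, Approval.INVESTIGATIONAL),
    ))
    integrated = [IntegratedPathway("PW_A", 1e-3, 1e-2, 1e-4, 1e-9, 1)]
    return collection, idmap, drugs, integrated


class TestFunnelMicroFixture:
    def test_funnel_counts_and_provenance(self, cfg):
        de = _micro_de(cfg)
        clusters = _micro_clusters(cfg)
        collection, idmap, drugs, integrated = _micro_world()
        trace = run_funnel(de, clusters, integrated, collection, idmap,
                           drugs, cfg, direction="up")
        assert trace.F == ["A", "B", "C", "D", "E"]
        assert trace.f == ["A", "B"]
        assert trace.T == ["A"]
        card = trace.cardinalities()
        assert (card["F"], card["f"], card["T"]) == (5, 2, 1)
        prov = trace.provenance["A"]
        assert prov["pathways"] == ["PW_A"]
        assert prov["drugs"][0]["drug"] == "inhibA"
        assert prov["phospho_features"][0]["feature_id"] == "A_S1"
        assert prov["clusters"]["rna"] == [0]

    def test_containment_invariant(self, cfg):
        de = _micro_de(cfg)
        clusters = _micro_clusters(cfg)
        collection, idmap, drugs, integrated = _micro_world()
        trace = run_funnel(de, clusters, integrated, collection, idmap,
                           drugs, cfg)
        assert set(trace.T) <= set(trace.f) <= set(trace.F)

    def test_empty_p_propagates(self, cfg):
        de = _micro_de(cfg)
        clusters = _micro_clusters(cfg)
        collection, idmap, drugs, _ = _micro_world()
        trace = run_funnel(de, clusters, [], collection, idmap, drugs, cfg)
        assert trace.F == [] and trace.f == [] and trace.T == []

    def test_down_direction_screens_nothing_by_default(self, cfg):
        de = _micro_de(cfg)
        clusters = _micro_clusters(cfg)
        collection, idmap, drugs, integrated = _micro_world()
        trace = run_funnel(de, clusters, integrated, collection, idmap,
                           drugs, cfg, direction="down")
        assert trace.T == []

    def test_config_mismatch_rejected(self, cfg):
        de = _micro_de(cfg)
        clusters = _micro_clusters(PipelineConfig(seed=999))
        collection, idmap, drugs, integrated = _micro_world()
        with pytest.raises(OmicsFunnelError, match="digest"):
            run_funnel(de, clusters, integrated, collection, idmap, drugs, cfg)

    def test_report_candidates_and_determinism(self, cfg):
        de = _micro_de(cfg)
        clusters = _micro_clusters(cfg)
        collection, idmap, drugs, integrated = _micro_world()
        trace = run_funnel(de, clusters, integrated, collection, idmap,
                           drugs, cfg)
        r1 = build_report(trace, cfg)
        r2 = build_report(trace, cfg)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
        assert [c["gene"] for c in r1["candidates"]] == ["A"]
        assert r1["candidates"][0]["best_weighted_p"] == pytest.approx(1e-9)

    def test_empty_target_report(self, cfg):
        de = _micro_de(cfg)
        clusters = _micro_clusters(cfg)
        collection, idmap, drugs, _ = _micro_world()
        trace = run_funnel(de, clusters, [], collection, idmap, drugs, cfg)
        report = build_report(trace, cfg)
        assert report["candidates"] == []
        assert report["funnel"]["T"] == 0


class TestWeightedRankingStability:
    def test_product_rank_equals_log_sum_rank(self):
        rng = np.random.default_rng(12)
        triples = 10 ** (-rng.uniform(0, 12, (10_000, 3)))
        w = triples.prod(axis=1)
        logw = np.log(triples).sum(axis=1)
        assert np.array_equal(np.argsort(w, kind="stable"),
                              np.argsort(logw, kind="stable"))


class TestRecoveryArithmetic:
    def test_recall_precision_cases(self):
        from omicsfunnel import truth_recovery_report
        from omicsfunnel.simulate import SimulationTruth

        truth = SimulationTruth(
            seed=0, gene_archetype={}, feature_archetype={},
            effect_size={}, drivers=["a", "b", "c", "d", "e"],
            active_pathways=["PW"], gene_pathways={},
        )

        class FakeTrace:
            def __init__(self, T):
                self.T = T

        perfect = truth_recovery_report(truth, FakeTrace(["a", "b", "c", "d", "e"]))
        assert perfect["driver_recall"] == 1.0
        assert perfect["target_precision"] == 1.0
        empty = truth_recovery_report(truth, FakeTrace([]))
        assert empty["driver_recall"] == 0.0
        assert empty["target_precision"] == 0.0
        decoy = truth_recovery_report(
            truth, FakeTrace(["a", "b", "c", "d", "e", "x"]))
        assert decoy["driver_recall"] == 1.0
        assert decoy["target_precision"] == pytest.approx(5 / 6)
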