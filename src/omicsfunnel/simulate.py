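"""Synthetic three-omics time-course generator with planted ground truth.

The generator emulates the data structure of a five-group exposure time
course (control plus four post-exposure time points, a few replicates per
group) measured on three layers: negative-binomial RNA counts, Gaussian
protein log2-intensities, and sparser Gaussian phosphosite log2-intensities
with one to three sites per gene.  Each gene carries one temporal archetype
— monotone up, monotone down, transient (rise-and-return), or flat — shared
across layers, with effect curves piecewise-linear in scaled time.  A small
set of driver genes is planted: upregulated in all three layers, extra
phospho effect, and an approved-inhibitor row in the drug table.  One
"active" pathway is composed mostly of upregulated genes (all drivers
included) so the funnel has a recoverable signal; the remaining pathways
sample genes uniformly.  The returned :class:`SimulationTruth` carries
everything recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    Approval,
    DEFAULT_DESIGN,
    DrugRow,
    DrugTargetTable,
    GeneSetCollection,
    GroupDesign,
    IdMap,
    Layer,
    Modality,
    OmicsMatrix,
    ValidationError,
)
from . import io as ofio

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "simulate_multiomics",
    "truth_recovery_report",
    "write_fixture_set",
]

ARCHETYPES = ("up", "down", "transient", "flat")


@dataclass
class SimulationParams:
    """Study conditions of the synthetic benchmark (defaults are the
    conditions every recovery test runs under)."""

    n_genes: int = 1000
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (10, 40)
    design: GroupDesign = field(default_factory=lambda: DEFAULT_DESIGN)
    replicates: int = 3
    frac_up: float = 0.15
    frac_down: float = 0.15
    frac_transient: float = 0.10
    n_driver_genes: int = 5
    rna_mean_range: tuple[float, float] = (20.0, 2000.0)
    rna_dispersion: float = 0.1
    noise_sd: float = 0.25
    effect_range: tuple[float, float] = (1.75, 2.0)
    driver_extra_phospho: float = 0.5
    phospho_missing: float = 0.1
    sites_per_gene: tuple[int, int] = (1, 3)
    active_up_fraction: float = 0.8
    n_decoy_drug_genes: int = 50
    library_spread: float = 2.0  # max/min sample library factor
    sample_shift_sd: float = 0.3  # per-sample batch shift, protein/phospho

    def __post_init__(self) -> None:
        if self.frac_up + self.frac_down + self.frac_transient > 1.0 + 1e-12:
            raise ValidationError("archetype fractions must sum to <= 1")
        if self.n_genes < 10 or self.n_pathways < 1 or self.replicates < 2:
            raise ValidationError("invalid sizes")
        if self.pathway_size[0] < 1 or self.pathway_size[1] < self.pathway_size[0]:
            raise ValidationError("invalid pathway size range")
        if self.effect_range[0] < 0 or self.effect_range[1] < self.effect_range[0]:
            raise ValidationError("invalid effect range")
        if not (0.0 <= self.phospho_missing < 1.0):
            raise ValidationError("phospho_missing must lie in [0, 1)")
        if self.library_spread < 1.0:
            raise ValidationError("library_spread must be >= 1")


@dataclass
class SimulationTruth:
    """Planted ground truth of one simulated dataset."""

    seed: int
    gene_archetype: dict[str, str]
    feature_archetype: dict[str, dict[str, str]]  # layer -> feature -> archetype
    effect_size: dict[str, float]
    drivers: list[str]
    active_pathways: list[str]
    gene_pathways: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "gene_archetype": self.gene_archetype,
            "feature_archetype": self.feature_archetype,
            "effect_size": self.effect_size,
            "drivers": self.drivers,
            "active_pathways": self.active_pathways,
            "gene_pathways": self.gene_pathways,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            seed=int(d["seed"]),
            gene_archetype=dict(d["gene_archetype"]),
            feature_archetype={k: dict(v) for k, v in d["feature_archetype"].items()},
            effect_size={k: float(v) for k, v in d["effect_size"].items()},
            drivers=list(d["drivers"]),
            active_pathways=list(d["active_pathways"]),
            gene_pathways={k: list(v) for k, v in d["gene_pathways"].items()},
        )


def _archetype_shape(arch: str, t_frac: np.ndarray) -> np.ndarray:
    """Piecewise-linear effect curve in scaled time, peak magnitude 1."""
    if arch == "up":
        return t_frac
    if arch == "down":
        return -t_frac
    if arch == "transient":
        return 1.0 - np.abs(2.0 * t_frac - 1.0)
    return np.zeros_like(t_frac)


def simulate_multiomics(
    params: SimulationParams, seed: int
) -> tuple[
    dict[Layer, OmicsMatrix],
    GeneSetCollection,
    IdMap,
    DrugTargetTable,
    SimulationTruth,
]:
    """Generate the three matrices, gene sets, id map, drug table and truth."""
    rng = np.random.default_rng(seed)
    n = params.n_genes
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    design = params.design
    t_frac = design.time_fractions
    reps = params.replicates
    samples = [f"{g}_{r+1}" for g in design.groups for r in range(reps)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}

    # ---- archetypes and effects
    n_up = round(params.frac_up * n)
    n_down = round(params.frac_down * n)
    n_tr = round(params.frac_transient * n)
    order = rng.permutation(n)
    arch = np.array(["flat"] * n, dtype=object)
    arch[order[:n_up]] = "up"
    arch[order[n_up:n_up + n_down]] = "down"
    arch[order[n_up + n_down:n_up + n_down + n_tr]] = "transient"
    effects = rng.uniform(params.effect_range[0], params.effect_range[1], n)
    # zero effect degenerates to a flat archetype
    arch[effects == 0.0] = "flat"
    up_idx = np.flatnonzero(arch == "up")
    if params.n_driver_genes > up_idx.size:
        raise ValidationError(
            f"n_driver_genes={params.n_driver_genes} exceeds the up-gene "
            f"budget ({up_idx.size})"
        )
    drivers_idx = rng.choice(up_idx, size=params.n_driver_genes, replace=False)
    drivers = sorted(genes[i] for i in drivers_idx)
    gene_arch = {g: str(a) for g, a in zip(genes, arch)}
    eff = {g: float(e) if a != "flat" else 0.0
           for g, e, a in zip(genes, effects, arch)}

    shapes = np.stack([_archetype_shape(a, t_frac) for a in arch])  # n x T
    log2_effect = shapes * np.array([eff[g] for g in genes])[:, None]  # n x T

    # ---- RNA layer: NB counts
    mu = np.exp(rng.uniform(np.log(params.rna_mean_range[0]),
                            np.log(params.rna_mean_range[1]), n))
    lib = np.exp(rng.uniform(0.0, np.log(params.library_spread), len(samples)))
    mean = (
        mu[:, None]
        * 2.0 ** np.repeat(log2_effect, reps, axis=1)
        * lib[None, :]
    )
    theta = params.rna_dispersion
    if theta > 0:
        lam = rng.gamma(1.0 / theta, mean * theta)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(float)
    rna = OmicsMatrix(
        layer=Layer.RNA,
        feature_ids=[f"{g}_mrna" for g in genes],
        sample_ids=list(samples),
        values=counts,
        groups=dict(groups),
    )

    # ---- protein layer: Gaussian log2 intensities
    base_p = rng.normal(25.0, 2.0, n)
    shift = rng.normal(0.0, params.sample_shift_sd, len(samples))
    prot_vals = (
        base_p[:, None]
        + np.repeat(log2_effect, reps, axis=1)
        + shift[None, :]
        + rng.normal(0.0, params.noise_sd, (n, len(samples)))
    )
    protein = OmicsMatrix(
        layer=Layer.PROTEIN,
        feature_ids=[f"{g}_prot" for g in genes],
        sample_ids=list(samples),
        values=prot_vals,
        groups=dict(groups),
    )

    # ---- phospho layer: 1-3 sites per gene, driver boost, MCAR missingness
    n_sites = rng.integers(params.sites_per_gene[0], params.sites_per_gene[1] + 1, n)
    pho_feats: list[str] = []
    pho_gene_idx: list[int] = []
    for gi, g in enumerate(genes):
        for s in range(int(n_sites[gi])):
            pho_feats.append(f"{g}_S{s+1}")
            pho_gene_idx.append(gi)
    pho_gene_idx = np.asarray(pho_gene_idx)
    driver_mask = np.zeros(n, dtype=bool)
    driver_mask[drivers_idx] = True
    pho_eff = np.array([eff[genes[gi]] for gi in pho_gene_idx])
    pho_eff = pho_eff + params.driver_extra_phospho * driver_mask[pho_gene_idx]
    pho_shapes = shapes[pho_gene_idx]
    pho_log2 = pho_shapes * pho_eff[:, None]
    base_s = rng.normal(22.0, 2.0, len(pho_feats))
    shift_s = rng.normal(0.0, params.sample_shift_sd, len(samples))
    pho_vals = (
        base_s[:, None]
        + np.repeat(pho_log2, reps, axis=1)
        + shift_s[None, :]
        + rng.normal(0.0, params.noise_sd, (len(pho_feats), len(samples)))
    )
    if params.phospho_missing > 0:
        miss = rng.random(pho_vals.shape) < params.phospho_missing
        pho_vals = np.where(miss, np.nan, pho_vals)
    phospho = OmicsMatrix(
        layer=Layer.PHOSPHO,
        feature_ids=list(pho_feats),
        sample_ids=list(samples),
        values=pho_vals,
        groups=dict(groups),
    )

    # ---- pathways: one active set stacked with up genes, the rest uniform
    sizes = rng.integers(params.pathway_size[0], params.pathway_size[1] + 1,
                         params.n_pathways)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    active_id = "PW001"
    # the planted signal pathway sits at the top of the size range so that
    # its enrichment is statistically identifiable in the count layer
    s0 = int(params.pathway_size[1])
    n_up_in = max(int(np.ceil(params.active_up_fraction * s0)), params.n_driver_genes)
    n_up_in = min(n_up_in, up_idx.size, s0)
    other_up = np.setdiff1d(up_idx, drivers_idx)
    extra_up = rng.choice(other_up, size=max(n_up_in - drivers_idx.size, 0),
                          replace=False)
    non_up = np.setdiff1d(np.arange(n), up_idx)
    fill = rng.choice(non_up, size=max(s0 - n_up_in, 0), replace=False)
    members0 = sorted(
        {genes[i] for i in np.concatenate([drivers_idx, extra_up, fill])}
    )
    sets[active_id] = ("planted active pathway (synthetic)", tuple(members0))
    for pi in range(1, params.n_pathways):
        sid = f"PW{pi+1:03d}"
        mem = rng.choice(n, size=int(sizes[pi]), replace=False)
        sets[sid] = ("random background pathway (synthetic)",
                     tuple(sorted(genes[i] for i in mem)))
    collection = GeneSetCollection(sets)
    gene_pathways: dict[str, list[str]] = {}
    for sid, (_, mem) in sets.items():
        for g in mem:
            gene_pathways.setdefault(g, []).append(sid)

    # ---- id map
    mapping: dict[tuple[Layer, str], str] = {}
    for g in genes:
        mapping[(Layer.RNA, f"{g}_mrna")] = g
        mapping[(Layer.PROTEIN, f"{g}_prot")] = g
    for feat, gi in zip(pho_feats, pho_gene_idx):
        mapping[(Layer.PHOSPHO, feat)] = genes[gi]
    idmap = IdMap(mapping)

    # ---- drug table: approved inhibitors for drivers, mixed decoys
    rows: list[DrugRow] = [
        DrugRow(g, f"inh-{g.lower()}", Modality.INHIBITOR, Approval.APPROVED)
        for g in drivers
    ]
    non_driver = np.setdiff1d(np.arange(n), drivers_idx)
    decoys = rng.choice(non_driver, size=min(params.n_decoy_drug_genes,
                                             non_driver.size), replace=False)
    modalities = rng.integers(0, 3, decoys.size)
    approvals = rng.integers(0, 2, decoys.size)
    mod_enum = (Modality.INHIBITOR, Modality.ACTIVATOR, Modality.OTHER)
    app_enum = (Approval.APPROVED, Approval.INVESTIGATIONAL)
    for di, mi, ai in zip(decoys, modalities, approvals):
        g = genes[int(di)]
        rows.append(DrugRow(g, f"cmpd-{g.lower()}", mod_enum[int(mi)],
                            app_enum[int(ai)]))
    drugs = DrugTargetTable(tuple(rows))

    feature_archetype = {
        "rna": {f"{g}_mrna": gene_arch[g] for g in genes},
        "protein": {f"{g}_prot": gene_arch[g] for g in genes},
        "phospho": {feat: gene_arch[genes[gi]]
                    for feat, gi in zip(pho_feats, pho_gene_idx)},
    }
    truth = SimulationTruth(
        seed=int(seed),
        gene_archetype=gene_arch,
        feature_archetype=feature_archetype,
        effect_size=eff,
        drivers=drivers,
        active_pathways=[active_id],
        gene_pathways=gene_pathways,
    )
    matrices = {Layer.RNA: rna, Layer.PROTEIN: protein, Layer.PHOSPHO: phospho}
    return matrices, collection, idmap, drugs, truth


def truth_recovery_report(truth: SimulationTruth, trace) -> dict:
    """Driver recall and precision of the final target list T.

    recall = |drivers ∩ T| / |drivers|; precision = |drivers ∩ T| / |T|
    (0 when T is empty).
    """
    drivers = set(truth.drivers)
    T = set(trace.T)
    hit = drivers & T
    recall = len(hit) / len(drivers) if drivers else 0.0
    precision = len(hit) / len(T) if T else 0.0
    return {
        "n_drivers": len(drivers),
        "n_targets": len(T),
        "driver_recall": recall,
        "target_precision": precision,
        "recovered_drivers": sorted(hit),
        "missed_drivers": sorted(drivers - T),
        "decoy_targets": sorted(T - drivers),
    }


def write_fixture_set(out_dir: str | Path, params: SimulationParams, seed: int) -> dict:
    """Simulate and write the full fixture set into ``out_dir``.

    Writes the three matrices, sample sheet, GMT, id map, drug table and
    truth JSON; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, collection, idmap, drugs, truth = simulate_multiomics(params, seed)
    paths = {
        "rna": out / "rna_counts.tsv",
        "protein": out / "protein_log2.tsv",
        "phospho": out / "phospho_log2.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "idmap": out / "idmap.tsv",
        "drug_table": out / "drug_table.tsv",
        "truth": out / "truth.json",
    }
    for layer, key in ((Layer.RNA, "rna"), (Layer.PROTEIN, "protein"),
                       (Layer.PHOSPHO, "phospho")):
        ofio.write_matrix(matrices[layer], paths[key])
    any_m = matrices[Layer.RNA]
    ofio.write_sample_sheet(any_m.groups, paths["sample_sheet"])
    ofio.write_gmt(collection, paths["gene_sets"])
    ofio.write_idmap(idmap, paths["idmap"])
    ofio.write_drug_table(drugs, paths["drug_table"])
    ofio.write_json(truth.to_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
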