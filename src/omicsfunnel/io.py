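"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular files are UTF-8 TSV with a header row; gene sets use the GMT
dialect; configuration and reports are JSON.  Readers are total: every
malformed input raises a typed :class:`~omicsfunnel.core.FormatError` that
names the offending line or cell, never a silent coercion.  Missing values
are written as ``NA``.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Approval,
    DrugRow,
    DrugTargetTable,
    FormatError,
    GeneSetCollection,
    IdMap,
    Layer,
    Modality,
    OmicsMatrix,
    PipelineConfig,
    ValidationError,
    _as_layer,
)

NA_TOKEN = "NA"

logger = logging.getLogger("omicsfunnel")


def setup_logging(level: str = "INFO") -> None:
    """Plain-text log with ISO-8601 timestamps to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s",
            datefmt="%Y-%m-%dT%H:%M:%S",
        )
    )
    root = logging.getLogger("omicsfunnel")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Sample → group mapping, preserving the sheet's sample order."""
    path = Path(path)
    df = _read_tsv(path, required=("sample_id", "group"))
    groups: dict[str, str] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        sid, grp = str(row.sample_id), str(row.group)
        if sid in groups:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        groups[sid] = grp
    if not groups:
        raise FormatError(f"{path}: empty sample sheet")
    return groups


def read_matrix(
    path: str | Path, layer: Layer | str, sample_sheet_path: str | Path
) -> OmicsMatrix:
    """Read a feature × sample TSV matrix for one omics layer.

    Sample order is taken from the sample sheet and the matrix is
    re-indexed to it; matrix columns absent from the sheet are dropped
    (logged), sheet samples absent from the matrix are an error.
    """
    layer = _as_layer(layer)
    path = Path(path)
    sheet = read_sample_sheet(sample_sheet_path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        matrix_samples = cols[1:]
        if not matrix_samples:
            raise FormatError(f"{path}: header has no sample columns")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            fid = fields[0]
            if fid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen.add(fid)
            vals: list[float] = []
            for ci, cell in enumerate(fields[1:], start=2):
                if cell == NA_TOKEN:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {ci}"
                    ) from None
            feature_ids.append(fid)
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no features")

    keep = [s for s in matrix_samples if s in sheet]
    dropped = [s for s in matrix_samples if s not in sheet]
    if dropped:
        logger.info("%s: dropping %d sample(s) absent from sample sheet: %s",
                    path.name, len(dropped), ", ".join(dropped))
    missing_samples = [s for s in sheet if s not in matrix_samples]
    if missing_samples:
        raise FormatError(
            f"{path}: sample sheet sample(s) missing from matrix: "
            + ", ".join(missing_samples)
        )
    values = np.asarray(rows, dtype=float)
    col_of = {s: i for i, s in enumerate(matrix_samples)}
    ordered_samples = list(sheet)  # every sheet sample is present (checked above)
    order = [col_of[s] for s in ordered_samples]
    values = values[:, order]
    if layer is Layer.RNA and np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing value for rna feature {feature_ids[i]!r} "
            f"sample {ordered_samples[j]!r}"
        )
    if layer is Layer.RNA and np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative count for rna feature {feature_ids[i]!r} "
            f"sample {ordered_samples[j]!r}"
        )
    try:
        return OmicsMatrix(
            layer=layer,
            feature_ids=feature_ids,
            sample_ids=ordered_samples,
            values=values,
            groups={s: sheet[s] for s in ordered_samples},
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for i, fid in enumerate(m.feature_ids):
            cells = [
                NA_TOKEN if m.missing[i, j] else _fmt_num(m.values[i, j])
                for j in range(m.n_samples)
            ]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def write_sample_sheet(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in groups.items():
            fh.write(f"{sid}\t{grp}\n")


def _fmt_num(x: float) -> str:
    """Round-trippable decimal representation (shortest via repr)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: set_id TAB description TAB member..."""
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); need >= 3"
                )
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {sid!r} has no members")
            sets[sid] = (desc, tuple(members))
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


def read_idmap(path: str | Path) -> IdMap:
    """TSV with columns layer, feature_id, gene."""
    path = Path(path)
    df = _read_tsv(path, required=("layer", "feature_id", "gene"))
    mapping: dict[tuple[Layer, str], str] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            layer = _as_layer(str(row.layer))
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        key = (layer, str(row.feature_id))
        if key in mapping:
            raise FormatError(
                f"{path}:{lineno}: duplicate mapping for {layer.value}:{row.feature_id}"
            )
        mapping[key] = str(row.gene)
    return IdMap(mapping)


def write_idmap(idmap: IdMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("layer\tfeature_id\tgene\n")
        for (layer, fid), gene in idmap.mapping.items():
            fh.write(f"{layer.value}\t{fid}\t{gene}\n")


def read_drug_table(path: str | Path) -> DrugTargetTable:
    """TSV with columns gene, drug, modality, approval."""
    path = Path(path)
    df = _read_tsv(path, required=("gene", "drug", "modality", "approval"))
    rows: list[DrugRow] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            modality = Modality(str(row.modality).lower())
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: unknown modality {row.modality!r}; "
                f"allowed: {[m.value for m in Modality]}"
            ) from None
        try:
            approval = Approval(str(row.approval).lower())
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: unknown approval {row.approval!r}; "
                f"allowed: {[a.value for a in Approval]}"
            ) from None
        rows.append(DrugRow(str(row.gene), str(row.drug), modality, approval))
    try:
        return DrugTargetTable(tuple(rows))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_drug_table(table: DrugTargetTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdrug\tmodality\tapproval\n")
        for r in table.rows:
            fh.write(f"{r.gene}\t{r.drug}\t{r.modality.value}\t{r.approval.value}\n")


def read_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a JSON object")
    try:
        return PipelineConfig.from_dict(data)
    except (ValidationError, TypeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, no timestamps, trailing newline."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_tsv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df
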