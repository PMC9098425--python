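"""Shared data model for the multi-omics funnel pipeline.

The pipeline operates on three omics layers measured over a five-group
time course (an untreated control plus four post-exposure time points).
Everything downstream — differential calling, trend clustering, enrichment,
and target prioritization — consumes the small set of validated containers
defined here.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class OmicsFunnelError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(OmicsFunnelError):
    """A container invariant was violated."""


class FormatError(OmicsFunnelError):
    """A file could not be parsed into a valid container."""


class Layer(str, enum.Enum):
    RNA = "rna"
    PROTEIN = "protein"
    PHOSPHO = "phospho"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_layer(layer: "Layer | str") -> Layer:
    if isinstance(layer, Layer):
        return layer
    try:
        return Layer(str(layer).lower())
    except ValueError:
        raise ValidationError(
            f"unknown layer {layer!r}; expected one of "
            f"{[m.value for m in Layer]}"
        ) from None


class Modality(str, enum.Enum):
    INHIBITOR = "inhibitor"
    ACTIVATOR = "activator"
    OTHER = "other"


class Approval(str, enum.Enum):
    APPROVED = "approved"
    INVESTIGATIONAL = "investigational"


@dataclass(frozen=True)
class GroupDesign:
    """Ordered experimental groups with their time codes in weeks.

    The control group comes first at time 0 and time codes are strictly
    increasing, mirroring a single-exposure time-course design.
    """

    groups: tuple[str, ...]
    times: tuple[float, ...]
    control: str

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.times):
            raise ValidationError("groups and times must have equal length")
        if len(self.groups) < 2:
            raise ValidationError("need at least two groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValidationError("duplicate group labels")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("time codes must be strictly increasing")
        if self.control != self.groups[0]:
            raise ValidationError("control group must be first in time order")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def time_fractions(self) -> np.ndarray:
        """Times rescaled to [0, 1]."""
        t = np.asarray(self.times, dtype=float)
        span = t[-1] - t[0]
        return (t - t[0]) / span

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "times": list(self.times),
            "control": self.control,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupDesign":
        return cls(tuple(d["groups"]), tuple(float(t) for t in d["times"]), d["control"])


#: The five-group design used throughout: PBS control plus 2/4/6/10 weeks.
DEFAULT_DESIGN = GroupDesign(
    groups=("PBS", "2W", "4W", "6W", "10W"),
    times=(0.0, 2.0, 4.0, 6.0, 10.0),
    control="PBS",
)


@dataclass
class OmicsMatrix:
    """One omics layer: a feature × sample numeric matrix plus group labels.

    RNA values are non-negative counts; protein and phospho values are
    log-intensities where missing measurements are allowed.  Missing entries
    are tracked by the explicit boolean ``missing`` mask; the corresponding
    cells of ``values`` hold NaN purely for numpy convenience and the two
    representations are kept consistent by construction.
    """

    layer: Layer
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.layer = _as_layer(self.layer)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        dupf = _first_duplicate(self.feature_ids)
        if dupf is not None:
            raise ValidationError(f"duplicate feature id {dupf!r}")
        dups = _first_duplicate(self.sample_ids)
        if dups is not None:
            raise ValidationError(f"duplicate sample id {dups!r}")
        if len(self.feature_ids) == 0:
            raise ValidationError("no features")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValidationError("missing mask shape mismatch")
            if not np.array_equal(self.missing, np.isnan(self.values)):
                raise ValidationError("missing mask inconsistent with NaN cells")
        for s in self.sample_ids:
            if s not in self.groups:
                raise ValidationError(f"sample {s!r} missing from group assignment")
        counts: dict[str, int] = {}
        for s in self.sample_ids:
            counts[self.groups[s]] = counts.get(self.groups[s], 0) + 1
        for g, n in counts.items():
            if n < 2:
                raise ValidationError(f"group {g!r} has {n} sample(s); need >= 2")
        if self.layer is Layer.RNA:
            if self.missing.any():
                raise ValidationError("missing values are not permitted for the rna layer")
            if np.any(self.values < 0):
                raise ValidationError("rna counts must be non-negative")
        finite = self.values[~self.missing]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValidationError("non-finite value in matrix")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_columns(self, design: GroupDesign) -> dict[str, np.ndarray]:
        """Column indices per group, in design order."""
        out: dict[str, np.ndarray] = {}
        for g in design.groups:
            idx = [i for i, s in enumerate(self.sample_ids) if self.groups[s] == g]
            if not idx:
                raise ValidationError(f"design group {g!r} has no samples in matrix")
            out[g] = np.asarray(idx, dtype=int)
        return out

    def reindex_samples(self, sample_order: Sequence[str]) -> "OmicsMatrix":
        order = [self.sample_ids.index(s) for s in sample_order]
        return OmicsMatrix(
            layer=self.layer,
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_order),
            values=self.values[:, order].copy(),
            groups={s: self.groups[s] for s in sample_order},
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) keyed by set id."""

    sets: dict[str, tuple[str, tuple[str, ...]]]  # set_id -> (description, members)

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if len(members) < 1:
                raise ValidationError(f"gene set {sid!r} has no members")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {sid!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, sid: str) -> bool:
        return sid in self.sets

    def members(self, sid: str) -> tuple[str, ...]:
        return self.sets[sid][1]

    def description(self, sid: str) -> str:
        return self.sets[sid][0]

    def ids(self) -> list[str]:
        return list(self.sets)

    def sets_containing(self, gene: str) -> set[str]:
        return {sid for sid, (_, m) in self.sets.items() if gene in m}


@dataclass
class IdMap:
    """Mapping (layer, feature id) → gene symbol; many-to-one is allowed."""

    mapping: dict[tuple[Layer, str], str]

    def get(self, layer: "Layer | str", feature_id: str) -> str | None:
        return self.mapping.get((_as_layer(layer), feature_id))

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class DrugRow:
    gene: str
    drug: str
    modality: Modality
    approval: Approval


@dataclass
class DrugTargetTable:
    """Local gene → drug interaction table used for the repurposing screen."""

    rows: tuple[DrugRow, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.rows:
            key = (r.gene, r.drug)
            if key in seen:
                raise ValidationError(f"duplicate (gene, drug) pair {key!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def rows_for_gene(self, gene: str) -> list[DrugRow]:
        return [r for r in self.rows if r.gene == gene]


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run.

    One master ``seed`` feeds every source of randomness so a run is
    bit-reproducible from its config alone.
    """

    alpha: float = 0.05
    n_clusters: int = 6
    fuzzifier: float = 1.25
    membership_cutoff: float = 0.5
    trend_tau: float = 0.6
    top_k_pathways: int = 10
    min_set_size: int = 5
    max_set_size: int = 500
    min_obs_per_group: int = 2
    approved_only: bool = True
    seed: int = 0
    restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_clusters < 2:
            raise ValidationError("n_clusters must be >= 2")
        if self.fuzzifier <= 1.0:
            raise ValidationError("fuzzifier must be > 1")
        if not (0.0 < self.membership_cutoff <= 1.0):
            raise ValidationError("membership_cutoff must lie in (0, 1]")
        if self.min_set_size < 1 or self.max_set_size < self.min_set_size:
            raise ValidationError("invalid set size bounds")
        if self.restarts < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("invalid optimizer settings")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: d[k] for k in d})

    def digest(self) -> str:
        """Stable hash of the fully materialized configuration."""
        body = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(body.encode()).hexdigest()[:16]


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
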