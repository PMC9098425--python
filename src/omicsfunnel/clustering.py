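"""Temporal trend clustering of differential features (funnel stage C).

Group-mean profiles of the differential features are row-standardized and
soft-clustered with fuzzy c-means into K discrete expression clusters, the
convention popularized for omics time courses by Mfuzz.  Each cluster
centroid is then labelled consistently-up, consistently-down, or other by
the Kendall rank correlation of the centroid against time together with its
net change.  Features whose maximum membership exceeds the core cutoff are
the cluster's core members; with a cutoff > 0.5 a feature can be a core
member of at most one cluster, which is what makes the funnel's set C
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GroupDesign,
    Layer,
    OmicsFunnelError,
    OmicsMatrix,
    PipelineConfig,
    ValidationError,
)
from .differential import DifferentialResult
from .io import logger

__all__ = [
    "TrendLabel",
    "FCMFit",
    "ClusterModel",
    "standardize_profiles",
    "fuzzy_cmeans",
    "kendall_tau_a",
    "classify_trend",
    "cluster_layer",
    "pca_qc",
]


# --------------------------------------------------------------------------
# profile standardization

def standardize_profiles(
    de: DifferentialResult,
    design: GroupDesign,
    features: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Row-standardized group-mean profiles of the differential features.

    Each profile (the T group means in time order) is rescaled to mean 0
    and sample standard deviation 1 (n−1 denominator).  Constant profiles
    cannot be standardized and are dropped with a log entry.  Returns the
    standardized profile frame and the list of dropped features.
    """
    if features is None:
        features = de.significant
    means = de.group_means().loc[features]
    x = means.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = [f for f, k in zip(features, keep) if not k]
    if dropped:
        logger.info(
            "%s: dropped %d constant profile(s) before clustering",
            de.layer.value, len(dropped),
        )
    z = (x[keep] - mu[keep]) / sd[keep]
    frame = pd.DataFrame(z, index=[f for f, k in zip(features, keep) if k],
                         columns=list(design.groups))
    return frame, dropped


# --------------------------------------------------------------------------
# fuzzy c-means

@dataclass
class FCMFit:
    centroids: np.ndarray  # K x T
    memberships: np.ndarray  # n x K
    objective: float
    n_iter: int
    objective_trace: np.ndarray


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances (n × K).

    u_ik = 1 / Σ_j (d_ik/d_ij)^(2/(m−1)).  A point coincident with one or
    more centroids splits its membership equally among the coincident
    centroids (the documented zero-distance convention).
    """
    n, K = d2.shape
    u = np.zeros((n, K))
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    if any_zero.any():
        z = zero[any_zero]
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    reg = ~any_zero
    if reg.any():
        # (d_ik/d_ij)^(2/(m-1)) with squared distances -> power 1/(m-1)
        powd = d2[reg] ** (-1.0 / (m - 1.0))
        u[reg] = powd / powd.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    profiles: np.ndarray,
    K: int,
    m: float,
    seed: int,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    init_centroids: np.ndarray | None = None,
) -> FCMFit:
    """Fuzzy c-means with Euclidean distance and multi-restart initialization.

    Alternates the membership and centroid updates until the objective
    Σ_ik u_ik^m d_ik² changes by less than ``tol`` or ``max_iter`` is hit;
    keeps the best of ``restarts`` initializations (centroids drawn from
    distinct data rows) by lowest converged objective.  Supplying
    ``init_centroids`` runs a single fit from that start (used by the
    exhaustive-initialization oracle in the tests).
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValidationError("profiles must be a 2-d array")
    n = X.shape[0]
    if K < 2:
        raise ValidationError("K must be >= 2")
    if m <= 1.0:
        raise ValidationError("fuzzifier must be > 1")
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < K:
        raise ValidationError(
            f"need >= K={K} distinct profiles, have {distinct.shape[0]}"
        )

    def run(c0: np.ndarray) -> FCMFit:
        c = c0.copy()
        trace: list[float] = []
        prev = np.inf
        u = None
        for it in range(1, max_iter + 1):
            d2 = ((X[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
            u = _fcm_memberships(d2, m)
            um = u ** m
            obj = float((um * d2).sum())
            trace.append(obj)
            w = um.sum(axis=0)
            # a cluster abandoned by all points keeps its previous centroid
            nz = w > 0
            c_new = c.copy()
            c_new[nz] = (um.T[nz] @ X) / w[nz, None]
            if prev - obj < tol:
                c = c_new
                break
            c = c_new
            prev = obj
        arr = np.asarray(trace)
        if np.any(np.diff(arr) > 1e-8):  # objective must never increase
            raise OmicsFunnelError("fuzzy c-means objective increased")
        return FCMFit(c, u, float(arr[-1]), len(arr), arr)

    if init_centroids is not None:
        c0 = np.asarray(init_centroids, dtype=float)
        if c0.shape != (K, X.shape[1]):
            raise ValidationError("init_centroids shape mismatch")
        return run(c0)

    rng = np.random.default_rng(seed)
    best: FCMFit | None = None
    for _ in range(restarts):
        rows = rng.choice(distinct.shape[0], size=K, replace=False)
        fit = run(distinct[rows])
        if best is None or fit.objective < best.objective:
            best = fit
    assert best is not None
    return best


# --------------------------------------------------------------------------
# trend labelling

def kendall_tau_a(x, y) -> float:
    """Kendall tau by exhaustive pair counting, tau-a convention.

    tau = (concordant − discordant) / (n(n−1)/2); tied pairs count toward
    neither, which conservatively pulls flat-ish profiles toward "other".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 2:
        raise ValidationError("kendall_tau_a needs two equal-length sequences, n >= 2")
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(x[i + 1:] - x[i]) * np.sign(y[i + 1:] - y[i])))
    return 2.0 * s / (n * (n - 1))


@dataclass(frozen=True)
class TrendLabel:
    label: str  # up | down | other
    tau: float
    net_change: float


def classify_trend(centroid, times, trend_tau: float = 0.6) -> TrendLabel:
    """Label a centroid consistently-up/-down/other.

    "up" requires Kendall tau(centroid, time) ≥ trend_tau and a positive
    net change (last − first); "down" is symmetric; anything else —
    transient bumps, oscillations, weak drifts — is "other".
    """
    c = np.asarray(centroid, dtype=float)
    t = np.asarray(times, dtype=float)
    if c.size != t.size or c.size < 3:
        raise ValidationError("centroid and times must have equal length >= 3")
    tau = kendall_tau_a(c, t)
    net = float(c[-1] - c[0])
    if tau >= trend_tau and net > 0:
        label = "up"
    elif tau <= -trend_tau and net < 0:
        label = "down"
    else:
        label = "other"
    return TrendLabel(label, float(tau), net)


# --------------------------------------------------------------------------
# layer driver

@dataclass
class ClusterModel:
    """Fitted trend clustering for one layer.

    Soft memberships row-normalize to 1; ``core_members`` lists, per
    cluster, the features whose membership in it reaches the cutoff.
    """

    layer: Layer
    design: GroupDesign
    profiles: pd.DataFrame  # features x T (standardized)
    K: int
    fuzzifier: float
    centroids: np.ndarray  # K x T
    memberships: pd.DataFrame  # features x K
    objective: float
    n_iter: int
    seed: int
    trend_labels: list[TrendLabel]
    membership_cutoff: float
    dropped: list[str]
    config_digest: str

    @property
    def core_members(self) -> dict[int, list[str]]:
        u = self.memberships.to_numpy()
        out: dict[int, list[str]] = {k: [] for k in range(self.K)}
        # ties in argmax broken by lowest cluster index (np.argmax convention)
        best = np.argmax(u, axis=1)
        reach = u[np.arange(u.shape[0]), best] >= self.membership_cutoff
        for f, k, ok in zip(self.memberships.index, best, reach):
            if ok:
                out[int(k)].append(f)
        return out

    def hard_labels(self) -> pd.Series:
        u = self.memberships.to_numpy()
        return pd.Series(np.argmax(u, axis=1), index=self.memberships.index)

    def clusters_with_label(self, label: str) -> list[int]:
        return [k for k, t in enumerate(self.trend_labels) if t.label == label]

    def core_features_with_label(self, label: str) -> list[str]:
        cores = self.core_members
        out: list[str] = []
        for k in self.clusters_with_label(label):
            out.extend(cores[k])
        return out

    @classmethod
    def from_tsv(
        cls, centroids_path, memberships_path, labels_path,
        layer, design, cfg,
    ) -> "ClusterModel":
        """Rebuild a model from stage files (profiles are not preserved)."""
        cdf = pd.read_csv(centroids_path, sep="\t")
        centroids = cdf[list(design.groups)].to_numpy(dtype=float)
        mdf = pd.read_csv(memberships_path, sep="\t", dtype={"feature_id": str})
        mdf = mdf.set_index("feature_id")
        mdf.index.name = None
        ldf = pd.read_csv(labels_path, sep="\t")
        labels = [
            TrendLabel(str(r.label), float(r.tau), float(r.net_change))
            for r in ldf.itertuples(index=False)
        ]
        K = centroids.shape[0]
        return cls(
            layer=Layer(layer),
            design=design,
            profiles=pd.DataFrame(columns=list(design.groups)),
            K=K,
            fuzzifier=cfg.fuzzifier,
            centroids=centroids,
            memberships=mdf,
            objective=float("nan"),
            n_iter=0,
            seed=cfg.seed,
            trend_labels=labels,
            membership_cutoff=cfg.membership_cutoff,
            dropped=[],
            config_digest=cfg.digest(),
        )

    def write_tsv(self, centroids_path, memberships_path, labels_path) -> None:
        cols = list(self.design.groups)
        cdf = pd.DataFrame(self.centroids, columns=cols)
        cdf.insert(0, "cluster", range(self.K))
        cdf.to_csv(centroids_path, sep="\t", index=False)
        mdf = self.memberships.copy()
        mdf.insert(0, "feature_id", mdf.index)
        mdf.to_csv(memberships_path, sep="\t", index=False)
        ldf = pd.DataFrame(
            {
                "cluster": range(self.K),
                "label": [t.label for t in self.trend_labels],
                "tau": [t.tau for t in self.trend_labels],
                "net_change": [t.net_change for t in self.trend_labels],
                "n_core": [len(v) for v in self.core_members.values()],
            }
        )
        ldf.to_csv(labels_path, sep="\t", index=False)


def cluster_layer(
    de: DifferentialResult,
    design: GroupDesign,
    cfg: PipelineConfig,
    seed: int | None = None,
) -> ClusterModel:
    """Standardize the layer's differential profiles and cluster them."""
    profiles, dropped = standardize_profiles(de, design)
    if seed is None:
        # derive a per-layer stream from the master seed
        seed = int(
            np.random.SeedSequence(
                [cfg.seed, {"rna": 1, "protein": 2, "phospho": 3}[de.layer.value]]
            ).generate_state(1)[0] % (2**31)
        )
    fit = fuzzy_cmeans(
        profiles.to_numpy(),
        K=cfg.n_clusters,
        m=cfg.fuzzifier,
        seed=seed,
        restarts=cfg.restarts,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
    )
    times = np.asarray(design.times, dtype=float)
    labels = [classify_trend(c, times, cfg.trend_tau) for c in fit.centroids]
    return ClusterModel(
        layer=de.layer,
        design=design,
        profiles=profiles,
        K=cfg.n_clusters,
        fuzzifier=cfg.fuzzifier,
        centroids=fit.centroids,
        memberships=pd.DataFrame(
            fit.memberships, index=profiles.index,
            columns=[f"c{k}" for k in range(cfg.n_clusters)],
        ),
        objective=fit.objective,
        n_iter=fit.n_iter,
        seed=seed,
        trend_labels=labels,
        membership_cutoff=cfg.membership_cutoff,
        dropped=dropped,
        config_digest=cfg.digest(),
    )


# --------------------------------------------------------------------------
# PCA QC

@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x 2
    variance_explained: tuple[float, ...]


def pca_qc(m: OmicsMatrix, n_components: int = 2) -> PCAResult:
    """Sample scores on the first principal components of one layer.

    Column-centered SVD on features × samples (missing entries replaced by
    the feature mean before centering).  Deterministic sign convention:
    within each component the loading of largest magnitude is positive.
    """
    if m.n_samples < 3:
        raise ValidationError("pca_qc needs >= 3 samples")
    X = m.values.T.copy()  # samples x features
    if m.missing.any():
        fm = np.nanmean(m.values, axis=1)
        idx = np.where(m.missing.T)
        X[idx] = fm[idx[1]]
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    ncomp = min(n_components, S.size)
    for c in range(ncomp):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    scores = U[:, :ncomp] * S[:ncomp]
    var = S**2
    ratio = tuple(float(v) for v in (var / var.sum())[:ncomp])
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=m.sample_ids, columns=[f"PC{i+1}" for i in range(ncomp)]
        ),
        variance_explained=ratio,
    )
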