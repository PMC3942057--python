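"""Bootstrapped KL-NMF signature extraction and rank selection.

The factorization minimizes the generalized Kullback-Leibler divergence
with multiplicative updates (the natural objective for Poisson-like count
matrices). Rank stability is assessed by bootstrapping mutation counts
per sample, clustering the pooled replicate signatures, and measuring the
cophenetic correlation of the sample co-assignment consensus matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .errors import InsufficientDataError, ValidationError
from .scheme import DEFAULT_SCHEME, CategoryScheme

logger = logging.getLogger(__name__)

_EPS = 1e-12


def child_seed(master: int, *path: int) -> int:
    """Derive a stage seed from a master seed and an integer counter path."""
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# core factorization


def kl_divergence(M: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(M || WH) = sum m*log(m/wh) - m + wh."""
    WH = np.maximum(WH, _EPS)
    mask = M > 0
    term = np.sum(M[mask] * np.log(M[mask] / WH[mask]))
    return float(term - M.sum() + WH.sum())


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    divergence: float
    n_iter: int
    history: list[float] | None = None


def _init_factors(M: np.ndarray, r: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    m, n = M.shape
    # uniform(0,1] entries scaled so that mean(WH) ~ mean(M)
    W = 1.0 - rng.random((m, r))
    H = 1.0 - rng.random((r, n))
    scale = np.sqrt(M.mean() / max(r * W.mean() * H.mean(), _EPS))
    return W * scale, H * scale


def nmf_factorize(
    M: np.ndarray,
    r: int,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    track_objective: bool = False,
    update_W: bool = True,
) -> NMFResult:
    """Multiplicative-update KL-NMF.

    Stops when the relative objective decrease falls below ``tol`` or after
    ``max_iter`` iterations. Deterministic for a fixed seed. ``init`` may
    supply explicit (W, H) starting factors (e.g. to continue a run);
    ``update_W=False`` refits exposures against a fixed signature matrix.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValidationError("M must be a 2-D matrix")
    if np.any(M < 0):
        raise ValidationError("M must be non-negative")
    if not np.any(M > 0):
        raise ValidationError("M is all zero; nothing to factorize")
    if not (1 <= r <= min(M.shape)):
        raise ValidationError(f"rank {r} out of range for matrix of shape {M.shape}")

    rng = np.random.default_rng(seed)
    if init is not None:
        W = np.asarray(init[0], dtype=float).copy()
        H = np.asarray(init[1], dtype=float).copy()
        if W.shape != (M.shape[0], r) or H.shape != (r, M.shape[1]):
            raise ValidationError("init factor shapes do not match M and r")
    else:
        W, H = _init_factors(M, r, rng)

    row_ones = np.ones(M.shape[1])
    prev = np.inf
    history: list[float] | None = [] if track_objective else None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        R = M / WH
        if update_W:
            W *= (R @ H.T) / np.maximum(H @ row_ones, _EPS)
            WH = np.maximum(W @ H, _EPS)
            R = M / WH
        H *= (W.T @ R) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        div = kl_divergence(M, W @ H)
        if history is not None:
            history.append(div)
        if prev - div <= tol * max(abs(prev), 1.0) and np.isfinite(prev):
            prev = div
            break
        prev = div
    return NMFResult(W=W, H=H, divergence=prev, n_iter=n_iter, history=history)


def best_of_restarts(
    M: np.ndarray,
    r: int,
    n_restarts: int,
    seed: int,
    max_iter: int = 2_000,
    tol: float = 1e-6,
    restart_iter: int = 100,
) -> NMFResult:
    """Run ``n_restarts`` short factorizations, refine the best to convergence."""
    best: NMFResult | None = None
    best_k = 0
    for k in range(n_restarts):
        res = nmf_factorize(M, r, seed=child_seed(seed, k), max_iter=restart_iter, tol=0.0)
        if best is None or res.divergence < best.divergence:
            best, best_k = res, k
    assert best is not None
    refined = nmf_factorize(
        M, r, seed=child_seed(seed, best_k), max_iter=max_iter, tol=tol, init=(best.W, best.H)
    )
    return refined


def normalize_signatures(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Move column scale of W into rows of H so W is column-stochastic.

    Preserves the product W @ H exactly.
    """
    scale = W.sum(axis=0)
    scale_safe = np.where(scale > 0, scale, 1.0)
    return W / scale_safe, H * scale[:, None]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SignatureSet:
    """Column-stochastic 96 x r signature matrix with stability scores."""

    W: np.ndarray
    signature_ids: list[str]
    scheme: CategoryScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    stability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (96, len(self.signature_ids)):
            raise ValidationError("W must be 96 x r with one id per column")
        if np.any(self.W < 0):
            raise ValidationError("signatures must be non-negative")
        sums = self.W.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("signature columns must sum to 1")

    @property
    def r(self) -> int:
        return self.W.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(self.scheme.labels), columns=self.signature_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "category"
        df.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class ExposureMatrix:
    """Raw r x N signature loads plus per-sample relative loads."""

    H: np.ndarray
    sample_ids: list[str]
    signature_ids: list[str]
    degenerate: np.ndarray | None = None  # all-zero samples, uniform relative loads

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (len(self.signature_ids), len(self.sample_ids)):
            raise ValidationError("H must be r x N matching the id lists")
        if np.any(self.H < 0):
            raise ValidationError("exposures must be non-negative")
        if self.degenerate is None:
            self.degenerate = ~(self.H.sum(axis=0) > 0)

    @property
    def relative(self) -> np.ndarray:
        return relative_exposures(self.H)[0]

    def row(self, signature_id: str, relative: bool = False) -> np.ndarray:
        i = self.signature_ids.index(signature_id)
        return (self.relative if relative else self.H)[i]

    def to_frame(self, relative: bool = False) -> pd.DataFrame:
        data = self.relative if relative else self.H
        return pd.DataFrame(data, index=self.signature_ids, columns=self.sample_ids)

    def write_tsv(self, path, relative: bool = False) -> None:
        df = self.to_frame(relative=relative)
        df.index.name = "signature"
        df.to_csv(path, sep="\t", float_format="%.6g")


def relative_exposures(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-normalize loads so each sample's loads sum to 1.

    All-zero samples get uniform 1/r loads and are flagged. Returns
    (relative matrix, degenerate-column boolean mask).
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValidationError("exposures must be non-negative")
    totals = H.sum(axis=0)
    degenerate = ~(totals > 0)
    rel = np.where(degenerate[None, :], 1.0 / H.shape[0], H / np.where(degenerate, 1.0, totals))
    return rel, degenerate


# ---------------------------------------------------------------------------
# metrics


def hoyer_sparseness(v: np.ndarray) -> float:
    """Hoyer sparseness (sqrt(n) - l1/l2) / (sqrt(n) - 1) in [0, 1]."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("hoyer_sparseness expects a 1-D vector of length >= 2")
    if np.any(v < 0):
        raise ValidationError("vector must be non-negative")
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ValidationError("sparseness undefined for the zero vector")
    n = np.sqrt(v.size)
    value = (n - np.abs(v).sum() / l2) / (n - 1.0)
    return float(min(max(value, 0.0), 1.0))


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus co-clustering matrix.

    Distances 1 - consensus are hierarchically clustered (average linkage);
    the returned value is the Pearson correlation between those distances
    and the cophenetic distances of the dendrogram. A constant distance
    matrix is degenerate and defined as 1 (with a warning).
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("consensus must be square")
    if not np.allclose(C, C.T, atol=1e-9):
        raise ValidationError("consensus must be symmetric")
    if np.any(C < -1e-9) or np.any(C > 1 + 1e-9):
        raise ValidationError("consensus entries must lie in [0, 1]")
    if not np.allclose(np.diag(C), 1.0, atol=1e-9):
        raise ValidationError("consensus diagonal must be 1")
    D = 1.0 - np.clip(C, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if condensed.size == 0 or np.ptp(condensed) < 1e-12:
        warnings.warn("constant consensus distances; cophenetic coefficient degenerate, returning 1")
        return 1.0
    Z = average(condensed)
    with np.errstate(invalid="ignore"):
        c, _ = cophenet(Z, condensed)
    if not np.isfinite(c):
        warnings.warn("degenerate cophenetic distances; returning 1")
        return 1.0
    return float(c)


# ---------------------------------------------------------------------------
# consensus clustering of pooled bootstrap signatures


def _cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    sim = (X / norms[:, None]) @ (X / norms[:, None]).T
    return np.clip(1.0 - sim, 0.0, 2.0)


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int = 8,
              max_iter: int = 200) -> np.ndarray:
    """Alternating k-medoids on a precomputed distance matrix.

    Deterministic given the generator state; ties broken toward the lowest
    index. Returns integer labels in [0, k).
    """
    n = D.shape[0]
    if k > n:
        raise ValidationError(f"cannot form {k} clusters from {n} points")
    best_labels: np.ndarray | None = None
    best_cost = np.inf
    for _ in range(n_restarts):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.where(labels == c)[0]
                if members.size == 0:
                    continue  # keep the old medoid; cluster re-forms next sweep
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[int(np.argmin(within))]
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = float(D[np.arange(n), medoids[labels]].sum())
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_labels = labels
    assert best_labels is not None
    # deterministic relabeling: clusters ordered by their first member index
    order = {}
    for idx in range(n):
        c = best_labels[idx]
        if c not in order:
            order[c] = len(order)
    return np.array([order[c] for c in best_labels], dtype=int)


def _cluster_stability(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean silhouette per cluster; defined as 1 for a single cluster."""
    k = labels.max() + 1
    if k == 1:
        return np.ones(1)
    sil = silhouette_samples(D, labels, metric="precomputed")
    return np.array([sil[labels == c].mean() if np.any(labels == c) else -1.0 for c in range(k)])


def _multinomial_resample(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample each sample's counts multinomially, preserving column totals."""
    out = np.zeros_like(M, dtype=float)
    for j in range(M.shape[1]):
        total = M[:, j].sum()
        if total <= 0:
            continue
        p = M[:, j] / total
        out[:, j] = rng.multinomial(int(round(total)), p)
    return out


@dataclass
class BootstrapExtraction:
    signatures: SignatureSet
    exposures: ExposureMatrix
    consensus: np.ndarray
    replicate_divergences: list[float]
    pooled_labels: np.ndarray


def bootstrap_extract(
    M: np.ndarray,
    r: int,
    n_bootstrap: int = 10,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 2_000,
    tol: float = 1e-5,
    restart_iter: int = 100,
    resample: str = "multinomial",
    sample_ids: Sequence[str] | None = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> tuple[SignatureSet, ExposureMatrix, np.ndarray]:
    """Consensus signatures from bootstrapped best-of-restarts factorizations.

    Each bootstrap replicate resamples every sample's mutation counts
    multinomially (column totals preserved), is factorized with the best of
    ``n_restarts`` seeded initializations, and contributes r signatures to a
    pool that is partitioned into r clusters by cosine k-medoids. Cluster
    centroids (renormalized) form the consensus signatures; per-cluster mean
    silhouette is the stability. Exposures are refit against the consensus
    W on the original matrix under the same KL objective. The returned
    consensus matrix is the N x N sample co-assignment frequency (dominant
    signature agreement across replicates).
    """
    M = np.asarray(M, dtype=float)
    if n_bootstrap < 2:
        raise ValidationError("n_bootstrap must be >= 2")
    if resample not in ("multinomial", "none"):
        raise ValidationError(f"unknown resampling scheme {resample!r}")
    if sample_ids is None:
        sample_ids = [f"sample{j + 1}" for j in range(M.shape[1])]
    sample_ids = list(sample_ids)

    nonzero = M.sum(axis=0) > 0
    M_fit = M[:, nonzero]
    if M_fit.shape[1] == 0:
        raise ValidationError("all samples have zero mutations")
    if r > min(96, M_fit.shape[1]):
        raise ValidationError(f"rank {r} exceeds the number of non-degenerate samples")

    rng = np.random.default_rng(child_seed(seed, 0))
    pooled_W: list[np.ndarray] = []
    dominant: list[np.ndarray] = []  # per replicate: dominant pooled-signature index per sample
    divergences: list[float] = []
    for b in range(n_bootstrap):
        Mb = _multinomial_resample(M_fit, rng) if resample == "multinomial" else M_fit
        res = best_of_restarts(
            Mb, r, n_restarts=n_restarts, seed=child_seed(seed, 1, b),
            max_iter=max_iter, tol=tol, restart_iter=restart_iter,
        )
        Wb, Hb = normalize_signatures(res.W, res.H)
        pooled_W.append(Wb)
        dominant.append(np.argmax(Hb, axis=0))
        divergences.append(res.divergence)

    pool = np.concatenate(pooled_W, axis=1).T  # (n_bootstrap * r) x 96
    D = _cosine_distance_matrix(pool)
    labels = _kmedoids(D, r, np.random.default_rng(child_seed(seed, 2)))
    if len(set(labels.tolist())) < r:
        # one reseeded retry, then hard failure
        logger.warning("degenerate signature clustering; retrying with a fresh seed")
        labels = _kmedoids(D, r, np.random.default_rng(child_seed(seed, 3)))
        if len(set(labels.tolist())) < r:
            raise InsufficientDataError("signature clustering produced an empty cluster")

    W_cons = np.zeros((96, r))
    for c in range(r):
        members = pool[labels == c]
        W_cons[:, c] = members.mean(axis=0)
    W_cons /= W_cons.sum(axis=0, keepdims=True)
    stability = _cluster_stability(D, labels)

    # sample co-assignment consensus over replicates (non-degenerate samples)
    n_fit = M_fit.shape[1]
    consensus = np.zeros((n_fit, n_fit))
    for b, dom in enumerate(dominant):
        cluster_of = labels[b * r : (b + 1) * r]
        assigned = cluster_of[dom]
        consensus += assigned[:, None] == assigned[None, :]
    consensus /= n_bootstrap
    np.fill_diagonal(consensus, 1.0)

    # refit exposures on the original matrix with W fixed
    H_fit = refit_exposures(M_fit, W_cons, max_iter=max_iter, tol=tol)
    H_full = np.zeros((r, M.shape[1]))
    H_full[:, nonzero] = H_fit

    sig_ids = [f"sig{c + 1}" for c in range(r)]
    signatures = SignatureSet(W=W_cons, signature_ids=sig_ids, scheme=scheme, stability=stability)
    exposures = ExposureMatrix(H=H_full, sample_ids=sample_ids, signature_ids=sig_ids)
    return signatures, exposures, consensus


def refit_exposures(M: np.ndarray, W: np.ndarray, max_iter: int = 2_000,
                    tol: float = 1e-6) -> np.ndarray:
    """KL-optimal non-negative loads for a fixed signature matrix.

    Deterministic and column-separable: each sample's loads depend only on
    its own counts (the objective is convex in H, and the uniform start
    makes the multiplicative updates reproducible).
    """
    M = np.asarray(M, dtype=float)
    r, n = W.shape[1], M.shape[1]
    H = np.tile(np.maximum(M.sum(axis=0), _EPS) / r, (r, 1))
    res = nmf_factorize(M, r, seed=0, max_iter=max_iter, tol=tol, init=(W.copy(), H),
                        update_W=False)
    return res.H


# ---------------------------------------------------------------------------
# rank selection


@dataclass
class RankSelectionReport:
    """Per-rank quality metrics and the selected factorization rank."""

    table: pd.DataFrame  # rank, divergence, cophenetic, sparseness, stability, error
    chosen_rank: int
    rationale: str

    def write(self, tsv_path, json_path=None) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
        if json_path is not None:
            import json

            payload = {
                "chosen_rank": self.chosen_rank,
                "rationale": self.rationale,
                "ranks": self.table.to_dict(orient="records"),
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2, default=str)


def select_rank(
    M: np.ndarray,
    rank_range: Iterable[int],
    n_bootstrap: int = 10,
    n_restarts: int = 20,
    seed: int = 0,
    cophenetic_threshold: float = 0.95,
    stability_threshold: float = 0.8,
    max_iter: int = 2_000,
    tol: float = 1e-5,
    restart_iter: int = 100,
) -> RankSelectionReport:
    """Scan candidate ranks and pick the factorization rank.

    Rule: the largest rank whose cophenetic coefficient and mean stability
    both clear their thresholds; if none qualifies, the rank with maximal
    cophenetic coefficient. Per-rank failures are recorded, not fatal.
    """
    ranks = sorted(set(int(r) for r in rank_range))
    if not ranks:
        raise ValidationError("empty rank range")
    M = np.asarray(M, dtype=float)

    rows = []
    for r in ranks:
        row: dict = {"rank": r, "divergence": np.nan, "cophenetic": np.nan,
                     "sparseness": np.nan, "stability": np.nan, "error": ""}
        try:
            best = best_of_restarts(
                M[:, M.sum(axis=0) > 0], r, n_restarts=n_restarts,
                seed=child_seed(seed, 10, r), max_iter=max_iter, tol=tol,
                restart_iter=restart_iter,
            )
            sigs, _, consensus = bootstrap_extract(
                M, r, n_bootstrap=n_bootstrap, n_restarts=n_restarts,
                seed=child_seed(seed, 20, r), max_iter=max_iter, tol=tol,
                restart_iter=restart_iter,
            )
            row["divergence"] = best.divergence
            row["cophenetic"] = cophenetic_coefficient(consensus)
            row["sparseness"] = float(np.mean([hoyer_sparseness(sigs.W[:, c]) for c in range(r)]))
            row["stability"] = float(np.mean(sigs.stability))
        except (ValidationError, InsufficientDataError) as exc:
            row["error"] = str(exc)
            logger.warning("rank %d failed: %s", r, exc)
        rows.append(row)

    table = pd.DataFrame(rows)
    ok = table[(table["cophenetic"] >= cophenetic_threshold)
               & (table["stability"] >= stability_threshold)]
    if len(ok):
        chosen = int(ok["rank"].max())
        rationale = (
            f"largest rank with cophenetic >= {cophenetic_threshold} and "
            f"mean stability >= {stability_threshold}"
        )
    else:
        valid = table.dropna(subset=["cophenetic"])
        if valid.empty:
            raise InsufficientDataError("no rank produced a valid factorization")
        chosen = int(valid.loc[valid["cophenetic"].idxmax(), "rank"])
        rationale = "no rank cleared both thresholds; rank with maximal cophenetic coefficient"
    return RankSelectionReport(table=table, chosen_rank=chosen, rationale=rationale)
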