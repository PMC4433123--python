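"""Unsupervised voxel classifiers and the multi-start fitting protocol.

Four classifiers over per-voxel feature vectors x_n in R^D:

* **K-means** — Lloyd iterations minimizing the within-cluster sum of squared
  point-to-centroid distances.  Statistically this is a Gaussian mixture with
  shared identity covariance, uniform priors and hard assignments.
* **Fuzzy K-means** — soft memberships u_nc with fuzzifier m (> 1), exact
  alternating minimization of sum_n sum_c u_nc^m ||x_n - mu_c||^2.
* **GMM** — full-covariance Gaussian mixture fit by EM; the negative
  log-likelihood is non-increasing every iteration.
* **GHMRF** — Gaussian emission model with an Ising spatial prior on the
  label field: E(Y) = sum_n -log N(x_n | mu_{y_n}, S_{y_n})
  + beta * sum_{(n,m) in Q} [y_n != y_m] over 6-connected in-mask voxel
  pairs Q.  Fit by hard EM: an ICM labelling step (fixed lexicographic visit
  order, ties to the lowest label, energy non-increasing) alternating with
  maximum-likelihood Gaussian parameter updates.

The fitting protocol draws ``n_inits`` K-means++ seedings, keeps the
``keep`` best by mean nearest-seed squared distance, fits each, and selects
the best fit: lowest distance objective for the K-means variants, lowest
mixture negative log-likelihood for GMM/GHMRF.  Everything is deterministic
given the seed.

Labels are 1-based in :class:`Labelling` (class 0 is reserved for
background in label volumes); internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

from .volume_io import FeatureMatrix

DEFAULT_N_CLASSES = 14  # 7 tissues x 2 Gaussians each
DEFAULT_BETA = 1.0
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200
DEFAULT_ICM_SWEEPS = 5
COV_RIDGE = 1e-6

ALGORITHMS = ("kmeans", "fuzzy", "gmm", "ghmrf")


@dataclass
class ClusterModel:
    """Per-class Gaussian parameters plus fit diagnostics.

    ``nll`` holds the final negative log-likelihood for gmm/ghmrf and the
    final distance objective for the K-means variants.
    """

    n_classes: int
    means: np.ndarray        # (C, D)
    covariances: np.ndarray  # (C, D, D)
    priors: np.ndarray       # (C,)
    model_kind: str
    nll: float
    n_iter: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if (self.priors < -1e-12).any() or abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must be non-negative and sum to 1")


@dataclass
class Labelling:
    """Per-voxel class assignment (1..C) with optional soft memberships."""

    assignment: np.ndarray               # (N,) ints in 1..C
    n_classes: int
    memberships: np.ndarray | None = None  # (N, C), rows sum to 1

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int32)
        if self.assignment.min(initial=1) < 1 or self.assignment.max(initial=1) > self.n_classes:
            raise ValueError("assignment labels must lie in 1..C")
        if self.memberships is not None:
            u = np.asarray(self.memberships, dtype=float)
            if (u < -1e-12).any() or np.abs(u.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("membership rows must be non-negative and sum to 1")
            self.memberships = u


@dataclass
class MrfSpec:
    """Ising pairwise structure over in-mask voxels (6-connectivity)."""

    neighbour_pairs: np.ndarray  # (M, 2) row indices into the feature matrix
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        pairs = np.asarray(self.neighbour_pairs, dtype=np.int64).reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        self.neighbour_pairs = np.unique(pairs, axis=0) if len(pairs) else pairs


def mrf_from_mask(mask: np.ndarray, beta: float = DEFAULT_BETA) -> MrfSpec:
    """Build the 6-connected pair list matching lexicographic voxel order."""
    mask = np.asarray(mask) > 0
    rank = np.full(mask.shape, -1, dtype=np.int64)
    rank[mask] = np.arange(int(mask.sum()))
    pairs = []
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        ra, rb = rank[tuple(a)], rank[tuple(b)]
        ok = (ra >= 0) & (rb >= 0)
        pairs.append(np.column_stack([ra[ok], rb[ok]]))
    all_pairs = np.vstack(pairs) if pairs else np.empty((0, 2), dtype=np.int64)
    return MrfSpec(neighbour_pairs=all_pairs, beta=beta)


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _sq_dists(x: np.ndarray, centres: np.ndarray) -> np.ndarray:
    """(N, C) squared Euclidean distances."""
    return np.maximum(
        (x * x).sum(1)[:, None] - 2.0 * x @ centres.T + (centres * centres).sum(1)[None, :],
        0.0)


# ---------------------------------------------------------------------------
# seeding


def kmeanspp_seed(features, n_classes: int, rng_seed: int) -> np.ndarray:
    """One K-means++ seeding: first seed uniform, then D^2 sampling."""
    x = _as_array(features)
    n = x.shape[0]
    if n_classes < 1 or n_classes > n:
        raise ValueError(f"need 1 <= C <= N, got C={n_classes}, N={n}")
    rng = np.random.default_rng(rng_seed)
    seeds = np.empty((n_classes, x.shape[1]))
    idx = int(rng.integers(n))
    seeds[0] = x[idx]
    closest = ((x - seeds[0]) ** 2).sum(1)
    for c in range(1, n_classes):
        total = closest.sum()
        if total <= 0:  # all remaining points coincide with a seed
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=closest / total))
        seeds[c] = x[idx]
        closest = np.minimum(closest, ((x - seeds[c]) ** 2).sum(1))
    return seeds


def seeding_score(features, seeds: np.ndarray) -> float:
    """Mean over points of squared distance to the nearest seed."""
    x = _as_array(features)
    return float(_sq_dists(x, np.asarray(seeds, dtype=float)).min(axis=1).mean())


def rank_seedings(features, seed_sets: list[np.ndarray], keep: int = 10) -> list[np.ndarray]:
    """Keep the lowest-scoring seed sets (ties broken by input order).

    Exact-duplicate seed sets (which occur when the data has few distinct
    rows) collapse to their first occurrence, so the kept candidates are
    distinct initializations.  Fewer than ``keep`` sets may be returned in
    that case.
    """
    if not seed_sets:
        raise ValueError("no seed sets given")
    if keep > len(seed_sets):
        raise ValueError("keep exceeds number of seed sets")
    unique: list[np.ndarray] = []
    for s in seed_sets:
        if not any(np.array_equal(s, u) for u in unique):
            unique.append(s)
    scores = np.array([seeding_score(features, s) for s in unique])
    order = np.argsort(scores, kind="stable")[:keep]
    return [unique[i] for i in order]


# ---------------------------------------------------------------------------
# K-means variants


def _labelling_from_hard(labels0: np.ndarray, n_classes: int,
                         memberships: np.ndarray | None = None) -> Labelling:
    return Labelling(assignment=labels0 + 1, n_classes=n_classes, memberships=memberships)


def fit_kmeans(features, seeds: np.ndarray, max_iter: int = DEFAULT_MAX_ITER,
               tol: float = DEFAULT_TOL) -> tuple[ClusterModel, Labelling]:
    """Lloyd's algorithm from explicit seeds.

    An emptied cluster is re-seeded at the point farthest from its assigned
    centroid.  Reported covariances are identity and priors uniform (the
    mixture-model reading of K-means); ``nll`` is the final total
    within-cluster sum of squared distances.
    """
    x = _as_array(features)
    mu = np.array(seeds, dtype=float)
    c = mu.shape[0]
    labels = np.empty(x.shape[0], dtype=np.int64)
    trace = []
    prev = None
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(x, mu)
        labels = d2.argmin(axis=1)
        for k in range(c):  # empty-cluster policy
            if not (labels == k).any():
                far = int(d2[np.arange(len(labels)), labels].argmax())
                mu[k] = x[far]
                labels[far] = k
                d2[:, k] = ((x - mu[k]) ** 2).sum(1)
        trace.append(float(d2[np.arange(len(labels)), labels].sum()))
        if prev is not None and np.array_equal(labels, prev):
            break
        prev = labels.copy()
        for k in range(c):
            sel = labels == k
            if sel.any():
                mu[k] = x[sel].mean(axis=0)
    objective = float(_sq_dists(x, mu)[np.arange(len(labels)), labels].sum())
    d = x.shape[1]
    model = ClusterModel(n_classes=c, means=mu,
                         covariances=np.broadcast_to(np.eye(d), (c, d, d)).copy(),
                         priors=np.full(c, 1.0 / c), model_kind="kmeans",
                         nll=objective, n_iter=it,
                         objective_trace=np.array(trace))
    return model, _labelling_from_hard(labels, c)


def _fuzzy_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Exact minimizer of the fuzzy objective for fixed centroids.

    u_nc = 1 / sum_j (d2_nc / d2_nj)^(1/(m-1)); a point coincident with one
    or more centroids puts all its mass on the lowest-index such centroid.
    """
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        # ratio-to-minimum keeps the powers in [0, 1], so no overflow even
        # for fuzzifiers close to 1
        inv = (d2 / d2.min(axis=1, keepdims=True)) ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
    zero = d2 <= 0
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = 0.0
        u[hit, zero[hit].argmax(axis=1)] = 1.0
    return u


def fit_fuzzy_kmeans(features, seeds: np.ndarray, m: float = 2.0,
                     max_iter: int = DEFAULT_MAX_ITER,
                     tol: float = DEFAULT_TOL) -> tuple[ClusterModel, Labelling]:
    """Fuzzy K-means (fuzzy c-means) by alternating exact minimization."""
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = _as_array(features)
    mu = np.array(seeds, dtype=float)
    c = mu.shape[0]
    prev_obj = None
    trace = []
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(x, mu)
        u = _fuzzy_memberships(d2, m)
        obj = float((u**m * d2).sum())
        trace.append(obj)
        if prev_obj is not None and abs(prev_obj - obj) <= tol * max(1.0, abs(prev_obj)):
            break
        prev_obj = obj
        w = u**m
        denom = w.sum(axis=0)
        mu = np.where(denom[:, None] > 0, w.T @ x / np.maximum(denom, 1e-300)[:, None], mu)
    d = x.shape[1]
    labels = u.argmax(axis=1)
    model = ClusterModel(n_classes=c, means=mu,
                         covariances=np.broadcast_to(np.eye(d), (c, d, d)).copy(),
                         priors=np.full(c, 1.0 / c), model_kind="fuzzy",
                         nll=trace[-1], n_iter=it, objective_trace=np.array(trace))
    return model, _labelling_from_hard(labels, c, memberships=u)


# ---------------------------------------------------------------------------
# Gaussian machinery


def _log_gaussians(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(N, C) matrix of log N(x_n | mu_c, S_c) via Cholesky factors."""
    n, d = x.shape
    c = means.shape[0]
    out = np.empty((n, c))
    const = -0.5 * d * np.log(2.0 * np.pi)
    for k in range(c):
        try:
            chol = linalg.cholesky(covs[k], lower=True)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                f"covariance of class {k + 1} is not positive definite") from exc
        sol = linalg.solve_triangular(chol, (x - means[k]).T, lower=True)
        logdet = np.log(np.diag(chol)).sum()
        out[:, k] = const - logdet - 0.5 * (sol**2).sum(axis=0)
    return out


def _ridge(cov: np.ndarray, fallback_trace: float, reg: float = COV_RIDGE) -> np.ndarray:
    d = cov.shape[0]
    tr = float(np.trace(cov))
    eps = reg * ((tr if tr > 0 else fallback_trace) / d)
    return cov + eps * np.eye(d)


def negative_log_likelihood(features, model: ClusterModel) -> float:
    """Mixture NLL -sum_n log sum_c p_c N(x_n|mu_c,S_c), log-sum-exp stabilized."""
    x = _as_array(features)
    logp = _log_gaussians(x, model.means, model.covariances)
    with np.errstate(divide="ignore"):
        lw = np.log(model.priors)
    return float(-logsumexp(logp + lw[None, :], axis=1).sum())


def fit_gmm(features, seeds: np.ndarray, max_iter: int = DEFAULT_MAX_ITER,
            tol: float = DEFAULT_TOL, reg: float = COV_RIDGE
            ) -> tuple[ClusterModel, Labelling]:
    """Full-covariance EM from K-means++ seeds.

    Initial means are the seeds, initial covariances the global data
    covariance, priors uniform.  Each M-step adds a relative ridge
    ``reg * trace(S)/D`` to the covariance diagonal.  Converges when the
    relative NLL change drops below ``tol``.
    """
    x = _as_array(features)
    n, d = x.shape
    mu = np.array(seeds, dtype=float)
    c = mu.shape[0]
    global_cov = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
    global_tr = max(float(np.trace(global_cov)), 1e-12)
    covs = np.array([_ridge(global_cov.copy(), global_tr, reg) for _ in range(c)])
    priors = np.full(c, 1.0 / c)

    trace = []
    prev_nll = None
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            log_joint = _log_gaussians(x, mu, covs) + np.log(priors)[None, :]
        lse = logsumexp(log_joint, axis=1)
        nll = float(-lse.sum())
        trace.append(nll)
        resp = np.exp(log_joint - lse[:, None])
        if prev_nll is not None and abs(prev_nll - nll) <= tol * max(1.0, abs(prev_nll)):
            break
        prev_nll = nll
        nk = resp.sum(axis=0)
        priors = nk / n
        for k in range(c):
            if nk[k] <= 0:
                continue
            mu[k] = resp[:, k] @ x / nk[k]
            diff = x - mu[k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            covs[k] = _ridge(cov, global_tr, reg)
    labels = resp.argmax(axis=1)
    model = ClusterModel(n_classes=c, means=mu, covariances=covs, priors=priors,
                         model_kind="gmm", nll=trace[-1], n_iter=it,
                         objective_trace=np.array(trace))
    return model, _labelling_from_hard(labels, c, memberships=resp)


# ---------------------------------------------------------------------------
# GHMRF


def ising_energy(assignment: np.ndarray, mrf: MrfSpec) -> float:
    """beta times the number of neighbour pairs with differing labels."""
    a = np.asarray(assignment)
    pairs = mrf.neighbour_pairs
    if len(pairs) == 0:
        return 0.0
    if pairs.max() >= len(a):
        raise IndexError("pair endpoint outside assignment")
    return float(mrf.beta) * int((a[pairs[:, 0]] != a[pairs[:, 1]]).sum())


def _neighbour_csr(n: int, pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric adjacency in CSR form (indptr, indices)."""
    if len(pairs) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    return np.cumsum(indptr), dst.astype(np.int64)


def _icm_sweeps_python(labels, energies, indptr, indices, beta, n_sweeps):
    n, c = energies.shape
    for _ in range(n_sweeps):
        changed = 0
        for i in range(n):
            best_c = 0
            best_e = np.inf
            for k in range(c):
                e = energies[i, k]
                for p in range(indptr[i], indptr[i + 1]):
                    if labels[indices[p]] != k:
                        e += beta
                if e < best_e:
                    best_e = e
                    best_c = k
            if best_c != labels[i]:
                labels[i] = best_c
                changed += 1
        if changed == 0:
            break
    return labels


try:  # jit-compiled sweep; identical arithmetic to the python fallback
    from numba import njit
    _icm_sweeps_fast = njit(cache=False, nogil=True)(_icm_sweeps_python)
except ImportError:  # pragma: no cover
    _icm_sweeps_fast = _icm_sweeps_python


def ghmrf_energy(emission: np.ndarray, labels0: np.ndarray, mrf: MrfSpec) -> float:
    """Total energy sum_n -logN(x_n|y_n) + beta * disagreeing pairs (0-based labels)."""
    return float(emission[np.arange(len(labels0)), labels0].sum()) + ising_energy(labels0, mrf)


def fit_ghmrf(features, seeds: np.ndarray, mrf: MrfSpec,
              max_iter: int = DEFAULT_MAX_ITER, icm_sweeps: int = DEFAULT_ICM_SWEEPS,
              tol: float = DEFAULT_TOL, reg: float = COV_RIDGE
              ) -> tuple[ClusterModel, Labelling]:
    """Hard-EM for the Gaussian hidden MRF.

    Each cycle freezes the Gaussian parameters, minimizes the label-field
    energy by ICM sweeps (fixed lexicographic visit order, ties to the
    lowest label index), then refits means/covariances/priors from the hard
    assignment.  Stops when the labelling is unchanged or ``max_iter``
    cycles.  An emptied class is re-seeded at the voxel worst explained by
    its current class, with the global covariance.
    """
    x = _as_array(features)
    n, d = x.shape
    mu = np.array(seeds, dtype=float)
    c = mu.shape[0]
    global_cov = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
    global_tr = max(float(np.trace(global_cov)), 1e-12)
    covs = np.array([_ridge(global_cov.copy(), global_tr, reg) for _ in range(c)])
    priors = np.full(c, 1.0 / c)
    indptr, indices = _neighbour_csr(n, mrf.neighbour_pairs)
    beta = float(mrf.beta)

    labels = _sq_dists(x, mu).argmin(axis=1).astype(np.int64)
    energy_trace = []
    for it in range(1, max_iter + 1):
        emission = -_log_gaussians(x, mu, covs)
        prev_labels = labels.copy()
        labels = _icm_sweeps_fast(labels, emission, indptr, indices, beta,
                                  int(icm_sweeps))
        energy_trace.append(ghmrf_energy(emission, labels, mrf))
        # M-step
        counts = np.bincount(labels, minlength=c).astype(float)
        for k in range(c):
            sel = labels == k
            if counts[k] < 1:
                worst = int(emission[np.arange(n), labels].argmax())
                mu[k] = x[worst]
                covs[k] = _ridge(global_cov.copy(), global_tr, reg)
                counts[k] = 1.0
                continue
            mu[k] = x[sel].mean(axis=0)
            diff = x[sel] - mu[k]
            covs[k] = _ridge(diff.T @ diff / counts[k], global_tr, reg)
        priors = counts / counts.sum()
        if np.array_equal(labels, prev_labels) and it > 1:
            break
    model = ClusterModel(n_classes=c, means=mu, covariances=covs, priors=priors,
                         model_kind="ghmrf", nll=float("nan"), n_iter=it,
                         objective_trace=np.array(energy_trace))
    model.nll = negative_log_likelihood(x, model)
    return model, _labelling_from_hard(labels, c)


# ---------------------------------------------------------------------------
# multistart protocol


def run_multistart(features, n_classes: int, algorithm: str,
                   n_inits: int = 100, keep: int = 10, rng_seed: int = 0,
                   mrf: MrfSpec | None = None, **fit_kwargs
                   ) -> tuple[ClusterModel, Labelling]:
    """K-means++ multi-start: seed ``n_inits`` times, keep the ``keep`` most
    promising seedings, fit each, return the best solution.

    Selection uses the intra-cluster distance objective for the K-means
    variants and the mixture NLL for GMM/GHMRF.  Deterministic given
    ``rng_seed``.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if algorithm == "ghmrf" and mrf is None:
        raise ValueError("ghmrf requires an MrfSpec")
    x = _as_array(features)
    master = np.random.default_rng(rng_seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_inits)
    seed_sets = [kmeanspp_seed(x, n_classes, int(s)) for s in child_seeds]
    kept = rank_seedings(x, seed_sets, keep=keep)

    best = None
    scores = []
    for seeds in kept:
        if algorithm == "kmeans":
            model, lab = fit_kmeans(x, seeds, **fit_kwargs)
            score = model.nll
        elif algorithm == "fuzzy":
            model, lab = fit_fuzzy_kmeans(x, seeds, **fit_kwargs)
            score = model.nll
        elif algorithm == "gmm":
            model, lab = fit_gmm(x, seeds, **fit_kwargs)
            score = model.nll
        else:
            model, lab = fit_ghmrf(x, seeds, mrf=mrf, **fit_kwargs)
            score = model.nll
        scores.append(score)
        if best is None or score < best[0]:
            best = (score, model, lab)
    _, model, lab = best
    model.extras["candidate_scores"] = scores
    return model, lab
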