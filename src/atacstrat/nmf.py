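"""Non-smooth NMF consensus clustering with cophenetic model selection.

Samples are clustered by factorising the log2(CPM+1) matrix of the most
variable peaks as V ~ W S H, where S = (1-theta) I + (theta/k) 11^T is the
non-smooth smoothing matrix that drives W and H towards sparse, parts-based
factors.  Updates are the KL-divergence multiplicative rules with S folded
into the opposite factor (W updates see S H, H updates see W S).  Cluster
number is chosen by maximising the cophenetic correlation of the consensus
matrix over repeated randomly initialised runs, the standard consensus-NMF
model-selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "NsNMF",
    "ConsensusNMFClusterer",
    "NsnmfFactors",
    "nsnmf_factorize",
    "consensus_cophenetic",
    "select_top_variance_peaks",
    "assign_clusters",
    "cluster_agreement",
]

_EPS = 1e-12


def _smooth_right(W: np.ndarray, theta: float) -> np.ndarray:
    """W @ S for S = (1-theta) I + (theta/k) 11^T, computed without forming S."""
    if theta == 0.0:
        return W
    k = W.shape[1]
    return (1.0 - theta) * W + (theta / k) * W.sum(axis=1, keepdims=True)


def _smooth_left(H: np.ndarray, theta: float) -> np.ndarray:
    """S @ H computed without forming S."""
    if theta == 0.0:
        return H
    k = H.shape[0]
    return (1.0 - theta) * H + (theta / k) * H.sum(axis=0, keepdims=True)


def _kl_divergence(V: np.ndarray, R: np.ndarray, v_logv_minus_v: float) -> float:
    """D(V || R) = sum(V log(V/R) - V + R), with 0 log 0 = 0."""
    return float(v_logv_minus_v - np.sum(V * np.log(R)) + R.sum())


def _nsnmf_core(V, k, theta, max_iter, tol, rng, eval_every: int = 1, dtype=np.float64):
    """Multiplicative KL updates for V ~ W S H on a non-negative matrix V.

    The KL objective is recorded every ``eval_every`` iterations;
    convergence is declared when the relative change between consecutive
    evaluations drops below ``tol``.
    """
    dtype = np.dtype(dtype)
    V = np.asarray(V, dtype=dtype)
    m, n = V.shape
    if k >= min(m, n):
        raise ValueError(f"k={k} must be < min(matrix dims)={min(m, n)}")
    # uniform (0, 1] initialisation; determinism under the supplied generator
    W = (1.0 - rng.random((m, k))).astype(dtype)
    H = (1.0 - rng.random((k, n))).astype(dtype)

    mask = V > 0
    v_logv_minus_v = float(np.sum(V[mask] * np.log(V[mask])) - V.sum())
    eps = dtype.type(_EPS)
    trace = []
    prev = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        Ws = _smooth_right(W, theta)
        R = Ws @ H
        R += eps
        H *= (Ws.T @ np.divide(V, R, out=R)) / (Ws.sum(axis=0)[:, None] + eps)

        Hs = _smooth_left(H, theta)
        R = W @ Hs
        R += eps
        if n_iter % eval_every == 0 or n_iter == max_iter:
            # R == W S H here: record the objective at (W_t, H_{t+1});
            # every half-update is non-increasing, so the recorded
            # sequence is monotone
            obj = _kl_divergence(V, R, v_logv_minus_v)
            trace.append(obj)
            converged = np.isfinite(prev) and abs(prev - obj) <= tol * max(
                abs(prev), _EPS
            )
            prev = obj
        W *= (np.divide(V, R, out=R) @ Hs.T) / (Hs.sum(axis=1)[None, :] + eps)
        if converged:
            break
    return W, H, np.asarray(trace), n_iter


class NsNMF(BaseEstimator):
    """Non-smooth NMF estimator, sklearn decomposition conventions.

    ``fit(X)`` factorises X (n_samples x n_features, non-negative) as
    X ~ W S H with W = ``transform_`` loadings (n_samples x k) and
    H = ``components_`` (k x n_features).  ``theta`` in [0, 1] controls
    sparseness (theta=0 is plain KL-NMF).
    """

    def __init__(
        self,
        n_components: int = 3,
        theta: float = 0.5,
        max_iter: int = 2000,
        tol: float = 1e-9,
        random_state=None,
    ):
        self.n_components = n_components
        self.theta = theta
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        V = np.asarray(X, dtype=float)
        if V.ndim != 2:
            raise ValueError("X must be 2-D")
        if (V < 0).any():
            raise ValueError("X must be non-negative")
        if not V.any():
            raise ValueError("X is all zero")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0, 1]")
        rng = np.random.default_rng(self.random_state)
        W, H, trace, n_iter = _nsnmf_core(
            V, self.n_components, self.theta, self.max_iter, self.tol, rng
        )
        self.transform_ = W
        self.components_ = H
        self.objective_trace_ = trace
        self.n_iter_ = n_iter
        self.reconstruction_err_ = float(trace[-1])
        return W

    def smoothing_matrix(self) -> np.ndarray:
        k = self.n_components
        return (1.0 - self.theta) * np.eye(k) + (self.theta / k) * np.ones((k, k))

    def reconstruct(self) -> np.ndarray:
        return _smooth_right(self.transform_, self.theta) @ self.components_


@dataclass
class NsnmfFactors:
    """Factorisation of a peaks x samples matrix: V ~ W S H."""

    W: np.ndarray  # peaks x k
    H: np.ndarray  # k x samples
    theta: float
    objective_trace: np.ndarray
    seed: object

    @property
    def S(self) -> np.ndarray:
        k = self.H.shape[0]
        return (1.0 - self.theta) * np.eye(k) + (self.theta / k) * np.ones((k, k))


def nsnmf_factorize(
    V, k: int, theta: float = 0.5, seed=None, max_iter: int = 2000, tol: float = 1e-9
) -> NsnmfFactors:
    """Factorise a peaks x samples matrix; thin wrapper over :class:`NsNMF`.

    Note the domain orientation: rows are peaks, columns samples, so the
    sample loadings live in H.
    """
    est = NsNMF(
        n_components=k, theta=theta, max_iter=max_iter, tol=tol, random_state=seed
    )
    Wt = est.fit_transform(np.asarray(V, dtype=float).T)  # samples x k
    return NsnmfFactors(
        W=est.components_.T,
        H=Wt.T,
        theta=theta,
        objective_trace=est.objective_trace_,
        seed=seed,
    )


def _cophenetic_rho(consensus: np.ndarray) -> float:
    """Pearson correlation between consensus distances and their
    average-linkage cophenetic distances; NaN when distances are constant."""
    d = squareform(1.0 - consensus, checks=False)
    if np.ptp(d) == 0:
        return float("nan")
    Z = linkage(d, method="average")
    coph = cophenet(Z)
    if np.std(coph) == 0:
        return float("nan")
    return float(np.corrcoef(d, coph)[0, 1])


class ConsensusNMFClusterer(ClusterMixin, BaseEstimator):
    """Consensus nsNMF clustering of samples with cophenetic k selection.

    ``fit(X)`` expects samples in rows and (selected) peaks in columns,
    non-negative (log2(CPM+1) by construction).  For each k in
    ``k_range`` the factorisation is repeated ``n_runs`` times from
    random initialisations; the connectivity matrix of each run assigns
    two samples together iff they share the argmax factor, and the
    consensus is the run average.  k maximising the cophenetic
    correlation is chosen (ties to the smallest k).

    Attributes
    ----------
    chosen_k_ : int
    labels_ : ndarray of int (0-based cluster labels)
    consensus_ : dict k -> (n x n) consensus matrix
    cophenetic_ : dict k -> cophenetic correlation
    run_labels_ : dict k -> (n_valid_runs x n) per-run argmax labels
    """

    def __init__(
        self,
        k_range=(2, 8),
        n_runs: int = 30,
        theta: float = 0.5,
        max_iter: int = 2000,
        tol: float = 1e-9,
        eval_every: int = 10,
        dtype="float64",
        random_state=None,
    ):
        self.k_range = k_range
        self.n_runs = n_runs
        self.theta = theta
        self.max_iter = max_iter
        self.tol = tol
        self.eval_every = eval_every
        self.dtype = dtype
        self.random_state = random_state

    def _ks(self):
        lo, hi = self.k_range
        return list(range(lo, hi + 1))

    def fit(self, X, y=None):
        V = np.asarray(X, dtype=float)
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        n = V.shape[0]
        base = 0 if self.random_state is None else int(self.random_state)
        self.consensus_, self.cophenetic_, self.run_labels_ = {}, {}, {}
        for k in self._ks():
            labels_per_run = []
            for r in range(self.n_runs):
                rng = np.random.default_rng(np.random.SeedSequence([base, k, r]))
                W, H, _, _ = _nsnmf_core(
                    V,
                    k,
                    self.theta,
                    self.max_iter,
                    self.tol,
                    rng,
                    eval_every=self.eval_every,
                    dtype=self.dtype,
                )
                if (np.abs(W) < _EPS).all(axis=1).any():
                    continue  # degenerate run: a sample with all-zero loadings
                labels_per_run.append(np.argmax(W, axis=1))
            if len(labels_per_run) < 2:
                raise RuntimeError(f"fewer than 2 valid consensus runs at k={k}")
            L = np.asarray(labels_per_run)
            consensus = np.mean(
                L[:, :, None] == L[:, None, :], axis=0, dtype=float
            )
            np.fill_diagonal(consensus, 1.0)
            self.consensus_[k] = consensus
            self.cophenetic_[k] = _cophenetic_rho(consensus)
            self.run_labels_[k] = L

        rhos = np.array([self.cophenetic_[k] for k in self._ks()])
        if np.isnan(rhos).all():
            raise RuntimeError("cophenetic correlation undefined for every k")
        self.chosen_k_ = self._select_k(self._ks(), rhos)
        self.labels_ = self._representative_labels(self.chosen_k_)
        self.n_samples_ = n
        return self

    @staticmethod
    def _select_k(ks, rhos) -> int:
        """k maximising the cophenetic correlation.

        Exact ties at the maximum resolve to the end of the contiguous
        plateau that starts at the smallest tied k: cleanly separable
        data makes the consensus perfectly stable (rho = 1) for every k
        up to the true cluster number, so the informative point is where
        that plateau ends, not its first member.  An isolated larger k
        that happens to tie does not override the initial plateau.
        """
        max_rho = np.nanmax(rhos)
        tied = {k for k, r in zip(ks, rhos) if r == max_rho}
        chosen = min(tied)
        while chosen + 1 in tied:
            chosen += 1
        return int(chosen)

    def _representative_labels(self, k: int) -> np.ndarray:
        """Labels of the run whose connectivity best matches the consensus."""
        consensus = self.consensus_[k]
        d_cons = squareform(consensus, checks=False)
        best_run, best_score = 0, -np.inf
        for r, lab in enumerate(self.run_labels_[k]):
            conn = (lab[:, None] == lab[None, :]).astype(float)
            d_conn = squareform(conn, checks=False)
            if np.std(d_conn) == 0 or np.std(d_cons) == 0:
                score = 1.0 if np.allclose(d_conn, d_cons) else 0.0
            else:
                score = float(np.corrcoef(d_conn, d_cons)[0, 1])
            if score > best_score:
                best_run, best_score = r, score
        return self.run_labels_[k][best_run].copy()

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cophenetic(
    V,
    k_range=(2, 8),
    n_runs: int = 30,
    theta: float = 0.5,
    seed=None,
    max_iter: int = 2000,
    tol: float = 1e-9,
    eval_every: int = 10,
    dtype="float64",
) -> ConsensusNMFClusterer:
    """Consensus clustering of a peaks x samples matrix over a k range."""
    est = ConsensusNMFClusterer(
        k_range=k_range,
        n_runs=n_runs,
        theta=theta,
        max_iter=max_iter,
        tol=tol,
        eval_every=eval_every,
        dtype=dtype,
        random_state=seed,
    )
    return est.fit(np.asarray(V, dtype=float).T)


def select_top_variance_peaks(logcpm, fraction: float | None = 0.2, count: int | None = None):
    """Indices (or ids) of the highest-variance rows of a peak matrix.

    Rows are ranked by variance descending; ties break on peak id
    ascending.  Exactly one of ``fraction`` (default 0.20) and ``count``
    applies; ``count`` wins if given.
    """
    if isinstance(logcpm, pd.DataFrame):
        ids = logcpm.index.to_numpy()
        mat = logcpm.to_numpy(dtype=float)
    else:
        mat = np.asarray(logcpm, dtype=float)
        ids = np.arange(mat.shape[0])
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 samples to rank by variance")
    if count is None:
        if fraction is None or not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        count = max(1, int(round(fraction * mat.shape[0])))
    if count > mat.shape[0]:
        raise ValueError("count exceeds number of peaks")
    var = mat.var(axis=1, ddof=1)
    order = np.lexsort((ids, -var))
    sel = order[:count]
    if isinstance(logcpm, pd.DataFrame):
        return pd.Index(ids[sel])
    return sel


def assign_clusters(H) -> np.ndarray:
    """Per-sample cluster label from H (k x samples): argmax over factors.

    Ties take the lowest factor index (numpy argmax); a column that is
    entirely (near-)zero is unassigned and labelled -1.
    """
    H = np.asarray(H, dtype=float)
    labels = np.argmax(H, axis=0)
    dead = (np.abs(H) < _EPS).all(axis=0)
    labels = labels.astype(int)
    labels[dead] = -1
    return labels


def cluster_agreement(labels_a, labels_b) -> dict:
    """Contingency table, permutation-matched agreement and ARI.

    ``matched_agreement`` maximises the label-permutation-invariant
    fraction of co-assigned samples via the Hungarian algorithm on the
    contingency table.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("labelings must cover the same non-empty sample set")
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        if not labels_a.index.sort_values().equals(labels_b.index.sort_values()):
            raise ValueError("labelings reference different sample sets")
        b = labels_b.reindex(labels_a.index)
        a = labels_a
    table = pd.crosstab(a.to_numpy(), b.to_numpy())
    cost = -table.to_numpy(dtype=float)
    # pad to square so every label can be matched
    nrow, ncol = cost.shape
    size = max(nrow, ncol)
    padded = np.zeros((size, size))
    padded[:nrow, :ncol] = cost
    rows, cols = linear_sum_assignment(padded)
    matched = -padded[rows, cols].sum() / len(a)
    return {
        "contingency": table,
        "matched_agreement": float(matched),
        "ari": float(adjusted_rand_score(a.to_numpy(), b.to_numpy())),
    }
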