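"""Signature extraction by non-negative matrix factorization.

The count catalog V (samples x 96) is decomposed as V ~ H W with H
(samples x k) the exposures and W (k x 96) the signature patterns, by
multiplicative updates minimizing the generalized Kullback-Leibler
divergence D(V || HW). The update rules guarantee a monotone non-increasing
objective. The signature number is chosen from the stability (cophenetic
correlation) of random-restart factorizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .errors import AlignmentError, DegenerateInputError, ParameterError

_EPS = 1e-12


@dataclass
class SignatureSet:
    """k x 96 row-stochastic signature patterns with labels."""

    W: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if (self.W < 0).any():
            raise ParameterError("signature matrix must be non-negative")
        rowsum = self.W.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ParameterError("signature rows must sum to 1 within 1e-9")
        if len(self.names) != self.W.shape[0]:
            raise ParameterError("one name per signature row required")

    @property
    def k(self) -> int:
        return self.W.shape[0]

    def to_frame(self, channels: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.names, columns=list(channels))


@dataclass
class ExposureMatrix:
    """Absolute and relative per-sample signature contributions."""

    H_counts: np.ndarray  # samples x k
    samples: list[str]
    signature_names: list[str]
    H_rel: np.ndarray = field(init=False)
    zero_samples: np.ndarray = field(init=False)  # rows with no attributable mutations

    def __post_init__(self):
        self.H_counts = np.asarray(self.H_counts, dtype=float)
        if (self.H_counts < 0).any():
            raise ParameterError("exposures must be non-negative")
        rowsum = self.H_counts.sum(axis=1)
        self.zero_samples = rowsum == 0
        safe = np.where(self.zero_samples, 1.0, rowsum)
        self.H_rel = self.H_counts / safe[:, None]

    def rel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.H_rel, index=pd.Index(self.samples, name="sample_id"), columns=self.signature_names
        )

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.H_counts, index=pd.Index(self.samples, name="sample_id"), columns=self.signature_names
        )


@dataclass
class RankSelection:
    k_range: list[int]
    cophenetic: dict[int, float]
    reconstruction_error: dict[int, float]
    chosen_k: int


def kl_divergence(V: np.ndarray, P: np.ndarray) -> float:
    """Generalized KL divergence D(V || P), with 0*log0 = 0."""
    V = np.asarray(V, dtype=float)
    P = np.asarray(P, dtype=float)
    mask = V > 0
    out = float(P.sum() - V.sum())
    out += float((V[mask] * np.log(V[mask] / np.maximum(P[mask], _EPS))).sum())
    return out


def _mu_kl(V, H, W, n_iter_check=10, max_iter=500, tol=1e-6):
    """Multiplicative updates for KL loss; returns (H, W, objective)."""
    prev = kl_divergence(V, H @ W + _EPS)
    for it in range(1, max_iter + 1):
        P = H @ W + _EPS
        H *= (V / P) @ W.T / np.maximum(W.sum(axis=1), _EPS)
        P = H @ W + _EPS
        W *= H.T @ (V / P) / np.maximum(H.sum(axis=0)[:, None], _EPS)
        if it % n_iter_check == 0 or it == max_iter:
            obj = kl_divergence(V, H @ W + _EPS)
            denom = max(abs(prev), _EPS)
            if (prev - obj) / denom < tol:
                return H, W, obj
            prev = obj
    return H, W, kl_divergence(V, H @ W + _EPS)


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    names: Optional[list[str]] = None,
    samples: Optional[list[str]] = None,
) -> tuple[SignatureSet, ExposureMatrix, float]:
    """Factorize V ~ H W; returns (signatures, exposures, final KL divergence).

    W rows are rescaled to sum to 1 with the compensating rescale folded into
    H, so the product HW is unchanged. Deterministic for a fixed seed.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ParameterError("V must be a 2-D matrix")
    n, m = V.shape
    if (V < 0).any():
        raise ParameterError("V must be non-negative")
    if V.sum() == 0:
        raise DegenerateInputError("all-zero catalog cannot be factorized")
    if not (1 <= k <= min(n, m)):
        raise ParameterError(f"k must lie in [1, min(n_samples, n_channels)] = [1, {min(n, m)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    H = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    W = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    H, W, obj = _mu_kl(V, H, W, max_iter=max_iter, tol=tol)

    row = np.maximum(W.sum(axis=1), _EPS)
    W = W / row[:, None]
    H = H * row[None, :]
    sig_names = names or [f"S{i + 1}" for i in range(k)]
    sample_ids = samples or [f"sample{i}" for i in range(n)]
    sigs = SignatureSet(W=W, names=list(sig_names))
    expo = ExposureMatrix(H_counts=H, samples=list(sample_ids), signature_names=list(sig_names))
    return sigs, expo, obj


def estimate_rank(
    V: np.ndarray,
    k_range: Sequence[int],
    n_runs: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> RankSelection:
    """Random-restart stability analysis over candidate signature numbers.

    For each k, ``n_runs`` factorizations (seeds ``seed*1000 + run``) are
    summarized by a sample consensus matrix built from dominant-signature
    assignments; cophenetic[k] correlates that consensus dissimilarity with
    its average-linkage dendrogram. chosen_k maximizes the cophenetic
    coefficient (ties break toward the smaller k); callers may override.
    """
    if n_runs < 2:
        raise ParameterError("n_runs must be >= 2 for a consensus to be defined")
    ks = sorted(set(int(k) for k in k_range))
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    cophenetic: dict[int, float] = {}
    recon: dict[int, float] = {}
    for k in ks:
        consensus = np.zeros((n, n))
        best_obj = np.inf
        for run in range(n_runs):
            _, expo, obj = nmf_factorize(V, k, seed=seed * 1000 + run, max_iter=max_iter, tol=tol)
            best_obj = min(best_obj, obj)
            assign = expo.H_rel.argmax(axis=1)
            consensus += (assign[:, None] == assign[None, :]).astype(float)
        consensus /= n_runs
        recon[k] = best_obj
        cophenetic[k] = _cophenetic_corr(1.0 - consensus)
    chosen = _choose_k(ks, cophenetic)
    return RankSelection(k_range=ks, cophenetic=cophenetic, reconstruction_error=recon, chosen_k=chosen)


def _cophenetic_corr(dissim: np.ndarray) -> float:
    d = squareform(np.clip((dissim + dissim.T) / 2, 0, None), checks=False)
    if np.allclose(d, d[0] if d.size else 0.0):
        return 1.0  # degenerate: all pairwise dissimilarities equal -> perfectly stable
    Z = average(d)
    c, _ = cophenet(Z, d)
    return float(c)


def _choose_k(ks: list[int], cophenetic: dict[int, float]) -> int:
    # maximal-stability rule: the k whose restarts co-cluster most consistently;
    # ties break toward the smaller (more parsimonious) k
    return min(ks, key=lambda k: (-cophenetic[k], k))


@dataclass
class ReferenceSignatures:
    names: list[str]
    R: np.ndarray  # m x 96, rows sum to 1
    channels: tuple[str, ...]

    @classmethod
    def from_tsv(cls, path) -> "ReferenceSignatures":
        """Load a v2-layout probability file: 96 context rows x signature columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        from .catalog96 import CHANNELS

        df = df.reindex(list(CHANNELS))
        if df.isna().any().any():
            raise AlignmentError("reference file does not cover the 96 canonical channels")
        R = df.to_numpy().T
        R = R / R.sum(axis=1, keepdims=True)
        return cls(names=list(df.columns), R=R, channels=CHANNELS)


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    return (A / np.maximum(na, _EPS)) @ (B / np.maximum(nb, _EPS)).T


def match_reference(
    S: SignatureSet, R: ReferenceSignatures, channels: Optional[Sequence[str]] = None
) -> tuple[list[tuple[str, str, float]], np.ndarray]:
    """Assign each extracted signature its best-cosine reference; returns the full k x m matrix too."""
    if channels is not None and tuple(channels) != tuple(R.channels):
        raise AlignmentError("signature and reference channel orders differ")
    if S.W.shape[1] != R.R.shape[1]:
        raise AlignmentError("signature and reference channel dimensions differ")
    sim = cosine_similarity_matrix(S.W, R.R)
    matches = []
    for i, name in enumerate(S.names):
        j = int(sim[i].argmax())
        matches.append((name, R.names[j], float(sim[i, j])))
    return matches, sim


def binarize_activity(E: ExposureMatrix, threshold: float = 0.25) -> np.ndarray:
    """Signature presence: relative activity strictly greater than ``threshold``."""
    if not (0.0 <= threshold < 1.0):
        raise ParameterError(f"threshold must lie in [0, 1), got {threshold}")
    return E.H_rel > threshold
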