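"""Participant-level similarity from graph spectra (lambda distance).

Two participants are compared through the eigenvalue spectra of their
association graphs' unnormalized Laplacians: the lambda distance is the
Euclidean distance between the sorted spectra (all graphs share the region
node set, so spectra are directly comparable).  Distances become affinities
through the locally scaled exponential kernel used by Similarity Network
Fusion, so the scaling factor mu and the neighbourhood size K act exactly
where the fusion stage expects them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SpectralSignature:
    """Ascending Laplacian eigenvalues of one participant graph."""

    participant_id: str
    measure: str
    eigenvalues: np.ndarray


def laplacian_spectrum(weights: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of L = Deg - W for one symmetric weight matrix.

    The diagonal of ``weights`` is ignored (self-loops carry no information
    about region association).  The smallest eigenvalue of a Laplacian is 0.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    lap = np.diag(w.sum(axis=1)) - w
    vals = np.linalg.eigvalsh(lap)
    return np.clip(vals, 0.0, None)


def lambda_distance(eigs_a: np.ndarray, eigs_b: np.ndarray) -> float:
    """Euclidean distance between two sorted eigenvalue vectors."""
    a = np.sort(np.asarray(eigs_a, dtype=float))
    b = np.sort(np.asarray(eigs_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    return float(np.linalg.norm(a - b))


def spectral_distance_matrix(graph_stack: np.ndarray) -> np.ndarray:
    """All-pairs lambda distances for a stack of participant graphs."""
    n = graph_stack.shape[0]
    r = graph_stack.shape[1]
    spectra = np.empty((n, r))
    stack = np.array(graph_stack, dtype=float, copy=True)
    idx = np.arange(r)
    stack[:, idx, idx] = 0.0
    for i in range(n):
        w = stack[i]
        lap = np.diag(w.sum(axis=1)) - w
        spectra[i] = np.linalg.eigvalsh(lap)
    spectra = np.clip(spectra, 0.0, None)
    diff = spectra[:, None, :] - spectra[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return (dist + dist.T) / 2


def scaled_exponential_kernel(distances: np.ndarray, mu: float, K: int) -> np.ndarray:
    """Locally scaled affinity W(i,j) = exp(-d_ij^2 / (mu * eps_ij)).

    eps_ij averages the mean distance of i and of j to their K nearest
    neighbours with d_ij itself, so the bandwidth adapts to local density.
    The diagonal is set to 1 (maximal self-affinity).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not (1 <= K < n):
        raise ValueError("K must satisfy 1 <= K < n")
    off = d + np.diag(np.full(n, np.inf))
    knn_mean = np.sort(off, axis=1)[:, :K].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0
    floored = eps < 1e-12
    if floored.any():
        warnings.warn("zero local bandwidth floored at 1e-12", stacklevel=2)
        eps = np.maximum(eps, 1e-12)
    w = np.exp(-(d**2) / (mu * eps))
    np.fill_diagonal(w, 1.0)
    return (w + w.T) / 2


def build_similarity(graph_stack: np.ndarray, mu: float, K: int) -> np.ndarray:
    """Participant similarity matrix for one measure's graph stack."""
    return scaled_exponential_kernel(spectral_distance_matrix(graph_stack), mu, K)
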