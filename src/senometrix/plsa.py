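"""Probabilistic latent semantic analysis over binned mass spectra.

Spectra are TIC-normalized and summed into fixed-width m/z bins to form
a document-term matrix (documents = spectra, terms = bins; continuous
nonnegative weights are used directly — pLSA's EM updates never require
integer counts). The aspect model

    P(d, w) = P(d) * sum_z P(z|d) P(w|z)

is fitted by plain EM (no tempering): the E-step computes the posterior
P(z|d,w) and the M-step re-estimates P(w|z) and P(z|d). The
log-likelihood is non-decreasing across iterations; several random
restarts (symmetric Dirichlet(1) initialization from the stated seed)
keep the best solution. Group discrimination is read off the
document-topic simplex via nearest-centroid assignment and a silhouette
score — the topic factorization itself never sees the labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import SpectrumSet
from .maldi import tic_normalize

__all__ = ["DocTermMatrix", "PLSAModel", "bin_spectra", "fit", "discriminate"]


@dataclass
class DocTermMatrix:
    """Nonnegative spectra-by-bins weight matrix."""

    weights: np.ndarray  # (n_docs, n_terms)
    doc_ids: List[str]
    bin_centers: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(self.weights.sum(axis=1) <= 0):
            raise ValueError("every document needs at least one positive entry")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.weights.shape


@dataclass
class PLSAModel:
    """Fitted aspect model: P(w|z) columns and P(z|d) rows sum to 1."""

    k: int
    term_given_topic: np.ndarray  # (k, n_terms), rows sum to 1
    topic_given_doc: np.ndarray  # (n_docs, k), rows sum to 1
    loglik_trace: List[float]
    seed: int
    n_iter: int
    doc_ids: List[str] = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k,
            "term_given_topic": self.term_given_topic.tolist(),
            "topic_given_doc": self.topic_given_doc.tolist(),
            "loglik_trace": self.loglik_trace,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "doc_ids": self.doc_ids,
        }))


def bin_spectra(spectra: SpectrumSet, bin_width: float = 1.0) -> DocTermMatrix:
    """Sum each spectrum's TIC-normalized intensity into fixed m/z bins.

    Bin edges start at the floor of the global minimum m/z; columns that
    no document populates are dropped. Each row sums to 1 (the
    normalized TIC) up to floating-point error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    spectra_list = list(spectra)
    if not spectra_list:
        raise ValueError("empty spectrum set")
    lo = min(s.mz[0] for s in spectra_list)
    hi = max(s.mz[-1] for s in spectra_list)
    if hi - lo < bin_width:
        raise ValueError("bin_width exceeds the spectral span")
    start = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)

    rows = []
    for s in spectra_list:
        sn = tic_normalize(s)
        idx = np.floor((sn.mz - start) / bin_width).astype(int)
        row = np.bincount(idx, weights=sn.intensity, minlength=n_bins)
        rows.append(row)
    weights = np.vstack(rows)
    keep = weights.sum(axis=0) > 0
    centers = (edges[:-1] + bin_width / 2)[keep]
    return DocTermMatrix(
        weights=weights[:, keep],
        doc_ids=[s.sample for s in spectra_list],
        bin_centers=centers,
        bin_width=bin_width,
    )


def _loglik(n: np.ndarray, mix: np.ndarray) -> float:
    mask = n > 0
    return float((n[mask] * np.log(mix[mask])).sum())


def _em(
    n: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    rel_tol: float,
) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    n_docs, n_terms = n.shape
    theta = rng.dirichlet(np.ones(k), size=n_docs)  # P(z|d)
    phi = rng.dirichlet(np.ones(n_terms), size=k)  # P(w|z)
    trace: List[float] = []
    for _ in range(max_iter):
        mix = theta @ phi  # (d, w): sum_z P(z|d)P(w|z)
        trace.append(_loglik(n, mix))
        # E+M fused: responsibilities never materialized per z beyond a loop
        ratio = np.where(mix > 0, n / np.where(mix > 0, mix, 1.0), 0.0)
        new_theta = np.empty_like(theta)
        new_phi = np.empty_like(phi)
        for z in range(k):
            # A[d,w] = n[d,w] * P(z|d,w)
            a = ratio * np.outer(theta[:, z], phi[z])
            new_phi[z] = a.sum(axis=0)
            new_theta[:, z] = a.sum(axis=1)
        phi_norm = new_phi.sum(axis=1, keepdims=True)
        theta_norm = new_theta.sum(axis=1, keepdims=True)
        phi = np.where(phi_norm > 0, new_phi / phi_norm, 1.0 / n_terms)
        theta = np.where(theta_norm > 0, new_theta / theta_norm, 1.0 / k)
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= rel_tol * abs(prev):
                break
    trace.append(_loglik(n, theta @ phi))
    return theta, phi, trace


def fit(
    dtm: DocTermMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    rel_tol: float = 1e-6,
    restarts: int = 5,
) -> PLSAModel:
    """Fit a K-topic pLSA model by EM with random restarts.

    The best restart by final log-likelihood is kept. The stored
    ``loglik_trace`` is non-decreasing (EM guarantee, slack 1e-10).
    """
    n_docs, n_terms = dtm.shape
    if k < 1 or k > min(n_docs, n_terms):
        raise ValueError(f"k must lie in [1, min(docs, terms)]; got {k}")
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, np.ndarray, List[float]]] = None
    for _ in range(max(1, restarts)):
        theta, phi, trace = _em(dtm.weights, k, rng, max_iter, rel_tol)
        if best is None or trace[-1] > best[2][-1]:
            best = (theta, phi, trace)
    theta, phi, trace = best
    return PLSAModel(
        k=k, term_given_topic=phi, topic_given_doc=theta,
        loglik_trace=trace, seed=seed, n_iter=len(trace) - 1,
        doc_ids=list(dtm.doc_ids),
    )


def discriminate(
    model: PLSAModel, labels: Sequence[str]
) -> Dict[str, object]:
    """Class separation of documents in topic space.

    Nearest-centroid assignment (centroids = per-class means of P(z|d))
    plus accuracy against ``labels`` and a silhouette score. With a
    single class the accuracy is undefined (None); with K = 1 all
    loadings coincide and the silhouette is undefined (None).
    Deterministic given the model.
    """
    theta = model.topic_given_doc
    labels = list(labels)
    if len(labels) != theta.shape[0]:
        raise ValueError("one label per document required")
    classes = sorted(set(labels))
    loadings = pd.DataFrame(
        theta, columns=[f"topic_{z}" for z in range(model.k)]
    )
    loadings.insert(0, "doc_id", model.doc_ids or range(theta.shape[0]))
    loadings["label"] = labels

    result: Dict[str, object] = {"loadings": loadings}
    if len(classes) < 2:
        result.update(assignments=None, accuracy=None, silhouette=None)
        return result

    centroids = np.vstack(
        [theta[[l == c for l in labels]].mean(axis=0) for c in classes]
    )
    d2 = ((theta[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = [classes[i] for i in d2.argmin(axis=1)]
    accuracy = float(np.mean([a == l for a, l in zip(assigned, labels)]))

    silhouette: Optional[float] = None
    if model.k > 1 and np.ptp(theta, axis=0).max() > 0:
        from sklearn.metrics import silhouette_score

        try:
            silhouette = float(silhouette_score(theta, labels))
        except ValueError:
            silhouette = None

    result.update(assignments=assigned, accuracy=accuracy, silhouette=silhouette)
    return result
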