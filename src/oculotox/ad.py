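"""k-nearest-neighbor Euclidean applicability domain.

A model's domain is defined by a single distance threshold
``D_T = ȳ + Z·σ`` where ȳ and σ are the mean and standard deviation, pooled
over the training set, of each training compound's mean Euclidean distance
to its k nearest training neighbors (self excluded). A query is in-domain
when its mean distance to its k nearest training compounds does not exceed
D_T (boundary inclusive). Z (default 0.5) controls how permissive the
domain is; larger Z admits more queries.

Continuous features are z-scaled with training statistics before distances
are computed; bit fingerprints are used raw as 0/1 coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .descriptors import DescriptorBlock

__all__ = ["AdThreshold", "fit_ad", "in_domain", "coverage"]

DEFAULT_K = 5
DEFAULT_Z = 0.5


@dataclass
class AdThreshold:
    """Fitted applicability-domain state."""

    k: int
    Z: float
    y_bar: float
    sigma: float
    D_T: float
    scale_mean: np.ndarray
    scale_std: np.ndarray
    train_matrix: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "k": self.k, "Z": self.Z, "y_bar": self.y_bar,
            "sigma": self.sigma, "D_T": self.D_T,
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "train_matrix": self.train_matrix.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AdThreshold":
        with open(path) as fh:
            p = json.load(fh)
        return cls(k=p["k"], Z=p["Z"], y_bar=p["y_bar"], sigma=p["sigma"],
                   D_T=p["D_T"],
                   scale_mean=np.array(p["scale_mean"]),
                   scale_std=np.array(p["scale_std"]),
                   train_matrix=np.array(p["train_matrix"]))


def _scaling(matrix: np.ndarray, kind: str):
    if kind == "CONTINUOUS":
        mean = matrix.mean(axis=0)
        std = matrix.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros(matrix.shape[1])
        std = np.ones(matrix.shape[1])
    return mean, std


def fit_ad(train_block: DescriptorBlock, k: int = DEFAULT_K,
           Z: float = DEFAULT_Z) -> AdThreshold:
    """Fit the kNN-distance domain threshold on a training block."""
    X = np.asarray(train_block.matrix, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than training size {n}")
    mean, std = _scaling(X, train_block.kind)
    Xs = (X - mean) / std

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xs)
    dists, _ = nn.kneighbors(Xs)
    per_compound = dists[:, 1:].mean(axis=1)  # drop self (distance 0)

    y_bar = float(per_compound.mean())
    sigma = float(per_compound.std())
    return AdThreshold(k=k, Z=Z, y_bar=y_bar, sigma=sigma,
                       D_T=y_bar + Z * sigma,
                       scale_mean=mean, scale_std=std, train_matrix=Xs)


def _query_distances(queries: np.ndarray, ad: AdThreshold) -> np.ndarray:
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != ad.train_matrix.shape[1]:
        raise ValueError(
            f"query dimension {Q.shape[1]} does not match "
            f"training dimension {ad.train_matrix.shape[1]}"
        )
    Qs = (Q - ad.scale_mean) / ad.scale_std
    nn = NearestNeighbors(n_neighbors=ad.k).fit(ad.train_matrix)
    dists, _ = nn.kneighbors(Qs)
    return dists.mean(axis=1)


def in_domain(query_vector: np.ndarray, ad: AdThreshold) -> bool:
    """True iff the query's mean kNN distance to training is ≤ D_T."""
    return bool(_query_distances(query_vector, ad)[0] <= ad.D_T)


def in_domain_batch(queries: np.ndarray, ad: AdThreshold) -> np.ndarray:
    return _query_distances(queries, ad) <= ad.D_T


def coverage(in_ad_flags) -> float:
    """Fraction of assessed predictions inside the applicability domain."""
    flags = [f for f in in_ad_flags]
    if not flags:
        raise ValueError("coverage of an empty prediction list is undefined")
    return sum(1 for f in flags if f in (True, "IN")) / len(flags)
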