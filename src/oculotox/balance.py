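"""Similarity-driven under-sampling of the majority (negative) class.

An imbalanced curated set is balanced by keeping every positive and
selecting an equal number of negatives in two stages: the ceil(n_pos/2)
negatives most similar (max Tanimoto over positives, on a bit-fingerprint
space) to any positive — deliberately the hardest negatives, so the model
must separate close structural analogues — and the remaining floor(n_pos/2)
drawn uniformly at random from the rest to keep chemical-space coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np

from .curation import CompoundRecord
from .descriptors import compute_block

__all__ = [
    "BalanceConfig",
    "BalancedSet",
    "tanimoto",
    "nearest_positive_similarity",
    "balance_dataset",
]


@dataclass
class BalanceConfig:
    fingerprint_space: str = "MORGAN"
    rng_seed: int = 0


@dataclass
class BalancedSet:
    positives: list[CompoundRecord]
    negatives_similarity: list[CompoundRecord]
    negatives_random: list[CompoundRecord]
    #: max Tanimoto to any positive, for each similarity-selected negative,
    #: in selection (non-increasing) order
    similarity_scores: list[float] = field(default_factory=list)
    rng_seed: int = 0

    @property
    def records(self) -> list[CompoundRecord]:
        return self.positives + self.negatives_similarity + self.negatives_random

    def manifest(self) -> dict:
        return {
            "rng_seed": self.rng_seed,
            "n_positives": len(self.positives),
            "n_negatives_similarity": len(self.negatives_similarity),
            "n_negatives_random": len(self.negatives_random),
            "selection": (
                [{"record_id": r.record_id, "reason": "positive"}
                 for r in self.positives]
                + [{"record_id": r.record_id, "reason": "similarity",
                    "score": s}
                   for r, s in zip(self.negatives_similarity,
                                   self.similarity_scores)]
                + [{"record_id": r.record_id, "reason": "random"}
                   for r in self.negatives_random]
            ),
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two bit vectors.

    Defined as 0 when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between rows of two bit matrices."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def nearest_positive_similarity(neg_fps: np.ndarray,
                                pos_fps: np.ndarray) -> np.ndarray:
    """For each negative, its maximum Tanimoto over all positives."""
    pos_fps = np.atleast_2d(pos_fps)
    neg_fps = np.atleast_2d(neg_fps)
    if pos_fps.shape[0] == 0:
        raise ValueError("positive set is empty")
    return tanimoto_matrix(neg_fps, pos_fps).max(axis=1)


def balance_dataset(
    pos: list[CompoundRecord],
    neg: list[CompoundRecord],
    cfg: BalanceConfig | None = None,
) -> BalancedSet:
    """Under-sample negatives to match the positive count.

    ceil(n_pos/2) negatives are taken by descending nearest-positive
    Tanimoto similarity (ties broken by stable record order), the remaining
    floor(n_pos/2) uniformly at random (seeded) from the unselected pool.
    """
    cfg = cfg or BalanceConfig()
    n_pos = len(pos)
    if n_pos < 1:
        raise ValueError("need at least one positive")
    if len(neg) < n_pos:
        raise ValueError(
            f"cannot balance by under-sampling: {len(neg)} negatives "
            f"< {n_pos} positives"
        )
    n_sim = math.ceil(n_pos / 2)
    n_rand = n_pos - n_sim

    pos_fps = compute_block(pos, cfg.fingerprint_space).matrix
    neg_fps = compute_block(neg, cfg.fingerprint_space).matrix
    scores = nearest_positive_similarity(neg_fps, pos_fps)

    # stable sort on (score desc, original order asc)
    order = np.argsort(-scores, kind="stable")
    sim_idx = order[:n_sim]
    rest_idx = np.sort(order[n_sim:])

    rng = np.random.default_rng(cfg.rng_seed)
    rand_pick = rng.choice(len(rest_idx), size=n_rand, replace=False)
    rand_idx = rest_idx[np.sort(rand_pick)]

    return BalancedSet(
        positives=list(pos),
        negatives_similarity=[neg[i] for i in sim_idx],
        negatives_random=[neg[i] for i in rand_idx],
        similarity_scores=[float(scores[i]) for i in sim_idx],
        rng_seed=cfg.rng_seed,
    )
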