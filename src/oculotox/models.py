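"""Classifier back ends: a random-forest learner over a single descriptor
space and the multi-descriptor read-across (MuDRA) instance-based
classifier.

MuDRA builds no global model. For a query it finds, in each configured
descriptor space, the k most similar training compounds (Tanimoto for bit
fingerprints, 1/(1 + Euclidean distance) on z-scaled features for
continuous spaces) and forms a similarity-weighted class vote per space.
The consensus label comes from the space whose top neighbor is most similar
to the query — the space giving the most confident read-across — and the
prediction's confidence is that space's winning weighted-vote fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .ad import AdThreshold, in_domain_batch
from .balance import tanimoto_matrix
from .descriptors import DescriptorBlock

__all__ = [
    "ClassifierSpec",
    "Prediction",
    "RandomForestModel",
    "MudraClassifier",
    "train_rf",
    "predict_batch",
]

DEFAULT_N_TREES = 500
DEFAULT_K = 5


@dataclass
class ClassifierSpec:
    """Which algorithm, which descriptor spaces, which hyperparameters."""

    algorithm: str  # "RF" | "MUDRA"
    spaces: list[str]
    class_labels: list[str] = field(default_factory=lambda: ["NEG", "POS"])
    n_trees: int = DEFAULT_N_TREES
    max_depth: int | None = None
    rng_seed: int = 0
    k: int = DEFAULT_K
    similarity_floor: float = 0.0

    def __post_init__(self):
        if self.algorithm == "RF" and len(self.spaces) != 1:
            raise ValueError("RF uses exactly one descriptor space")
        if self.algorithm == "MUDRA" and len(self.spaces) < 2:
            raise ValueError("MuDRA is multi-descriptor: needs ≥2 spaces")


@dataclass
class Prediction:
    compound_id: str
    predicted_label: str
    confidence: float
    in_ad: str = "NOT_ASSESSED"  # IN | OUT | NOT_ASSESSED
    per_space_evidence: dict = field(default_factory=dict)
    low_evidence: bool = False


class RandomForestModel:
    """Seeded random-forest classifier over one descriptor block.

    Thin wrapper fixing the probability-to-label convention: positive when
    the positive-class probability is ≥ 0.5 (ties called positive — the
    conservative call for a toxicity endpoint).
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.classes_: list[str] = []
        self._rf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            max_features="sqrt",
            random_state=spec.rng_seed,
        )

    @property
    def space(self) -> str:
        return self.spec.spaces[0]

    def fit(self, block: DescriptorBlock, labels) -> "RandomForestModel":
        labels = list(labels)
        if len(labels) != block.n_compounds:
            raise ValueError("labels not aligned to block rows")
        if len(set(labels)) < 2:
            raise ValueError("training data must contain ≥2 classes")
        self._rf.fit(block.matrix, labels)
        self.classes_ = list(self._rf.classes_)
        return self

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        return self._rf.predict_proba(np.atleast_2d(matrix))

    def predict(self, matrix: np.ndarray) -> list[str]:
        proba = self.predict_proba(matrix)
        if set(self.classes_) == {"POS", "NEG"}:
            p_pos = proba[:, self.classes_.index("POS")]
            return ["POS" if p >= 0.5 else "NEG" for p in p_pos]
        return [self.classes_[i] for i in proba.argmax(axis=1)]

    def confidence(self, matrix: np.ndarray) -> np.ndarray:
        return self.predict_proba(matrix).max(axis=1)


    # ------------------------------------------------------------ persistence

    def save(self, directory) -> None:
        import joblib

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self._rf, d / "rf.joblib")
        with open(d / "spec.json", "w") as fh:
            json.dump({"algorithm": "RF", "spaces": self.spec.spaces,
                       "class_labels": self.spec.class_labels,
                       "n_trees": self.spec.n_trees,
                       "max_depth": self.spec.max_depth,
                       "rng_seed": self.spec.rng_seed,
                       "classes_": self.classes_}, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "RandomForestModel":
        import joblib

        d = Path(directory)
        with open(d / "spec.json") as fh:
            meta = json.load(fh)
        spec = ClassifierSpec(algorithm="RF", spaces=meta["spaces"],
                              class_labels=meta["class_labels"],
                              n_trees=meta["n_trees"],
                              max_depth=meta["max_depth"],
                              rng_seed=meta["rng_seed"])
        obj = cls(spec)
        obj._rf = joblib.load(d / "rf.joblib")
        obj.classes_ = meta["classes_"]
        return obj


def train_rf(block: DescriptorBlock, labels,
             spec: ClassifierSpec | None = None) -> RandomForestModel:
    """Train a seeded RF on one block; labels aligned to block rows."""
    spec = spec or ClassifierSpec(algorithm="RF", spaces=[block.space])
    return RandomForestModel(spec).fit(block, labels)


def _similarity_to_train(query: np.ndarray, ref_matrix: np.ndarray,
                         kind: str, scale: tuple | None) -> np.ndarray:
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != ref_matrix.shape[1]:
        raise ValueError(
            f"query length {q.shape[1]} does not match reference "
            f"space dimension {ref_matrix.shape[1]}"
        )
    if kind == "BIT":
        return tanimoto_matrix(q, ref_matrix)[0]
    mean, std = scale
    qs = (q - mean) / std
    dist = np.sqrt(((qs - ref_matrix) ** 2).sum(axis=1))
    return 1.0 / (1.0 + dist)


class MudraClassifier:
    """Multi-descriptor read-across: consensus over per-space kNN votes.

    ``fit`` only stores the training reference (descriptor blocks aligned on
    one compound list, plus labels); all work happens at prediction time.
    """

    def __init__(self, spec: ClassifierSpec | None = None, k: int | None = None,
                 similarity_floor: float | None = None):
        self.spec = spec or ClassifierSpec(
            algorithm="MUDRA", spaces=["MORGAN", "KEYS166"])
        self.k = k if k is not None else self.spec.k
        self.similarity_floor = (similarity_floor if similarity_floor is not None
                                 else self.spec.similarity_floor)
        self.blocks: dict[str, DescriptorBlock] = {}
        self.labels: list[str] = []
        self._scales: dict[str, tuple] = {}

    def fit(self, blocks: dict[str, DescriptorBlock], labels) -> "MudraClassifier":
        labels = list(labels)
        ids = None
        for space, block in blocks.items():
            if ids is None:
                ids = block.compound_ids
            elif block.compound_ids != ids:
                raise ValueError("all spaces must index the same compounds")
            if block.n_compounds != len(labels):
                raise ValueError("labels not aligned to block rows")
        if not (1 <= self.k <= len(labels)):
            raise ValueError(f"k={self.k} outside [1, n_train]")
        self.blocks = dict(blocks)
        self.labels = labels
        self._scales = {}
        for space, block in blocks.items():
            if block.kind == "CONTINUOUS":
                mean = block.matrix.mean(axis=0)
                std = block.matrix.std(axis=0)
                std = np.where(std > 0, std, 1.0)
                self._scales[space] = (mean, std)
                # store scaled copy for distance computation
                block.matrix_scaled = (block.matrix - mean) / std
        return self

    def _space_vote(self, space: str, query: np.ndarray):
        block = self.blocks[space]
        ref = (block.matrix_scaled if block.kind == "CONTINUOUS"
               else block.matrix)
        if block.kind == "CONTINUOUS":
            mean, std = self._scales[space]
            q = (np.atleast_2d(np.asarray(query, dtype=float)) - mean) / std
            if q.shape[1] != ref.shape[1]:
                raise ValueError("query length mismatch")
            dist = np.sqrt(((q - ref) ** 2).sum(axis=1))
            sims = 1.0 / (1.0 + dist)
        else:
            sims = _similarity_to_train(query, ref, "BIT", None)
        order = np.argsort(-sims, kind="stable")[: self.k]
        votes: dict[str, float] = {}
        for i in order:
            if sims[i] < self.similarity_floor:
                continue
            votes[self.labels[i]] = votes.get(self.labels[i], 0.0) + float(sims[i])
        top = int(order[0])
        return {
            "top_neighbor_id": block.compound_ids[top],
            "top_similarity": float(sims[top]),
            "votes": votes,
        }

    def predict_one(self, query_vectors: dict[str, np.ndarray],
                    compound_id: str = "") -> Prediction:
        """Predict one query given a vector per configured space."""
        evidence = {}
        for space in self.blocks:
            if space not in query_vectors:
                raise ValueError(f"query missing a vector for space {space}")
            evidence[space] = self._space_vote(space, query_vectors[space])

        # consensus: the space whose top neighbor is most similar wins
        best_space = max(evidence, key=lambda s: evidence[s]["top_similarity"])
        votes = evidence[best_space]["votes"]
        total = sum(votes.values())
        if total == 0:
            # no neighbor cleared the similarity floor in any space
            label = self.labels[0]
            return Prediction(compound_id=compound_id, predicted_label=label,
                              confidence=0.0, per_space_evidence=evidence,
                              low_evidence=True)
        label = max(votes, key=lambda c: (votes[c], c))
        return Prediction(compound_id=compound_id, predicted_label=label,
                          confidence=votes[label] / total,
                          per_space_evidence=evidence)

    def predict(self, query_blocks: dict[str, DescriptorBlock]) -> list[Prediction]:
        ids = None
        for space, block in query_blocks.items():
            if ids is None:
                ids = block.compound_ids
        preds = []
        for i, cid in enumerate(ids or []):
            vectors = {s: b.matrix[i] for s, b in query_blocks.items()}
            preds.append(self.predict_one(vectors, compound_id=cid))
        return preds

    # ------------------------------------------------------------ persistence

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for space, block in self.blocks.items():
            block.to_csv(d / f"{space}.csv", d / f"{space}.json")
        with open(d / "mudra.json", "w") as fh:
            json.dump({"k": self.k, "similarity_floor": self.similarity_floor,
                       "spaces": list(self.blocks), "labels": self.labels},
                      fh, indent=2)

    @classmethod
    def load(cls, directory) -> "MudraClassifier":
        d = Path(directory)
        with open(d / "mudra.json") as fh:
            meta = json.load(fh)
        obj = cls(spec=ClassifierSpec(algorithm="MUDRA", spaces=meta["spaces"],
                                      k=meta["k"],
                                      similarity_floor=meta["similarity_floor"]))
        blocks = {s: DescriptorBlock.from_csv(d / f"{s}.csv", d / f"{s}.json")
                  for s in meta["spaces"]}
        return obj.fit(blocks, meta["labels"])


def mudra_predict(query_vectors: dict[str, np.ndarray],
                  ref: MudraClassifier, compound_id: str = "") -> Prediction:
    """Functional alias for single-query MuDRA prediction."""
    return ref.predict_one(query_vectors, compound_id)


def predict_batch(model, blocks, ad: AdThreshold | None = None) -> list[Prediction]:
    """One Prediction per compound; AD assessed for RF models when supplied.

    MuDRA predictions are never AD-assessed (instance-based approach);
    their in_ad stays NOT_ASSESSED.
    """
    if isinstance(model, MudraClassifier):
        return model.predict(blocks)

    block = blocks if isinstance(blocks, DescriptorBlock) else blocks[model.space]
    if block.n_compounds == 0:
        return []
    labels = model.predict(block.matrix)
    confs = model.confidence(block.matrix)
    if ad is not None:
        flags = in_domain_batch(block.matrix, ad)
        status = ["IN" if f else "OUT" for f in flags]
    else:
        status = ["NOT_ASSESSED"] * block.n_compounds
    return [
        Prediction(compound_id=cid, predicted_label=lab,
                   confidence=float(c), in_ad=st)
        for cid, lab, c, st in zip(block.compound_ids, labels, confs, status)
    ]
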