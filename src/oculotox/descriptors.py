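"""Descriptor spaces: 2048-bit Morgan fingerprints (radius 2), the 166
public structural keys, and the RDKit whole-molecule physicochemical set,
plus the invariance/correlation feature filter applied before modeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .curation import CompoundRecord, StructureParseError

__all__ = [
    "DescriptorBlock",
    "FilterReport",
    "compute_morgan",
    "compute_keys166",
    "compute_physchem",
    "compute_block",
    "filter_features",
    "SPACES",
]

MORGAN_BITS = 2048
MORGAN_RADIUS = 2
N_KEYS = 166

SPACES = ("MORGAN", "KEYS166", "PHYSCHEM")

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_BITS
)


@dataclass
class DescriptorBlock:
    """A named descriptor space's matrix for a compound set.

    ``matrix`` rows align with ``compound_ids``; ``kind`` is BIT for
    fingerprints and CONTINUOUS for physicochemical descriptors.
    """

    space: str
    matrix: np.ndarray
    feature_names: list[str]
    kind: str
    compound_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("descriptor matrix must be 2-D")
        if self.matrix.shape[0] != len(self.compound_ids):
            raise ValueError("row count does not match compound_ids")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature_names")
        if not np.isfinite(self.matrix).all():
            raise ValueError("finalized block contains non-finite values")

    @property
    def n_compounds(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_rows(self, idx) -> "DescriptorBlock":
        idx = np.asarray(idx)
        return DescriptorBlock(
            space=self.space,
            matrix=self.matrix[idx],
            feature_names=list(self.feature_names),
            kind=self.kind,
            compound_ids=[self.compound_ids[i] for i in idx],
        )

    def to_csv(self, path, sidecar_path=None, filter_report=None) -> None:
        """Persist as dense CSV; metadata goes to a JSON sidecar."""
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "compound_id", self.compound_ids)
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {"space": self.space, "kind": self.kind,
                    "feature_names": self.feature_names}
            if filter_report is not None:
                meta["filter_report"] = filter_report.to_dict()
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "DescriptorBlock":
        df = pd.read_csv(path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            space=meta["space"],
            matrix=df[meta["feature_names"]].to_numpy(),
            feature_names=meta["feature_names"],
            kind=meta["kind"],
            compound_ids=[str(c) for c in df["compound_id"]],
        )


@dataclass
class FilterReport:
    """What the invariance/correlation filter removed and why."""

    removed_invariant: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = 0.9

    def to_dict(self) -> dict:
        return {
            "removed_invariant": self.removed_invariant,
            "removed_correlated": [list(t) for t in self.removed_correlated],
            "threshold": self.threshold,
        }


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return mol


def compute_morgan(smiles: str) -> np.ndarray:
    """Circular (ECFP-like) hashed fingerprint, radius 2, 2048 bits."""
    fp = _morgan_gen.GetFingerprint(_mol(smiles))
    arr = np.zeros(MORGAN_BITS, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def compute_keys166(smiles: str) -> np.ndarray:
    """The 166 public structural keys (the toolkit's key 0 is unused)."""
    fp = MACCSkeys.GenMACCSKeys(_mol(smiles))
    arr = np.zeros(167, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr[1:]


# physicochemical feature names are fixed by the installed toolkit version
PHYSCHEM_NAMES: list[str] = [name for name, _ in Descriptors.descList]


def compute_physchem(smiles: str) -> np.ndarray:
    """Whole-molecule physicochemical descriptor vector.

    The descriptor list is the toolkit's full 2-D set; its length is
    version-dependent and recorded in ``PHYSCHEM_NAMES``. Non-finite values
    are replaced downstream by dropping either the feature or the compound.
    """
    # re-parse from the canonical form: several descriptors accumulate
    # atom-order-dependent float rounding, and identical structures must
    # give bit-identical vectors
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(_mol(smiles)))
    vals = Descriptors.CalcMolDescriptors(mol)
    return np.array([vals[name] for name in PHYSCHEM_NAMES], dtype=float)


_COMPUTE = {
    "MORGAN": (compute_morgan, "BIT",
               [f"morgan_{i}" for i in range(MORGAN_BITS)]),
    "KEYS166": (compute_keys166, "BIT",
                [f"key_{i}" for i in range(1, N_KEYS + 1)]),
    "PHYSCHEM": (compute_physchem, "CONTINUOUS", PHYSCHEM_NAMES),
}


def compute_block(records: list[CompoundRecord] | list[str], space: str,
                  drop_nonfinite: str = "feature") -> DescriptorBlock:
    """Compute one descriptor space for a compound set.

    ``drop_nonfinite`` controls how non-finite physicochemical values are
    resolved: "feature" drops the offending columns, "compound" drops the
    offending rows.
    """
    if space not in _COMPUTE:
        raise ValueError(f"unknown descriptor space {space!r}")
    func, kind, names = _COMPUTE[space]
    if records and isinstance(records[0], CompoundRecord):
        ids = [r.record_id for r in records]
        smiles = [r.smiles for r in records]
    else:
        ids = [f"c{i}" for i in range(len(records))]
        smiles = list(records)

    rows = [func(s) for s in smiles]
    matrix = (np.vstack(rows) if rows
              else np.zeros((0, len(names))))
    names = list(names)
    if kind == "CONTINUOUS" and matrix.size:
        finite = np.isfinite(matrix)
        if not finite.all():
            if drop_nonfinite == "feature":
                keep = finite.all(axis=0)
                matrix = matrix[:, keep]
                names = [n for n, k in zip(names, keep) if k]
            else:
                keep = finite.all(axis=1)
                matrix = matrix[keep]
                ids = [i for i, k in zip(ids, keep) if k]
    return DescriptorBlock(space=space, matrix=matrix, feature_names=names,
                           kind=kind, compound_ids=ids)


def filter_features(
    block: DescriptorBlock, threshold: float = 0.9
) -> tuple[DescriptorBlock, FilterReport]:
    """Remove invariant features, then one feature of every highly
    correlated pair.

    Invariant (zero-variance) columns go first. Remaining feature pairs are
    scanned in the block's feature order; whenever |Pearson r| exceeds the
    threshold, the later-indexed feature is dropped. The surviving block has
    no pair with |r| above the threshold, and applying the filter again
    removes nothing.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"correlation threshold must be in (0, 1]: {threshold}")
    report = FilterReport(threshold=threshold)
    X = block.matrix
    names = block.feature_names

    variant = X.std(axis=0) > 0
    report.removed_invariant = [n for n, v in zip(names, variant) if not v]
    X = X[:, variant]
    names = [n for n, v in zip(names, variant) if v]

    if X.shape[1] > 1:
        with np.errstate(invalid="ignore"):
            corr = np.abs(np.corrcoef(X, rowvar=False))
        keep = np.ones(X.shape[1], dtype=bool)
        for j in range(X.shape[1]):
            if not keep[j]:
                continue
            for i in range(j):
                if keep[i] and corr[i, j] > threshold:
                    keep[j] = False
                    report.removed_correlated.append(
                        (names[i], names[j], float(corr[i, j]))
                    )
                    break
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]

    out = DescriptorBlock(space=block.space, matrix=X, feature_names=names,
                          kind=block.kind, compound_ids=list(block.compound_ids))
    return out, report
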