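"""Synthetic SMILES datasets with a controlled structure–activity signal.

A small scaffold grammar (alkyl chains, benzene/heteroaryl cores, a fixed
set of linkers and decorating groups) is enumerated into a library of valid,
unique organic structures. Positives carry a planted "toxophore"
substructure — by default a sulfonic-acid group, a classic corrosive
chemotype — appended to a grammar base; negatives are toxophore-free by
construction and verified so by substructure match. Labels equal toxophore
presence XOR seeded noise, so the attainable classification ceiling is set
directly by the noise rate.

For curation testing the generator can also inject, at configured rates,
salt forms (recognized counter ions appended), concordant and discordant
duplicate records, inorganics and true mixtures. The manifest records
exactly what was injected and is the ground truth the curation tests
reconcile against.

The grammar is deliberately tiny so every substructure claim is auditable;
it does not emulate the chemical-space distribution of any real inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem

from .curation import CompoundRecord

__all__ = [
    "FixtureConfig",
    "FixtureManifest",
    "generate_fixture",
    "generate_ghs_fixture",
    "fixture_manifest",
    "ghs_to_three_class",
    "DEFAULT_TOXOPHORE",
]

#: planted activity-conferring substructure (SMILES suffix, also used as
#: the SMARTS the labels are checked against)
DEFAULT_TOXOPHORE = "S(=O)(=O)O"

_CHAINS = tuple("C" * k for k in range(1, 13))

# one open slot {a}
_TEMPLATES_1 = (
    "{a}", "{a}O", "{a}N", "{a}Cl", "{a}Br", "{a}C#N", "{a}C(=O)O",
    "{a}C1CCCCC1", "{a}c1ccccc1", "{a}c1ccncc1", "{a}c1ccco1", "{a}C(C)O",
)

# two open slots {a}, {b}
_TEMPLATES_2 = (
    "{a}O{b}", "{a}C(=O)O{b}", "{a}C(=O)N{b}", "{a}C(=O){b}", "{a}N{b}",
    "{a}c1ccc({b})cc1", "{a}c1cccc({b})c1", "{a}c1ccccc1{b}",
    "{a}OCCO{b}", "{a}OCC(=O)O{b}", "{a}N(C)C(=O){b}", "{a}C(O){b}",
    "{a}C({b})C#N", "{a}Oc1ccc({b})cc1", "{a}C(=O)Oc1ccc({b})cc1",
    "{a}c1ccc({b}O)cc1", "{a}c1ccc({b})cc1Cl", "{a}c1ccc({b})cc1F",
    "{a}c1ccc({b})cc1Br", "{a}OC(=O)c1ccc({b})cc1", "{a}NC(=O)c1ccc({b})cc1",
    "{a}OCC(O)CO{b}", "{a}SC{b}", "{a}OC(=O)CC(=O)O{b}",
    "{a}N1CCN(CC1){b}", "{a}N1CCC(CC1){b}", "{a}c1ccc({b})cn1",
)

_SALT_SUFFIXES = (".Cl", ".O", ".[Na+].[Cl-]")
_INORGANICS = ("O", "[Na+].[Cl-]", "O=S(=O)(O)O", "N", "O=[N+]([O-])O",
               "[K+].[Br-]")
_MIXTURES = ("CCO.CCC", "c1ccccc1.CCCCO", "CCCCO.CCOCCC",
             "CC(=O)OCC.CCCCCC")


@dataclass
class FixtureConfig:
    n_compounds: int = 400
    toxophore: str = DEFAULT_TOXOPHORE
    noise_rate: float = 0.0
    imbalance_ratio: float = 1.0  # negatives per positive
    duplicate_rate: float = 0.0
    salt_rate: float = 0.0
    inorganic_rate: float = 0.0
    mixture_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("noise_rate", "duplicate_rate", "salt_rate",
                     "inorganic_rate", "mixture_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.imbalance_ratio <= 0:
            raise ValueError("imbalance_ratio must be positive")
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be non-negative")


@dataclass
class FixtureManifest:
    n_records: int = 0
    n_pos: int = 0
    n_neg: int = 0
    n_noise_flips: int = 0
    n_salts: int = 0
    n_concordant_duplicates: int = 0
    n_discordant_duplicates: int = 0
    n_inorganics: int = 0
    n_mixtures: int = 0
    class_counts: dict = field(default_factory=dict)


def _enumerate_bases() -> list[str]:
    """Raw (appendable) grammar strings, before canonical dedup."""
    out = []
    for t in _TEMPLATES_1:
        out.extend(t.format(a=a) for a in _CHAINS)
    for t in _TEMPLATES_2:
        out.extend(t.format(a=a, b=b) for a in _CHAINS for b in _CHAINS)
    return out


def _unique_valid(smiles_list, exclude_pattern=None) -> list[str]:
    """Canonicalize, drop invalid, dedupe, optionally exclude matches."""
    patt = Chem.MolFromSmarts(exclude_pattern) if exclude_pattern else None
    seen = set()
    out = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        if patt is not None and mol.HasSubstructMatch(patt):
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            out.append(can)
    return sorted(out)


@lru_cache(maxsize=4)
def _pools(toxophore: str) -> tuple[tuple, tuple]:
    bases = _enumerate_bases()
    negatives = _unique_valid(bases, exclude_pattern=toxophore)
    positives = _unique_valid([b + toxophore for b in bases])
    patt = Chem.MolFromSmarts(toxophore)
    positives = tuple(
        s for s in positives
        if Chem.MolFromSmiles(s).HasSubstructMatch(patt)
    )
    return positives, tuple(negatives)


def _sample(pool, size, rng) -> list[str]:
    if size > len(pool):
        raise ValueError(
            f"requested {size} structures but the grammar yields only "
            f"{len(pool)}")
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in np.sort(idx)]


def generate_fixture(cfg: FixtureConfig) -> tuple[list[CompoundRecord],
                                                  FixtureManifest]:
    """Generate a raw (pre-curation) binary-labeled record list."""
    manifest = FixtureManifest()
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_compounds
    if n == 0:
        return [], manifest

    n_pos = int(round(n / (1.0 + cfg.imbalance_ratio)))
    n_pos = max(min(n_pos, n), 0)
    n_neg = n - n_pos
    pos_pool, neg_pool = _pools(cfg.toxophore)

    records = []
    for i, smi in enumerate(_sample(pos_pool, n_pos, rng)):
        records.append(CompoundRecord(record_id=f"pos{i:05d}", smiles=smi,
                                      label="POS", source="fixture"))
    for i, smi in enumerate(_sample(neg_pool, n_neg, rng)):
        records.append(CompoundRecord(record_id=f"neg{i:05d}", smiles=smi,
                                      label="NEG", source="fixture"))
    manifest.n_pos, manifest.n_neg = n_pos, n_neg

    # label noise: flip exactly round(noise_rate * n) labels
    n_flip = int(round(cfg.noise_rate * n))
    flip_idx = rng.choice(n, size=n_flip, replace=False)
    for i in flip_idx:
        r = records[i]
        records[i] = CompoundRecord(
            record_id=r.record_id, smiles=r.smiles,
            label="NEG" if r.label == "POS" else "POS", source=r.source)
    manifest.n_noise_flips = n_flip

    # salt forms: append recognized counter ions / solvents
    n_salt = int(round(cfg.salt_rate * n))
    for j, i in enumerate(rng.choice(n, size=n_salt, replace=False)):
        r = records[i]
        suffix = _SALT_SUFFIXES[j % len(_SALT_SUFFIXES)]
        records[i] = CompoundRecord(record_id=r.record_id,
                                    smiles=r.smiles + suffix,
                                    label=r.label, source=r.source)
    manifest.n_salts = n_salt

    # duplicates: two concordant for every discordant injection
    n_dup = int(round(cfg.duplicate_rate * n))
    for j, i in enumerate(rng.choice(n, size=n_dup, replace=False)):
        r = records[i]
        discordant = (j % 3 == 2)
        label = (("NEG" if r.label == "POS" else "POS")
                 if discordant else r.label)
        records.append(CompoundRecord(record_id=f"dup{j:05d}",
                                      smiles=r.smiles, label=label,
                                      source="fixture-duplicate"))
        if discordant:
            manifest.n_discordant_duplicates += 1
        else:
            manifest.n_concordant_duplicates += 1

    n_inorg = int(round(cfg.inorganic_rate * n))
    for j in range(n_inorg):
        records.append(CompoundRecord(
            record_id=f"inorg{j:05d}", smiles=_INORGANICS[j % len(_INORGANICS)],
            label="NEG", source="fixture-inorganic"))
    manifest.n_inorganics = n_inorg

    n_mix = int(round(cfg.mixture_rate * n))
    for j in range(n_mix):
        records.append(CompoundRecord(
            record_id=f"mix{j:05d}", smiles=_MIXTURES[j % len(_MIXTURES)],
            label="NEG", source="fixture-mixture"))
    manifest.n_mixtures = n_mix

    manifest.n_records = len(records)
    manifest.class_counts = _count_labels(records)
    return records, manifest


#: per-GHS-class planted substructures (severity-tiered chemotypes);
#: NC structures are plain grammar bases
_GHS_SUFFIXES = {
    "CAT1": "S(=O)(=O)O",       # sulfonic acid — corrosive chemotype
    "CAT2A": "S(=O)(=O)N",      # sulfonamide — milder irritant chemotype
    "CAT2B": "[N+](=O)[O-]",    # nitro — mild irritant chemotype
}


def generate_ghs_fixture(class_counts: dict[str, int],
                         rng_seed: int = 0) -> tuple[list[CompoundRecord],
                                                     FixtureManifest]:
    """Generate a multiclass set with the requested per-GHS-class counts."""
    rng = np.random.default_rng(rng_seed)
    records = []
    for cls in ("CAT1", "CAT2A", "CAT2B", "NC"):
        count = class_counts.get(cls, 0)
        if cls == "NC":
            _, pool = _pools(DEFAULT_TOXOPHORE)
        else:
            pool, _ = _pools(_GHS_SUFFIXES[cls])
        for i, smi in enumerate(_sample(pool, count, rng)):
            records.append(CompoundRecord(record_id=f"{cls.lower()}{i:05d}",
                                          smiles=smi, label=cls,
                                          source="fixture-ghs"))
    manifest = FixtureManifest(n_records=len(records),
                               class_counts=_count_labels(records))
    return records, manifest


def ghs_to_three_class(label: str) -> str:
    """Collapse GHS categories to the three modeling super-classes."""
    return {"CAT1": "CORROSIVE", "CAT2A": "IRRITANT", "CAT2B": "IRRITANT",
            "NC": "NC"}[label]


def _count_labels(records) -> dict:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.label] = counts.get(r.label, 0) + 1
    return counts


def fixture_manifest(records: list[CompoundRecord]) -> FixtureManifest:
    """Summarize an existing record list (class and injected-artifact counts)."""
    m = FixtureManifest(n_records=len(records),
                        class_counts=_count_labels(records))
    m.n_pos = m.class_counts.get("POS", 0)
    m.n_neg = m.class_counts.get("NEG", 0)
    m.n_salts = sum(1 for r in records if "." in r.smiles
                    and r.source == "fixture")
    m.n_inorganics = sum(1 for r in records if r.source == "fixture-inorganic")
    m.n_mixtures = sum(1 for r in records if r.source == "fixture-mixture")
    dup = [r for r in records if r.source == "fixture-duplicate"]
    by_smiles = {r.smiles: r.label for r in records
                 if r.source != "fixture-duplicate"}
    for r in dup:
        if by_smiles.get(r.smiles) == r.label:
            m.n_concordant_duplicates += 1
        else:
            m.n_discordant_duplicates += 1
    return m
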