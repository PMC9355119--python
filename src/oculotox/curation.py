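"""Chemical curation: standardization, salt stripping, mixture/inorganic
removal and duplicate resolution.

The workflow follows the widely used curation protocol for QSAR modeling
sets: every structure is normalized to a single canonical form (counter ions
stripped, charges neutralized where valence rules allow, chemotypes such as
nitro groups written in one canonical resonance form), records that are not
single organic molecules are discarded, and structural duplicates are
collapsed — or removed entirely when the duplicated structure carries
conflicting hazard labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "CurationLog",
    "StructureParseError",
    "standardize_structure",
    "standardize_records",
    "remove_inorganics_and_mixtures",
    "deduplicate",
    "curate",
    "read_smiles_table",
    "read_sdf",
    "write_curated_csv",
]

#: Labels a record may carry. POS/NEG for binary endpoints, the four GHS
#: eye-hazard categories for multiclass work, UNLABELED for screening input.
VALID_LABELS = ("POS", "NEG", "CAT1", "CAT2A", "CAT2B", "NC", "UNLABELED")

#: Canonical SMILES of fragments treated as counter ions or solvents when a
#: standardized structure contains more than one fragment. Anything not in
#: this set makes the record a true mixture. Configurable per call.
DEFAULT_COUNTER_IONS = frozenset(
    {
        # halides / hydrohalic acids
        "[Cl-]", "[Br-]", "[I-]", "[F-]", "Cl", "Br", "I", "F",
        # alkali / alkaline-earth cations
        "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Zn+2]", "[NH4+]",
        # small inorganic acids/bases and their anions
        "O=S(=O)(O)O", "O=S(=O)([O-])O", "O=S(=O)([O-])[O-]",
        "O=[N+]([O-])O", "O=[N+]([O-])[O-]", "O=C(O)O", "O=C([O-])O",
        "OP(=O)(O)O", "N",
        # common solvents
        "O", "CO", "CCO", "CC(C)=O", "C(Cl)(Cl)Cl",
    }
)


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable structure: {smiles!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """One structure with provenance and an optional hazard label."""

    record_id: str
    smiles: str
    label: str = "UNLABELED"
    source: str = ""
    curation_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    def with_flags(self, *flags: str) -> "CompoundRecord":
        return replace(self, curation_flags=self.curation_flags | set(flags))


@dataclass
class CurationLog:
    """Per-reason removal counts; always reconciles with input/output sizes."""

    input_count: int = 0
    output_count: int = 0
    removed_unparseable: int = 0
    removed_inorganic: int = 0
    removed_mixture: int = 0
    removed_discordant: int = 0
    removed_redundant_duplicate: int = 0
    discordant_groups: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.removed_unparseable
            + self.removed_inorganic
            + self.removed_mixture
            + self.removed_discordant
            + self.removed_redundant_duplicate
        )

    def check(self) -> None:
        if self.input_count != self.output_count + self.total_removed:
            raise AssertionError(f"curation log does not reconcile: {self}")

    def merged_with(self, other: "CurationLog") -> "CurationLog":
        out = CurationLog(
            input_count=self.input_count,
            output_count=other.output_count,
        )
        for f in (
            "removed_unparseable",
            "removed_inorganic",
            "removed_mixture",
            "removed_discordant",
            "removed_redundant_duplicate",
            "discordant_groups",
        ):
            setattr(out, f, getattr(self, f) + getattr(other, f))
        return out

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


_UNCHARGER = rdMolStandardize.Uncharger()


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def standardize_structure(
    smiles: str, counter_ions: frozenset = DEFAULT_COUNTER_IONS
) -> str:
    """Return the canonical standardized SMILES for one record.

    Normalization (nitro groups to the charge-separated canonical resonance
    form, consistent aromaticity perception) is applied first; then, for
    multi-fragment inputs, the largest organic fragment is kept whenever all
    remaining fragments are recognized counter ions or solvents. Charges are
    neutralized where valence rules allow (quaternary ammonium keeps its
    charge). The result is idempotent: standardizing twice equals
    standardizing once.

    A multi-fragment result (a true mixture) or an inorganic structure is
    returned as-is; downstream removal handles those.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise StructureParseError(smiles)
    try:
        mol = rdMolStandardize.Cleanup(mol)
    except Exception as exc:  # sanitization failure inside Cleanup
        raise StructureParseError(smiles) from exc

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        organic = [f for f in frags if _has_carbon(f)]
        others = [f for f in frags if not _has_carbon(f)]
        if organic:
            keep = max(organic, key=lambda f: f.GetNumHeavyAtoms())
            rest = [f for f in organic if f is not keep] + others
            if all(Chem.MolToSmiles(f) in counter_ions for f in rest):
                mol = keep

    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def standardize_records(
    records: list[CompoundRecord],
    counter_ions: frozenset = DEFAULT_COUNTER_IONS,
) -> tuple[list[CompoundRecord], CurationLog]:
    """Standardize every record; unparseable records are dropped and logged."""
    log = CurationLog(input_count=len(records))
    kept = []
    for rec in records:
        try:
            std = standardize_structure(rec.smiles, counter_ions)
        except StructureParseError:
            log.removed_unparseable += 1
            continue
        flags = ["STANDARDIZED"]
        if "." in rec.smiles and "." not in std:
            flags.append("SALT_STRIPPED")
        kept.append(replace(rec, smiles=std).with_flags(*flags))
    log.output_count = len(kept)
    log.check()
    return kept, log


def remove_inorganics_and_mixtures(
    records: list[CompoundRecord],
) -> tuple[list[CompoundRecord], CurationLog]:
    """Drop records with no carbon atom (inorganic) and records whose
    standardized form still holds more than one fragment (true mixture)."""
    log = CurationLog(input_count=len(records))
    kept = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            log.removed_unparseable += 1
            continue
        if not _has_carbon(mol):
            log.removed_inorganic += 1
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            log.removed_mixture += 1
            continue
        kept.append(rec)
    log.output_count = len(kept)
    log.check()
    return kept, log


def _structure_key(smiles: str) -> str:
    """Canonical, stereo-aware structural identity key."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return Chem.MolToSmiles(mol)


def deduplicate(
    records: list[CompoundRecord],
) -> tuple[list[CompoundRecord], CurationLog]:
    """Collapse structural duplicates.

    Records are grouped by canonical structure key. Groups whose labels all
    agree collapse to the first record (flagged DEDUPLICATED when the group
    had more than one member); groups with conflicting labels are removed
    entirely and counted as discordant.
    """
    log = CurationLog(input_count=len(records))
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = _structure_key(rec.smiles)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    kept = []
    for key in order:
        group = groups[key]
        labels = {r.label for r in group}
        if len(labels) > 1:
            log.removed_discordant += len(group)
            log.discordant_groups += 1
            continue
        rec = group[0]
        if len(group) > 1:
            rec = rec.with_flags("DEDUPLICATED")
            log.removed_redundant_duplicate += len(group) - 1
        kept.append(rec)
    log.output_count = len(kept)
    log.check()
    return kept, log


def curate(
    records: list[CompoundRecord],
    counter_ions: frozenset = DEFAULT_COUNTER_IONS,
) -> tuple[list[CompoundRecord], CurationLog]:
    """Full curation: standardize, remove inorganics/mixtures, deduplicate."""
    std, log = standardize_records(records, counter_ions)
    clean, log2 = remove_inorganics_and_mixtures(std)
    final, log3 = deduplicate(clean)
    log = log.merged_with(log2).merged_with(log3)
    log.check()
    return final, log


# ---------------------------------------------------------------- I/O


def read_smiles_table(
    path,
    smiles_col: str = "smiles",
    label_col: str | None = "label",
    id_col: str | None = None,
    sep: str = ",",
) -> list[CompoundRecord]:
    """Read records from a CSV/TSV table of SMILES and labels."""
    df = pd.read_csv(path, sep=sep)
    if id_col is None and "record_id" in df.columns:
        id_col = "record_id"
    records = []
    for i, row in df.iterrows():
        rid = str(row[id_col]) if id_col else f"row{i}"
        label = "UNLABELED"
        if label_col and label_col in df.columns and pd.notna(row[label_col]):
            label = str(row[label_col])
        records.append(
            CompoundRecord(record_id=rid, smiles=str(row[smiles_col]),
                           label=label, source=str(path))
        )
    return records


def read_sdf(path, label_tag: str | None = "label") -> list[CompoundRecord]:
    """Read records from an SDF file, taking labels from a named SD tag."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        label = "UNLABELED"
        if label_tag and mol.HasProp(label_tag):
            label = mol.GetProp(label_tag)
        rid = mol.GetProp("_Name") if mol.GetProp("_Name") else f"sdf{i}"
        records.append(
            CompoundRecord(record_id=rid, smiles=Chem.MolToSmiles(mol),
                           label=label, source=str(path))
        )
    return records


def write_curated_csv(records: list[CompoundRecord], path) -> None:
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "smiles": [r.smiles for r in records],
            "label": [r.label for r in records],
            "curation_flags": [";".join(sorted(r.curation_flags)) for r in records],
        }
    )
    df.to_csv(path, index=False)
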