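"""SMILES handling, the 20-feature chemical descriptor vector, and dataset filters.

Every molecule entering the pipeline is represented by a :class:`MoleculeRecord`
holding a canonical SMILES, an identifier and a kinase-family label.  The
descriptor vector collects twenty whole-molecule features (ring and bond
counts, shape descriptors, surface area, hydrogen-bonding counts and the
drug-like triple QED / SAS / logP) used both for the kinase-inhibition
likelihood classifier and for drug-likeness profiling of generated sets.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig
from rdkit.Chem import rdMolDescriptors as rdmd

RDLogger.DisableLog("rdApp.*")

# fragment-contribution synthetic-accessibility scorer shipped with RDKit contrib
sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402


class Family(str, Enum):
    """Kinase family labels, plus background and generated provenance tags."""

    SRC = "SRC"
    ABL1 = "ABL1"
    CSF1R = "CSF1R"
    EGFR = "EGFR"
    FLT3 = "FLT3"
    KDR = "KDR"
    LCK = "LCK"
    MAPK10 = "MAPK10"
    MAPK14 = "MAPK14"
    MET = "MET"
    BACKGROUND = "BACKGROUND"
    GENERATED = "GENERATED"


KINASE_FAMILIES: tuple[Family, ...] = tuple(
    f for f in Family if f not in (Family.BACKGROUND, Family.GENERATED)
)


@dataclass(frozen=True)
class MoleculeRecord:
    """A canonical SMILES with identifier, family label and provenance.

    ``family == Family.GENERATED`` if and only if ``origin_family`` is set to
    the family of the seed molecule the record was perturbed from.
    """

    smiles: str
    id: str
    family: Family
    origin_family: Family | None = None

    def __post_init__(self) -> None:
        if (self.family is Family.GENERATED) != (self.origin_family is not None):
            raise ValueError(
                f"record {self.id!r}: family=GENERATED requires origin_family "
                "(and vice versa)"
            )


#: Fixed, documented column order of the 20-feature descriptor vector.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "ring_count",
    "exact_mol_weight",
    "rotatable_bonds",
    "fraction_csp3",
    "hall_kier_alpha",
    "labute_asa",
    "aliphatic_carbocycles",
    "aliphatic_heterocycles",
    "aliphatic_rings",
    "amide_bonds",
    "aromatic_carbocycles",
    "aromatic_heterocycles",
    "aromatic_rings",
    "stereocenters",
    "bridgehead_atoms",
    "hba",
    "hbd",
    "qed",
    "sas",
    "logp",
)


class InvalidSmilesError(ValueError):
    """Raised when a descriptor computation is asked for an unparsable SMILES."""


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES; multi-fragment inputs (salts, mixtures) are rejected
    because decoded outputs must be single molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if len(Chem.GetMolFrags(mol)) != 1:
        return None
    return mol


def canonicalize(smiles: str) -> str | None:
    """Return RDKit's canonical SMILES, or ``None`` for unparsable input.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.  Never
    raises on bad SMILES; the ``None`` marker signals the failure explicitly.
    """
    mol = _mol_from_smiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def is_valid(smiles: str) -> bool:
    return canonicalize(smiles) is not None


# sascorer is module state; indirect so tests can stub the (slow, fragment-
# table driven) score with a constant.
_sas_impl: Callable[[Chem.Mol], float] = sascorer.calculateScore


def set_sas_implementation(fn: Callable[[Chem.Mol], float] | None) -> None:
    """Swap the synthetic-accessibility scorer (``None`` restores the default)."""
    global _sas_impl
    _sas_impl = sascorer.calculateScore if fn is None else fn


def compute_descriptors(record: MoleculeRecord | str) -> dict[str, float]:
    """Compute the 20-feature descriptor vector for one molecule.

    Accepts a record or a bare SMILES.  Deterministic for a fixed toolkit
    version.  Stereocenter counting includes unassigned centers; existing
    stereochemistry is preserved but never enumerated.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    rec_id = record.id if isinstance(record, MoleculeRecord) else smiles
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"invalid SMILES for record {rec_id!r}: {smiles!r}")
    n_stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False))
    return {
        "ring_count": float(rdmd.CalcNumRings(mol)),
        "exact_mol_weight": float(Descriptors.ExactMolWt(mol)),
        "rotatable_bonds": float(rdmd.CalcNumRotatableBonds(mol)),
        "fraction_csp3": float(rdmd.CalcFractionCSP3(mol)),
        "hall_kier_alpha": float(rdmd.CalcHallKierAlpha(mol)),
        "labute_asa": float(rdmd.CalcLabuteASA(mol)),
        "aliphatic_carbocycles": float(rdmd.CalcNumAliphaticCarbocycles(mol)),
        "aliphatic_heterocycles": float(rdmd.CalcNumAliphaticHeterocycles(mol)),
        "aliphatic_rings": float(rdmd.CalcNumAliphaticRings(mol)),
        "amide_bonds": float(rdmd.CalcNumAmideBonds(mol)),
        "aromatic_carbocycles": float(rdmd.CalcNumAromaticCarbocycles(mol)),
        "aromatic_heterocycles": float(rdmd.CalcNumAromaticHeterocycles(mol)),
        "aromatic_rings": float(rdmd.CalcNumAromaticRings(mol)),
        "stereocenters": float(n_stereo),
        "bridgehead_atoms": float(rdmd.CalcNumBridgeheadAtoms(mol)),
        "hba": float(rdmd.CalcNumHBA(mol)),
        "hbd": float(rdmd.CalcNumHBD(mol)),
        "qed": float(QED.qed(mol)),
        "sas": float(_sas_impl(mol)),
        "logp": float(Crippen.MolLogP(mol)),
    }


def drug_like_triple(record: MoleculeRecord | str) -> tuple[float, float, float]:
    """Return (QED, SAS, logP): drug-likeness in [0,1], synthetic
    accessibility in [1,10] (low = easy), and Crippen octanol-water logP."""
    d = compute_descriptors(record)
    return d["qed"], d["sas"], d["logp"]


@dataclass(frozen=True)
class DatasetFilter:
    """Admission thresholds for dataset curation; all bounds are strict."""

    max_mw: float = 700.0
    max_logp: float = 6.0
    max_rotatable: int = 10


def admit(record: MoleculeRecord | str, flt: DatasetFilter = DatasetFilter()) -> bool:
    """True iff molecular weight, logP and rotatable-bond count are all
    strictly below the filter's bounds."""
    d = compute_descriptors(record)
    return (
        d["exact_mol_weight"] < flt.max_mw
        and d["logp"] < flt.max_logp
        and d["rotatable_bonds"] < flt.max_rotatable
    )


def descriptor_table(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """Descriptor vectors for a record list, one row per record, indexed by id,
    columns in :data:`DESCRIPTOR_NAMES` order."""
    rows = [compute_descriptors(r) for r in records]
    df = pd.DataFrame(rows, index=[r.id for r in records], columns=list(DESCRIPTOR_NAMES))
    df.index.name = "id"
    return df


# ---------------------------------------------------------------------------
# File formats: `SMILES[<ws>ID]` line files and smiles,id,family CSV tables.

def read_smiles_file(path: str | os.PathLike, family: Family) -> list[MoleculeRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            smi = canonicalize(parts[0])
            if smi is None:
                raise InvalidSmilesError(f"{path}:{i + 1}: invalid SMILES {parts[0]!r}")
            rec_id = parts[1] if len(parts) > 1 else f"{family.value}_{i}"
            records.append(MoleculeRecord(smi, rec_id, family))
    return records


def write_smiles_file(path: str | os.PathLike, records: Iterable[MoleculeRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.id}\n")


def read_labeled_csv(path: str | os.PathLike) -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype=str)
    records = []
    for row in df.itertuples(index=False):
        smi = canonicalize(row.smiles)
        if smi is None:
            raise InvalidSmilesError(f"{path}: invalid SMILES {row.smiles!r} (id {row.id})")
        origin = getattr(row, "origin_family", None)
        records.append(
            MoleculeRecord(
                smi,
                str(row.id),
                Family(row.family),
                Family(origin) if isinstance(origin, str) and origin else None,
            )
        )
    return records


def write_labeled_csv(path: str | os.PathLike, records: Iterable[MoleculeRecord]) -> None:
    pd.DataFrame(
        [
            {
                "smiles": r.smiles,
                "id": r.id,
                "family": r.family.value,
                "origin_family": r.origin_family.value if r.origin_family else "",
            }
            for r in records
        ]
    ).to_csv(path, index=False)
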