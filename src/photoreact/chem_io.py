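"""Structure ingestion, standardization, eligibility filtering and deduplication.

Builds the modeling-eligible molecule set from SMILES or SDF input: each
structure is normalized (aromaticity, mesomerism, tautomerism) to one
deterministic canonical form, filtered by molecular weight, fragment count
and element/charge/radical rules, and deduplicated on a stereochemistry-free
InChIKey so that stereoisomers collapse to a single record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, inchi
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Elements allowed in the curated organic set; anything else counts as "metal".
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

#: Primary rejection reason codes, in precedence order.
REASON_ORDER = ("valence", "metal", "radical", "charged", "multifragment", "mw_low", "mw_high")


@dataclass(frozen=True)
class EligibilityRule:
    """Structure eligibility thresholds for the curated data set.

    Molecular-weight window defaults to 98-1080 g/mol (average mass unless
    ``monoisotopic`` is set); multi-fragment entries, metal-containing,
    net-charged and radical species are excluded by default.
    """

    mw_min: float = 98.0
    mw_max: float = 1080.0
    max_fragments: int = 1
    allow_metals: bool = False
    allow_net_charge: bool = False
    allow_radicals: bool = False
    monoisotopic: bool = False

    def __post_init__(self) -> None:
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed, possibly standardized molecule with identity hashes."""

    mol_id: str
    canonical_smiles: str
    inchi_key_nostereo: str
    mol_weight: float
    mol_weight_monoisotopic: float
    n_fragments: int
    net_charge: int = 0
    n_radical_electrons: int = 0
    has_metal: bool = False
    valence_error: bool = False
    metadata: dict = field(default_factory=dict)

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.canonical_smiles)
        if mol is None:
            raise ValueError(f"stored SMILES no longer parses: {self.canonical_smiles}")
        return mol


def _nostereo_inchi_key(mol: Chem.Mol) -> str:
    ix = inchi.MolToInchi(mol, options="/SNon", treatWarningAsError=False)
    if not ix:
        # InChI generation can fail on exotica; fall back to canonical SMILES.
        return "SMILES:" + Chem.MolToSmiles(mol)
    return inchi.InchiToInchiKey(ix)


def _record_from_mol(mol: Chem.Mol, mol_id: str, metadata: dict | None = None) -> MoleculeRecord:
    return MoleculeRecord(
        mol_id=mol_id,
        canonical_smiles=Chem.MolToSmiles(mol),
        inchi_key_nostereo=_nostereo_inchi_key(mol),
        mol_weight=Descriptors.MolWt(mol),
        mol_weight_monoisotopic=Descriptors.ExactMolWt(mol),
        n_fragments=len(Chem.GetMolFrags(mol)),
        net_charge=Chem.GetFormalCharge(mol),
        n_radical_electrons=sum(a.GetNumRadicalElectrons() for a in mol.GetAtoms()),
        has_metal=any(a.GetSymbol() not in ORGANIC_ELEMENTS for a in mol.GetAtoms()),
        metadata=dict(metadata or {}),
    )


@dataclass
class ParseResult:
    records: list[MoleculeRecord]
    n_skipped: int
    skipped_entries: list[str] = field(default_factory=list)


def parse_structures(path: str | Path, format: str = "smiles") -> ParseResult:
    """Parse a SMILES (one molecule per line, optional tab-separated id) or
    SDF v2000 file into :class:`MoleculeRecord` objects.

    Unparseable entries are skipped and counted; a file with zero parseable
    entries is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    skipped: list[str] = []
    if format == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                skipped.append(smi)
                continue
            records.append(_record_from_mol(mol, mol_id))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped.append(f"entry {i + 1}")
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
            records.append(_record_from_mol(mol, mol_id))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'smiles' or 'sdf'")
    if not records:
        raise ValueError(f"no parseable entries in {path}")
    if skipped:
        logger.warning("skipped %d unparseable entries in %s", len(skipped), path)
    return ParseResult(records=records, n_skipped=len(skipped), skipped_entries=skipped)


_TAUTOMER_ENUMERATOR: rdMolStandardize.TautomerEnumerator | None = None


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _TAUTOMER_ENUMERATOR
    if _TAUTOMER_ENUMERATOR is None:
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMER_ENUMERATOR


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Normalize aromaticity, mesomerism and tautomerism to one canonical form.

    The output is deterministic: identical inputs always yield the same
    canonical SMILES. A structure that fails sanitization (valence error) is
    returned flagged ``valence_error`` so the eligibility filter can reject it.
    """
    try:
        mol = Chem.MolFromSmiles(record.canonical_smiles)
        if mol is None:
            raise ValueError("unparseable")
        # Cleanup: sanitize, normalize functional groups (mesomeric forms such
        # as pentavalent vs charge-separated nitro), reionize, fixed aromaticity.
        mol = rdMolStandardize.Cleanup(mol)
        # Fixed canonical tautomer under RDKit's scoring model.
        mol = _tautomer_enumerator().Canonicalize(mol)
    except Exception:
        return replace(record, valence_error=True)
    out = _record_from_mol(mol, record.mol_id, record.metadata)
    return out


@dataclass
class Rejection:
    record: MoleculeRecord
    reason: str


def rejection_reason(record: MoleculeRecord, rule: EligibilityRule) -> str | None:
    """Return the primary rejection reason code, or None if eligible."""
    mw = record.mol_weight_monoisotopic if rule.monoisotopic else record.mol_weight
    checks = {
        "valence": record.valence_error,
        "metal": record.has_metal and not rule.allow_metals,
        "radical": record.n_radical_electrons > 0 and not rule.allow_radicals,
        "charged": record.net_charge != 0 and not rule.allow_net_charge,
        "multifragment": record.n_fragments > rule.max_fragments,
        "mw_low": mw < rule.mw_min,
        "mw_high": mw > rule.mw_max,
    }
    for reason in REASON_ORDER:
        if checks[reason]:
            return reason
    return None


def filter_eligible(
    mols: Iterable[MoleculeRecord], rule: EligibilityRule | None = None
) -> tuple[list[MoleculeRecord], list[Rejection]]:
    """Partition records into (kept, rejected-with-reason) under ``rule``."""
    rule = rule or EligibilityRule()
    kept: list[MoleculeRecord] = []
    rejected: list[Rejection] = []
    for rec in mols:
        reason = rejection_reason(rec, rule)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append(Rejection(rec, reason))
    return kept, rejected


def deduplicate(
    mols: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], dict[str, list[str]]]:
    """Drop duplicates on the stereochemistry-free InChIKey, keeping the first
    occurrence.

    Returns the unique records and a map ``kept mol_id -> [duplicate mol_ids]``
    so callers can merge associated spectrum records (peak lists of duplicates
    are unioned downstream).
    """
    seen: dict[str, MoleculeRecord] = {}
    merged: dict[str, list[str]] = {}
    for rec in mols:
        key = rec.inchi_key_nostereo
        if key in seen:
            merged.setdefault(seen[key].mol_id, []).append(rec.mol_id)
        else:
            seen[key] = rec
    return list(seen.values()), merged


def curate(
    records: Iterable[MoleculeRecord], rule: EligibilityRule | None = None
) -> tuple[list[MoleculeRecord], list[Rejection], dict[str, list[str]]]:
    """standardize -> filter_eligible -> deduplicate, the full curation chain."""
    standardized = [standardize(r) for r in records]
    kept, rejected = filter_eligible(standardized, rule)
    unique, merged = deduplicate(kept)
    return unique, rejected, merged


def write_curated(
    kept: Sequence[MoleculeRecord], rejected: Sequence[Rejection], out_dir: str | Path
) -> None:
    """Write curated SMILES plus a kept/rejected audit CSV."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "curated.smi", "w") as fh:
        for rec in kept:
            fh.write(f"{rec.canonical_smiles}\t{rec.mol_id}\n")
    rows = [{"mol_id": r.mol_id, "status": "kept", "reason": ""} for r in kept]
    rows += [{"mol_id": r.record.mol_id, "status": "rejected", "reason": r.reason} for r in rejected]
    pd.DataFrame(rows).to_csv(out_dir / "audit.csv", index=False)
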