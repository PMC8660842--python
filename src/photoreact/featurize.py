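"""Feature-matrix assembly: fingerprints, 2D descriptors, Md histograms and
external quantum-descriptor tables.

Each descriptor family produces a :class:`FeatureMatrix` (mol_ids × named
columns, pandas-backed) with provenance; families can be concatenated
column-wise over the molecules every family succeeded on. Molecules a
calculator fails on are dropped and tracked, mirroring the slightly different
per-family training-set sizes that arise with real calculators.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .md import MdConfig, md_vector
from .element_data import ELEMENT_TABLE_VERSION

logger = logging.getLogger(__name__)

#: Family name -> expected column count (None = determined at runtime).
FAMILY_SIZES = {
    "maccs": 166,
    "morgan": 1024,
    "rdkitfp": 2048,
    "md": 1010,
    "oned2d": None,
    "qd": 10,
}

#: Families from the CDK/PaDEL ecosystem; no backend for them is configured
#: here, so requesting one raises with a clear message.
UNAVAILABLE_FAMILIES = {"cdk", "extcdk", "pubchem", "sub", "subc"}


@dataclass
class FeatureMatrix:
    """Molecules × descriptors with provenance.

    ``values`` is a DataFrame indexed by mol_id; ``provenance`` lists the
    descriptor sets that produced the columns; ``failed`` maps set name to the
    mol_ids its calculator could not process.
    """

    values: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)
    failed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def mol_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def write(self, prefix: str | Path) -> None:
        """Write values as CSV plus a JSON provenance sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(f"{prefix}.csv", index_label="mol_id")
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"provenance": self.provenance, "failed": self.failed}, fh, indent=2)

    @classmethod
    def read(cls, prefix: str | Path) -> "FeatureMatrix":
        values = pd.read_csv(f"{prefix}.csv", index_col="mol_id")
        values.index = values.index.astype(str)
        sidecar_path = Path(f"{prefix}.json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        return cls(values, meta.get("provenance", []), meta.get("failed", {}))


def _mol_from_smiles(smi: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smi)


def _morgan_row(mol: Chem.Mol, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.frombuffer(gen.GetFingerprint(mol).ToBitString().encode(), "u1") - ord("0")


def _rdkitfp_row(mol: Chem.Mol, n_bits: int = 2048) -> np.ndarray:
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    return np.frombuffer(gen.GetFingerprint(mol).ToBitString().encode(), "u1") - ord("0")


def _maccs_row(mol: Chem.Mol) -> np.ndarray:
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 always unset
    arr = np.frombuffer(fp.ToBitString().encode(), "u1") - ord("0")
    return arr[1:]


_2D_DESCRIPTORS: list[tuple[str, Callable]] | None = None


def _oned2d_descriptors() -> list[tuple[str, Callable]]:
    global _2D_DESCRIPTORS
    if _2D_DESCRIPTORS is None:
        _2D_DESCRIPTORS = [(name, fn) for name, fn in Descriptors.descList]
    return _2D_DESCRIPTORS


def _oned2d_row(mol: Chem.Mol) -> np.ndarray:
    vals = []
    for _, fn in _oned2d_descriptors():
        try:
            v = fn(mol)
        except Exception:
            v = np.nan
        vals.append(v)
    row = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(row)):
        raise ValueError("descriptor calculator produced non-finite values")
    return row


def compute_fingerprint(
    smiles_or_mol, family: str, md_config: MdConfig | None = None
) -> np.ndarray:
    """One descriptor row for one molecule. Binary families yield {0,1};
    count families nonnegative integers; deterministic for a given input."""
    family = family.lower()
    mol = _mol_from_smiles(smiles_or_mol) if isinstance(smiles_or_mol, str) else smiles_or_mol
    if mol is None:
        raise ValueError("unparseable structure")
    if family == "morgan":
        return _morgan_row(mol)
    if family == "maccs":
        return _maccs_row(mol)
    if family == "rdkitfp":
        return _rdkitfp_row(mol)
    if family == "md":
        return md_vector(mol, md_config)
    if family == "oned2d":
        return _oned2d_row(mol)
    if family in UNAVAILABLE_FAMILIES:
        raise NotImplementedError(
            f"descriptor family {family!r} needs a CDK/PaDEL-compatible backend, "
            "which is not configured; available families: "
            + ", ".join(sorted(set(FAMILY_SIZES) - {"qd"}))
        )
    raise ValueError(f"unknown descriptor family {family!r}")


def _column_names(family: str, n: int) -> list[str]:
    if family == "oned2d":
        return [f"oned2d_{name}" for name, _ in _oned2d_descriptors()]
    return [f"{family}_{i}" for i in range(n)]


def featurize_set(
    mol_ids: Sequence[str],
    smiles: Sequence[str],
    family: str,
    md_config: MdConfig | None = None,
) -> FeatureMatrix:
    """Featurize a molecule list with one descriptor family, dropping (and
    recording) molecules the calculator fails on."""
    rows, kept, failed = [], [], []
    for mol_id, smi in zip(mol_ids, smiles):
        try:
            rows.append(compute_fingerprint(smi, family, md_config))
            kept.append(mol_id)
        except NotImplementedError:
            raise
        except Exception:
            failed.append(mol_id)
    if not rows:
        raise ValueError(f"no molecule could be featurized with family {family!r}")
    mat = np.vstack(rows)
    expected = FAMILY_SIZES.get(family)
    if expected is not None and mat.shape[1] != expected:
        raise AssertionError(f"{family} produced {mat.shape[1]} columns, expected {expected}")
    df = pd.DataFrame(mat, index=pd.Index(kept, name="mol_id"), columns=_column_names(family, mat.shape[1]))
    prov = {"set": family, "n_columns": int(mat.shape[1])}
    if family == "md":
        cfg = md_config or MdConfig()
        prov.update(
            n_bins=cfg.n_bins, resolution=cfg.resolution, max_bonds=cfg.max_bonds,
            distance_factor=cfg.distance_factor, bin_anchor=0.0,
            element_table_version=ELEMENT_TABLE_VERSION,
        )
    if failed:
        logger.warning("family %s failed on %d molecules", family, len(failed))
    return FeatureMatrix(df, [prov], {family: failed} if failed else {})


def combine_sets(mats: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation restricted to molecules present in every
    input matrix (calculators may fail on different molecules)."""
    if not mats:
        raise ValueError("no matrices to combine")
    if len(mats) == 1:
        return mats[0]
    common = mats[0].values.index
    for m in mats[1:]:
        common = common.intersection(m.values.index)
    if len(common) == 0:
        raise ValueError("no molecule was successfully featurized by every set")
    # preserve the first matrix's molecule order
    common = [i for i in mats[0].mol_ids if i in set(common)]
    values = pd.concat([m.values.loc[common] for m in mats], axis=1)
    prov = [p for m in mats for p in m.provenance]
    failed: dict[str, list[str]] = {}
    for m in mats:
        failed.update(m.failed)
    return FeatureMatrix(values, prov, failed)


def external_qd(path: str | Path) -> FeatureMatrix:
    """Load an externally computed quantum-descriptor table (10 columns of
    estimated E_HOMO / E_LUMO / GAP values in eV from several models, indexed
    by mol_id). The estimators themselves are a pluggable external interface."""
    df = pd.read_csv(path, index_col="mol_id")
    df.index = df.index.astype(str)
    if df.shape[1] != FAMILY_SIZES["qd"]:
        raise ValueError(f"quantum-descriptor table must have exactly 10 value columns, got {df.shape[1]}")
    return FeatureMatrix(df, [{"set": "qd", "n_columns": 10, "units": "eV"}], {})
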