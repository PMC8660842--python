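"""Synthetic molecule / spectrum / phototoxicity generator.

Emulates the statistical structure of a literature-derived UV-Vis peak-list
data set so every pipeline stage is testable without licensed data:

* molecules come from two scaffold families — saturated (alkanes, alcohols,
  amines, ethers; no pi system) and conjugated ((hetero)aromatics, polyenes,
  extended fused systems) — decorated with enumerable substituent tails so
  the emitted set is structurally diverse, eligible (MW 98-1080, one
  neutral fragment) and standardizable;
* the primary absorption maximum follows a transparent monotone
  structure->spectrum rule, lambda = intercept + slope * conjugation + noise,
  where conjugation is the atom count of the largest pi system, so that
  saturated scaffolds absorb far below 290 nm and extended chromophores
  inside the 290-700 nm window;
* molar extinction coefficients are log-normal with family-dependent
  location, giving roughly balanced POS/NEG classes plus the characteristic
  sub-290 nm high-MEC negative peaks;
* realistic corruptions are injected at configurable rates with ground truth
  retained: log-unit MEC transcription (MEC replaced by log10(MEC), only
  plausible where every MEC is in [1e3, 1e5]), boundary-proximal primary
  peaks, and missing MEC values;
* phototoxicity outcomes are Bernoulli with class-conditional rates skewed
  the way an absorption-based alarm behaves (sensitive, unspecific).

The rule is deliberately not a physical model: it makes the ML stage's
success or failure interpretable and fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

from .labeling import LabelConfig, Peak, SpectrumRecord, label_spectrum
from .phototox import NON_TOXIC, TOXIC, PhototoxRecord

# --------------------------------------------------------------------------
# Scaffold library: finite curated SMILES templates with enumerable tails.
# Tails concatenate onto the final atom of the scaffold SMILES.

SATURATED_SCAFFOLDS = (
    "CCCCCCCC", "CCCCCCCCCC", "CCCCCCCCCCCC", "CC(C)CCCCC", "CC(C)CC(C)CC",
    "C1CCCCC1CC", "C1CCCCC1CCCC", "C1CCC(CC1)CC", "CC(CC)CCCC", "CCC(CC)CCC",
)
SATURATED_TAILS = (
    "", "C", "CC", "CCC", "O", "CO", "CCO", "N", "CN", "CCN", "OC", "OCC",
    "C(C)C", "CC(C)C", "COC", "CCOC",
)

# Single-ring / short chromophores: pi systems of ~6-8 atoms, absorbing
# below the 290 nm window edge but often with high MEC.
SMALL_CONJUGATED_SCAFFOLDS = (
    "c1ccccc1", "Cc1ccccc1", "c1ccc(Cl)cc1", "COc1ccccc1", "c1ccc(cc1)",
    "c1ccoc1", "c1ccsc1", "C=Cc1ccccc1", "CC(=O)c1ccccc1", "c1ccncc1",
)
SMALL_TAILS = ("C", "CC", "CCC", "CCCC", "OC", "OCC", "CCO", "N(C)C", "CC(C)C", "CCOC")

# Extended chromophores: fused aromatics, biaryls, push-pull and polyene
# systems with pi systems of >= 10 atoms, absorbing inside the window.
EXTENDED_SCAFFOLDS = (
    "c1ccc2ccccc2c1",                 # naphthalene
    "c1ccc2cc3ccccc3cc2c1",           # anthracene
    "c1ccc2ccc3ccccc3c2c1",           # phenanthrene
    "c1ccc2ncccc2c1",                 # quinoline
    "c1ccc2[nH]ccc2c1",               # indole
    "c1ccc(-c2ccccc2)cc1",            # biphenyl
    "O=C(c1ccccc1)c1ccccc1",          # benzophenone
    "C(=Cc1ccccc1)c1ccccc1",          # stilbene
    "N(=Nc1ccccc1)c1ccccc1",          # azobenzene
    "O=CC=Cc1ccccc1",                 # cinnamaldehyde
    "C(=Cc1ccccc1)C=Cc1ccccc1",       # diphenylbutadiene
    "c1ccc2oc3ccccc3c2c1",            # dibenzofuran
    "c1ccc2sc3ccccc3c2c1",            # dibenzothiophene
    "c1ccc2nc3ccccc3nc2c1",           # phenazine-like
    "O=c1oc2ccccc2cc1",               # coumarin
)
EXTENDED_TAILS = ("", "C", "CC", "CCC", "OC", "OCC", "N(C)C", "CCO", "Cl", "CCCC")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions the generator emulates.

    Wavelength rule: lambda = intercept + slope * conjugation + N(0, noise_sd)
    nm. MEC log10 locations/scales are per family. Corruption probabilities
    apply per molecule. ``pos_fraction`` is the target share of extended
    chromophores, hence (approximately) of POS labels.
    """

    n_molecules: int = 1000
    pos_fraction: float = 0.5
    wavelength_intercept: float = 150.0
    wavelength_slope: float = 16.0
    wavelength_noise_sd: float = 12.0
    mec_log10_saturated: tuple[float, float] = (2.0, 0.5)
    mec_log10_small: tuple[float, float] = (3.5, 0.45)
    mec_log10_extended: tuple[float, float] = (4.0, 0.35)
    log_corruption_p: float = 0.03
    boundary_peak_p: float = 0.04
    missing_mec_p: float = 0.03
    p_toxic_given_pos: float = 0.5
    p_toxic_given_neg: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("n_molecules must be >= 2")
        for p in (
            self.pos_fraction, self.log_corruption_p, self.boundary_peak_p,
            self.missing_mec_p, self.p_toxic_given_pos, self.p_toxic_given_neg,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SyntheticMolecule:
    mol_id: str
    smiles: str
    family: str  # "saturated" or "conjugated"
    pool: str    # "saturated", "small_conjugated", "extended"
    conjugation: int  # atoms in the largest pi system


def pi_system_size(mol: Chem.Mol) -> int:
    """Atom count of the largest connected system of conjugated / multiple /
    aromatic bonds (the latent chromophore size)."""
    parent = list(range(mol.GetNumAtoms()))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    relevant = False
    for bond in mol.GetBonds():
        if bond.GetIsConjugated() or bond.GetIsAromatic() or bond.GetBondTypeAsDouble() > 1:
            relevant = True
            a, b = find(bond.GetBeginAtomIdx()), find(bond.GetEndAtomIdx())
            if a != b:
                parent[a] = b
    if not relevant:
        return 0
    sizes: dict[int, set[int]] = {}
    for bond in mol.GetBonds():
        if bond.GetIsConjugated() or bond.GetIsAromatic() or bond.GetBondTypeAsDouble() > 1:
            for idx in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()):
                sizes.setdefault(find(idx), set()).add(idx)
    return max(len(s) for s in sizes.values())


def _build(scaffold: str, tail: str) -> Chem.Mol | None:
    mol = Chem.MolFromSmiles(scaffold + tail)
    return mol


def gen_molecules(cfg: GeneratorConfig) -> list[SyntheticMolecule]:
    """Draw eligible, standardizable molecules from the scaffold library.

    Every emitted structure parses, has one neutral fragment, contains only
    whitelisted elements, and has MW inside [98, 1080]; tails are extended
    with methylenes when a combination falls below the MW floor.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[SyntheticMolecule] = []
    pools = {
        "saturated": (SATURATED_SCAFFOLDS, SATURATED_TAILS),
        "small_conjugated": (SMALL_CONJUGATED_SCAFFOLDS, SMALL_TAILS),
        "extended": (EXTENDED_SCAFFOLDS, EXTENDED_TAILS),
    }
    i = 0
    while len(out) < cfg.n_molecules:
        i += 1
        u = rng.random()
        if u < cfg.pos_fraction:
            pool = "extended"
        elif u < cfg.pos_fraction + (1 - cfg.pos_fraction) * 0.6:
            pool = "saturated"
        else:
            pool = "small_conjugated"
        scaffolds, tails = pools[pool]
        scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
        tail = tails[int(rng.integers(len(tails)))]
        mol = _build(scaffold, tail)
        attempts = 0
        while mol is not None and Descriptors.MolWt(mol) < 98.0 and attempts < 20:
            tail = tail + "C"
            mol = _build(scaffold, tail)
            attempts += 1
        if mol is None or not (98.0 <= Descriptors.MolWt(mol) <= 1080.0):
            continue
        out.append(
            SyntheticMolecule(
                mol_id=f"syn-{len(out) + 1:05d}",
                smiles=Chem.MolToSmiles(mol),
                family="saturated" if pool == "saturated" else "conjugated",
                pool=pool,
                conjugation=pi_system_size(mol),
            )
        )
    return out


@dataclass
class CorruptionTruth:
    log_mec: list[str] = field(default_factory=list)
    boundary_peak: list[str] = field(default_factory=list)
    missing_mec: list[str] = field(default_factory=list)


def gen_spectra(
    mols: Sequence[SyntheticMolecule], cfg: GeneratorConfig
) -> tuple[list[SpectrumRecord], CorruptionTruth]:
    """Generate per-molecule peak lists from the latent conjugation sizes,
    then inject the configured corruptions (ground truth retained)."""
    rng = np.random.default_rng(cfg.seed + 1)
    loc = {
        "saturated": cfg.mec_log10_saturated,
        "small_conjugated": cfg.mec_log10_small,
        "extended": cfg.mec_log10_extended,
    }
    records: list[SpectrumRecord] = []
    truth = CorruptionTruth()
    for m in mols:
        lam = cfg.wavelength_intercept + cfg.wavelength_slope * m.conjugation
        lam += rng.normal(0.0, cfg.wavelength_noise_sd)
        lam = max(lam, 30.0)
        mu, sd = loc[m.pool]
        mec = 10.0 ** rng.normal(mu, sd)
        peaks = [(lam, mec)]
        for _ in range(int(rng.integers(0, 4))):  # 0-3 secondary maxima
            peaks.append(
                (lam * rng.uniform(0.55, 0.85), mec * 10.0 ** -rng.uniform(0.2, 1.0))
            )
        # --- corruptions ------------------------------------------------
        if rng.random() < cfg.boundary_peak_p:
            peaks[0] = (float(rng.uniform(281.0, 317.0)), peaks[0][1])
            truth.boundary_peak.append(m.mol_id)
        mec_vals = [p[1] for p in peaks]
        if (
            all(1e3 <= v <= 1e5 for v in mec_vals)
            and rng.random() < cfg.log_corruption_p
        ):
            peaks = [(wl, float(np.log10(v))) for wl, v in peaks]
            truth.log_mec.append(m.mol_id)
        peak_objs = [Peak(round(wl, 1), round(v, 4)) for wl, v in peaks]
        if peak_objs and rng.random() < cfg.missing_mec_p:
            k = int(rng.integers(len(peak_objs)))
            peak_objs[k] = Peak(peak_objs[k].wavelength, None)
            truth.missing_mec.append(m.mol_id)
        records.append(
            SpectrumRecord(m.mol_id, tuple(peak_objs), solvent="MeOH", source_id="synthetic")
        )
    return records, truth


def gen_phototox(
    labels: dict[str, str], cfg: GeneratorConfig
) -> list[PhototoxRecord]:
    """Bernoulli assay outcomes with class-conditional toxicity rates."""
    rng = np.random.default_rng(cfg.seed + 2)
    out = []
    for mol_id in labels:
        p = cfg.p_toxic_given_pos if labels[mol_id] == "POS" else cfg.p_toxic_given_neg
        out.append(PhototoxRecord(mol_id, TOXIC if rng.random() < p else NON_TOXIC))
    return out


def simulate(cfg: GeneratorConfig, out_dir: str | Path | None = None):
    """Full fixture: molecules, spectra (with corruption truth), labels and
    phototoxicity outcomes; optionally written to ``out_dir`` as curated.smi,
    peaks.csv, tox.csv and truth.json."""
    mols = gen_molecules(cfg)
    spectra, truth = gen_spectra(mols, cfg)
    label_cfg = LabelConfig()
    labels = {r.mol_id: label_spectrum(r, label_cfg).label for r in spectra}
    tox = gen_phototox(labels, cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "curated.smi", "w") as fh:
            for m in mols:
                fh.write(f"{m.smiles}\t{m.mol_id}\n")
        with open(out_dir / "peaks.csv", "w") as fh:
            fh.write("mol_id,wavelength_nm,mec,solvent,source_id\n")
            for r in spectra:
                for p in r.peaks:
                    mec = "" if p.mec is None else p.mec
                    fh.write(f"{r.mol_id},{p.wavelength},{mec},{r.solvent},{r.source_id}\n")
        with open(out_dir / "tox.csv", "w") as fh:
            fh.write("mol_id,outcome\n")
            for t in tox:
                fh.write(f"{t.mol_id},{t.outcome}\n")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(
                {
                    "latents": {m.mol_id: {"family": m.family, "pool": m.pool, "conjugation": m.conjugation} for m in mols},
                    "corruptions": {
                        "log_mec": truth.log_mec,
                        "boundary_peak": truth.boundary_peak,
                        "missing_mec": truth.missing_mec,
                    },
                    "labels": labels,
                },
                fh,
                indent=2,
            )
    return mols, spectra, truth, labels, tox
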