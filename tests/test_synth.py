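"""Synthetic fixture generator: validity, latent-signal structure,
corruption bookkeeping and end-to-end learnability."""

import json

import numpy as np
import pytest
from rdkit import Chem
from scipy import stats

from photoreact.chem_io import _record_from_mol, filter_eligible, standardize
from photoreact.evaluation import confusion, metrics_from_counts
from photoreact.featurize import featurize_set
from photoreact.labeling import label_spectrum
from photoreact.models import RFConfig, predict, train_rf
from photoreact.synth import (
    GeneratorConfig,
    gen_molecules,
    gen_phototox,
    gen_spectra,
    pi_system_size,
    simulate,
)


class TestGenMolecules:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_molecules=60, seed=4)
        a = gen_molecules(cfg)
        b = gen_molecules(cfg)
        assert [m.smiles for m in a] == [m.smiles for m in b]

    def test_every_structure_is_eligible(self, small_fixture):
        records = []
        for m in small_fixture["mols"][:80]:
            mol = Chem.MolFromSmiles(m.smiles)
            assert mol is not None
            records.append(standardize(_record_from_mol(mol, m.mol_id)))
        kept, rejected = filter_eligible(records)
        assert not rejected

    def test_family_correlates_with_aromaticity(self, small_fixture):
        fam = np.array([1 if m.family == "conjugated" else 0 for m in small_fixture["mols"]])
        arom = np.array(
            [
                sum(a.GetIsAromatic() for a in Chem.MolFromSmiles(m.smiles).GetAtoms())
                for m in small_fixture["mols"]
            ]
        )
        assert stats.pointbiserialr(fam, arom).statistic > 0.5

    def test_pi_system_size_examples(self):
        assert pi_system_size(Chem.MolFromSmiles("CCCCCCCC")) == 0
        assert pi_system_size(Chem.MolFromSmiles("c1ccccc1")) == 6
        assert pi_system_size(Chem.MolFromSmiles("c1ccc2ccccc2c1")) == 10

    def test_balance_near_target(self):
        cfg = GeneratorConfig(n_molecules=1000, seed=11)
        _, _, _, labels, _ = simulate(cfg)
        pos = np.mean([v == "POS" for v in labels.values()])
        assert abs(pos - cfg.pos_fraction) <= 0.05


class TestGenSpectra:
    def test_conjugation_wavelength_correlation(self):
        cfg = GeneratorConfig(n_molecules=400, seed=19)
        mols = gen_molecules(cfg)
        spectra, truth = gen_spectra(mols, cfg)
        moved = set(truth.boundary_peak)
        pairs = [
            (m.conjugation, r.peaks[0].wavelength)
            for m, r in zip(mols, spectra)
            if m.mol_id not in moved
        ]
        rho = stats.spearmanr([p[0] for p in pairs], [p[1] for p in pairs]).statistic
        assert rho > 0.8

    def test_saturated_stratum_labels_neg(self):
        cfg = GeneratorConfig(n_molecules=400, seed=19)
        mols = gen_molecules(cfg)
        spectra, _ = gen_spectra(mols, cfg)
        labels = {r.mol_id: label_spectrum(r).label for r in spectra}
        stratum = [labels[m.mol_id] for m in mols if m.conjugation == 0]
        assert len(stratum) > 30
        assert np.mean([l == "NEG" for l in stratum]) > 0.9

    def test_zero_corruption_rates(self):
        cfg = GeneratorConfig(
            n_molecules=150, seed=3, log_corruption_p=0.0, boundary_peak_p=0.0, missing_mec_p=0.0
        )
        mols = gen_molecules(cfg)
        _, truth = gen_spectra(mols, cfg)
        assert not truth.log_mec and not truth.boundary_peak and not truth.missing_mec

    def test_missing_mec_truth_matches_records(self):
        cfg = GeneratorConfig(n_molecules=200, seed=5, missing_mec_p=0.3)
        mols = gen_molecules(cfg)
        spectra, truth = gen_spectra(mols, cfg)
        with_missing = {r.mol_id for r in spectra if any(p.mec is None for p in r.peaks)}
        assert with_missing == set(truth.missing_mec)


class TestGenPhototox:
    def test_class_conditional_rates(self):
        labels = {f"m{i}": ("POS" if i % 2 else "NEG") for i in range(800)}
        cfg = GeneratorConfig(n_molecules=10, seed=1, p_toxic_given_pos=0.5, p_toxic_given_neg=0.1)
        tox = {t.mol_id: t.outcome for t in gen_phototox(labels, cfg)}
        pos_rate = np.mean([tox[k] == "toxic" for k, v in labels.items() if v == "POS"])
        neg_rate = np.mean([tox[k] == "toxic" for k, v in labels.items() if v == "NEG"])
        assert pos_rate > neg_rate + 0.2

    def test_zero_rate_all_nontoxic(self):
        labels = {f"m{i}": "POS" for i in range(50)}
        cfg = GeneratorConfig(n_molecules=10, seed=1, p_toxic_given_pos=0.0, p_toxic_given_neg=0.0)
        assert all(t.outcome == "non_toxic" for t in gen_phototox(labels, cfg))

    def test_seeded_determinism(self):
        labels = {f"m{i}": "POS" for i in range(50)}
        cfg = GeneratorConfig(n_molecules=10, seed=8)
        assert gen_phototox(labels, cfg) == gen_phototox(labels, cfg)


class TestEndToEnd:
    def test_accuracy_degrades_with_spectral_noise(self):
        """Held-out accuracy falls monotonically over low/mid/high noise."""
        qs = []
        for sd in (12.0, 60.0, 150.0):
            cfg = GeneratorConfig(n_molecules=600, seed=23, wavelength_noise_sd=sd)
            mols, spectra, _, labels, _ = simulate(cfg)
            fm = featurize_set([m.mol_id for m in mols], [m.smiles for m in mols], "morgan")
            y = np.array([labels[i] for i in fm.mol_ids])
            model = train_rf(fm.values.iloc[:450], y[:450], RFConfig(n_trees=150, seed=1))
            preds = predict(model, fm.values.iloc[450:])
            rep = metrics_from_counts(confusion(list(y[450:]), [p.predicted for p in preds]))
            qs.append(rep.q)
        assert qs[0] > qs[1] > qs[2]
        assert qs[0] >= 0.80

    def test_simulate_writes_fixture_files(self, tmp_path):
        cfg = GeneratorConfig(n_molecules=40, seed=2)
        simulate(cfg, tmp_path)
        for name in ("curated.smi", "peaks.csv", "tox.csv", "truth.json"):
            assert (tmp_path / name).exists()
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth) == {"latents", "corruptions", "labels"}
        assert len(truth["latents"]) == 40
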