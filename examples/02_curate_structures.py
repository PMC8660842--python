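"""Curate raw structures into a modeling-eligible set.

Standardization normalizes aromaticity, mesomerism and tautomerism;
eligibility filtering enforces MW 98-1080, one neutral organic fragment;
deduplication merges stereoisomers via a stereo-free InChIKey.
"""

from rdkit import Chem

from photoreact.chem_io import _record_from_mol, curate

smiles = {
    "anisole": "COc1ccccc1",
    "benzene": "c1ccccc1",                      # too light: MW 78 < 98
    "nitro-penta": "[O-][N+](=O)c1ccccc1CCCC",  # charge-separated nitro form
    "R-limonene": "CC(=C)[C@@H]1CCC(C)=CC1",
    "S-limonene": "CC(=C)[C@H]1CCC(C)=CC1",     # stereo duplicate of the above
    "salt": "CCCCCCCCCC.Cl",                    # two fragments
}
records = [_record_from_mol(Chem.MolFromSmiles(s), name) for name, s in smiles.items()]

kept, rejected, merged = curate(records)
print("kept:    ", [(r.mol_id, r.canonical_smiles) for r in kept])
print("rejected:", [(r.record.mol_id, r.reason) for r in rejected])
print("merged:  ", merged)

# Expected: anisole, the nitro compound (now in one canonical mesomeric
# form) and one limonene survive; benzene is rejected mw_low, the salt
# multifragment; S-limonene merges into R-limonene.
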