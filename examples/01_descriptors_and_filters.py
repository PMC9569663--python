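"""Descriptor vectors, drug-likeness and dataset admission filters.

Computes the 20-feature chemical descriptor vector for a few molecules,
reports the drug-like triple (QED, SAS, logP) and applies the standard
curation filter (MW < 700 Da, logP < 6, < 10 rotatable bonds).
"""

from kinogen import DatasetFilter, admit, compute_descriptors, drug_like_triple

MOLECULES = {
    "caffeine-like": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "aminopyrimidine": "Nc1ccnc(n1)NCCO",
    "n-tridecane": "C" * 13,
}

flt = DatasetFilter()
for name, smiles in MOLECULES.items():
    d = compute_descriptors(smiles)
    qed, sas, logp = drug_like_triple(smiles)
    ok = admit(smiles, flt)
    print(f"{name} ({smiles})")
    print(
        f"  MW {d['exact_mol_weight']:.1f} Da, rings {int(d['ring_count'])}, "
        f"rotatable {int(d['rotatable_bonds'])}, HBA {int(d['hba'])}, HBD {int(d['hbd'])}"
    )
    print(f"  QED {qed:.3f}  SAS {sas:.2f}  logP {logp:.2f}  admitted: {ok}")

print()
print("QED near 1 means drug-like; SAS near 1 means easy to synthesize;")
print("n-tridecane fails admission because 10 rotatable bonds is not < 10.")
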