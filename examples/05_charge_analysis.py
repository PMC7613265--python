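"""Charge analysis of the degradosome scaffold sequences.

Reports isoelectric point, charged-residue fractions and the kappa
charge-patterning parameter for the functional regions of the scaffold
endoribonuclease and its helicase partner.  Strongly basic RNA-binding
regions (high pI, high FCR) contrast with the acidic remainder of the
scaffold -- the charge polarity behind the proposed membrane electrostatic
switch.
"""
from flexsome.charge import region_report
from flexsome.io import reference_scaffold_sequences

seqs = reference_scaffold_sequences()
rne = seqs["RNASE_E_SCAFFOLD"]
rhlb = seqs["DEAD_BOX_HELICASE"]

cols = ["start", "end", "pI", "FCR", "NCPR", "kappa", "class"]
print("scaffold endoribonuclease:")
print(region_report(rne, [(1, 529), (1, 602), (603, 850),
                          (851, len(rne.residues))])[cols].to_string(index=False))
print()
print("helicase partner:")
print(region_report(rhlb, [(1, 390), (391, 421)])[cols].to_string(index=False))
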