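"""Miller units for a beta-galactosidase reporter assay.

Computes normalized reporter activity for a riboswitch-controlled lacZ
fusion grown without and with ligand; the ratio of the two activities is the
switch's in-vivo dynamic range.
"""

from switchsim import MillerInput, miller_units

no_ligand = MillerInput(A420=0.82, A550=0.02, A600=0.55, t=12.0, V=0.1)
with_ligand = MillerInput(A420=0.11, A550=0.01, A600=0.52, t=12.0, V=0.1)

mu_off = miller_units(no_ligand)
mu_on = miller_units(with_ligand)
print(f"activity without ligand: {mu_off:7.1f} Miller units")
print(f"activity with ligand:    {mu_on:7.1f} Miller units")
print(f"dynamic range:           {mu_off / mu_on:7.1f}-fold repression")
print()
print("MU = 1000 (A420 - 1.75 A550) / (t V A600), with t in minutes and V in")
print("mL: the 1.75*A550 term corrects the 420-nm reading for cell debris.")
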