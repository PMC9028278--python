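"""Diagnostic masses of the 2PCA imidazolidinone chemistry.

Prints the workflow's chemical constants and the a1/b1 doublet for a few
N-terminal residues. The doublet names the first residue of a linearized
cyclic peptide; its 27.9949 Da spacing (one CO) and the residue-independent
marker ion at m/z 107.0609 are the signatures screened for downstream.
"""

from cyclospot import CONSTANTS, doublet_for_residue, doublet_variants

print("Chemical constants (Da):")
for name, value in CONSTANTS.items():
    print(f"  {name:12s} {value:.4f}")

print("\nDiagnostic doublet (b1-type, a1-type m/z), spacing = CO:")
for aa in "TSGK":
    b1, a1 = doublet_for_residue(aa)
    print(f"  {aa}: {b1:9.4f} / {a1:9.4f}   spacing {b1 - a1:.4f}")

print("\nHydrogen-transfer variants for Ser (gas-phase H migration):")
for f in doublet_variants("S", (1, 0, -1)):
    print(f"  {f.label:12s} m/z {f.mz:.4f}")
print(
    "\nA b1/a1 pair at one consistent offset identifies the N-terminal "
    "residue; the +H Ser b1 value is the calculated mass convention often "
    "quoted for imidazolidinone fragments."
)
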