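"""Ring-opening enumeration and targeted inclusion lists.

A single amide hydrolysis linearizes a cyclic peptide at parent + 18.0106 Da
regardless of the site, so every opening is an isomeric candidate. This
script enumerates the candidates for a head-to-tail 12-mer (JB1) and a
disulfide-bridged 14-mer (somatostatin), and prints the inclusion list used
to target the hydrolyzed and 2PCA-derivatized species.
"""

from cyclospot import CyclicPeptide, build_target_list, candidate_for_nterm, enumerate_openings

jb1 = CyclicPeptide("JB1", "CYAAPLKPAKSC", topology="head-to-tail")
cands = enumerate_openings(jb1)
print(f"{jb1.name}: {len(cands)} ring-opening candidates, all at "
      f"{cands[0].neutral_mass:.4f} Da (isomers)")
for c in cands:
    print(f"  site {c.opening_site:2d}  N-term {c.n_term_residue}  {c.sequence}")

sst = CyclicPeptide(
    "somatostatin", "AGCKNFFWKTFTSC", topology="disulfide", disulfide_pair=(3, 14)
)
print(f"\n{sst.name}: {len(enumerate_openings(sst))} openings inside the "
      "Cys3-Cys14 loop")
thr = candidate_for_nterm(sst, "T")
print(f"  Thr openings (doublet says 'T', ladder must disambiguate): "
      f"sites {[c.opening_site for c in thr]}")

print("\nInclusion list for JB1 (parent, +H2O, +H2O+2PCA):")
tl = build_target_list(jb1, max_charge=2)
for e in tl.entries:
    print(f"  {e.species:12s} z={e.charge}  m/z {e.mz:9.4f}")
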