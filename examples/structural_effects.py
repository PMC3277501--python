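"""Residue solvent accessibility and structural effect of replacements.

Builds an ideal poly-alanine alpha-helix, computes Shrake-Rupley solvent
accessibility per residue with a 1.4 A water probe, bins residues into
burial classes, and classifies a handful of inter-species replacements with
the conservative/non-conservative x positive/neutral/negative rule cascade.
"""

from proteotherm import (
    ReplacementRecord,
    classify_replacement,
    make_ideal_helix,
    shrake_rupley_asa,
    summarize_effects,
)

helix = make_ideal_helix(20)
asa = shrake_rupley_asa(helix, probe=1.4, n_points=960)

print("residue  ASA(A^2)  burial")
for idx in (1, 2, 10, 11, 19, 20):
    r = asa[idx]
    print(f"  {r.name}{r.index:<4}  {r.asa:7.1f}  {r.burial}")
# Every residue of an isolated helix is solvent-exposed, most of all the
# ends; burial classes only separate once helices pack into a protein core.

replacements = [
    ("K", "I", "buried"),        # hydrophilic -> hydrophobic in the core
    ("S", "F", "exposed"),       # hydrophobic gain at the surface
    ("V", "A", "buried"),        # smaller aliphatic side chain
    ("S", "K", "exposed"),       # new positive charge at the surface
    ("D", "E", "exposed"),       # conservative charged pair
]
print("\nreplacement  burial        conservative  effect    rule")
classifications = []
for frm, to, burial in replacements:
    rec = ReplacementRecord(position=1, from_res=frm, to_res=to,
                            burial=burial, h_bond_delta=0, elec_delta=0)
    c = classify_replacement(rec)
    classifications.append(c)
    print(f"  {frm}->{to}        {burial:<12}  {str(c.conservative):<12} "
          f"{c.effect:<9} {c.rule}")

summary = summarize_effects(classifications)
print(f"\n{summary['n_conservative']} conservative / "
      f"{summary['n_non_conservative']} non-conservative; "
      f"net exposed positive charge {summary['net_exposed_positive_charge']:+d}")
# Positive effects stabilize (core packing or surface interactions); the
# exposed-charge tally tracks the surface-electrostatics gain of the focal
# species.
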