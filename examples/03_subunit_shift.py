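"""Measure how far an antenna subunit moved between two homologous models.

The comparison model here is the R. salina-like synthetic variant, which
plants a 3.2 Å translation of antenna chain k plus two extra chlorophylls at
published pair distances.  The shift protocol: fit a rigid transform on the
core chains (PsaA/PsaB Cα) only, apply it to the comparison model, then
report the Cα-centroid displacement of the subunit under test.
"""

import chlorofret as cf
from chlorofret.synthetic import psi_supercomplex, rsalina_psi_variant

reference = psi_supercomplex(seed=0)
other = rsalina_psi_variant(reference, seed=1)

shift = cf.subunit_shift(reference, other, core_chain_map={"A": "A", "B": "B"},
                         subunit_a="k")
print(f"ACPI-k centroid shift: {shift.centroid_shift:.2f} A "
      f"(per-atom rmsd {shift.per_atom_rmsd:.2f} A over {shift.n_atoms} Calpha; "
      f"core rmsd {shift.core_rmsd:.2f} A)")

chls, _ = cf.extract_chlorophylls(other)
by_site = {c.site_id[:2]: c for c in chls}
d1 = cf.mg_distance(by_site[("i", 306)], by_site[("Q", 303)])
d2 = cf.mg_distance(by_site[("c", 606)], by_site[("A", 855)])
print(f"a306/i - a303/Q Mg-Mg distance: {d1:.1f} A")
print(f"a606/c - a855/A Mg-Mg distance: {d2:.1f} A")

# The ~3.2 A shift is the planted antenna translocation recovered through the
# core-anchored superposition; the 17.9 A pair sits just inside the 20 A
# cutoff, so losing one partner removes an energy-transfer pathway.
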