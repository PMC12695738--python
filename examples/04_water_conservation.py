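"""Water shell around the Fe–S clusters and its conservation across models.

Collects the waters within 8 Å of the three Fe₄S₄ clusters (F_X, F_A, F_B)
of the PSI stand-in, then asks how many have counterparts in two
comparison stand-ins (cyanobacteria-like and plant-like), sweeping the
match radius because conservation counts depend on it.
"""

import chlorofret as cf
from chlorofret.hydration import HydrationParameters
from chlorofret.synthetic import conservation_variant, psi_cluster_sites, psi_supercomplex

psi = psi_supercomplex(seed=0)
shell = cf.water_shell(psi, psi_cluster_sites(psi))
print(f"{len(shell)} waters within 8 A of the three Fe-S clusters")

sites = [w.site_id for w in shell.waters]
cyano = conservation_variant(psi, sites, list(range(17)), seed=3,
                             model_id="cyano-like")
plant = conservation_variant(psi, sites, list(range(14)) + list(range(17, 22)),
                             seed=4, model_id="plant-like")

records = {}
for other in (cyano, plant):
    sup = cf.superpose_models(psi, other, chain_map={c: c for c in "ABC"})
    for radius in (0.8, 1.2, 1.5):
        recs = cf.conserved_waters(shell, other, sup,
                                   HydrationParameters(match_radius=radius))
        n = sum(r.conserved for r in recs)
        print(f"  vs {other.model_id:10s} match radius {radius:.1f} A: {n} conserved")
        if radius == 1.2:
            records[other.model_id] = recs

per_model, per_water = cf.conservation_summary(records)
n_any = int((per_water["n_models_conserved"] >= 1).sum())
print(f"conserved in at least one comparison model: {n_any} of {len(shell)}")
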