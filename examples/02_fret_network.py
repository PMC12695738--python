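"""Build the chlorophyll a → chlorophyll a Förster rate network.

The rate between two chlorophylls is K_DA = C·κ²/(n⁴ R⁶) with C = 32.26,
n = 1.55 and R the Mg–Mg distance in nm; pairs beyond 20 Å are not connected,
and chlorophyll c is left unconnected (its overlap constant is unknown).
"""

import chlorofret as cf
from chlorofret.fret import FretParameters
from chlorofret.synthetic import psi_supercomplex

model = psi_supercomplex(seed=0)
chls, excluded = cf.extract_chlorophylls(model)
net = cf.build_network(chls, FretParameters(), model_id=model.model_id)

print(f"{len(chls)} chlorophylls ({len(excluded)} incomplete, excluded)")
print(f"{len(net.edges)} edges within 20 A")
strongest = max(net.edges, key=lambda e: e.rate)
print(
    f"strongest pair: {strongest.donor} - {strongest.acceptor}  "
    f"R = {strongest.separation:.1f} A, kappa^2 = {strongest.kappa_sq:.2f}, "
    f"K_DA = {strongest.rate:.2f} /ns"
)

# A reference point for the unit convention: a pair at exactly 20 A with
# kappa^2 = 1 transfers at 32.26/(1.55^4 * 2.0^6) = 0.0873 per ns.
print(f"reference K_DA(kappa^2=1, R=20 A) = {32.26 / (1.55**4 * 2.0**6):.4f} /ns")
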