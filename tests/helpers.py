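import numpy as np

from chlorofret.fret import Chlorophyll


def make_chl(mg, dipole, kind="chl_a", site=None):
    """Minimal chlorophyll at mg with the NB→ND axis along `dipole`."""
    mg = np.asarray(mg, dtype=float)
    d = np.asarray(dipole, dtype=float)
    d = d / np.linalg.norm(d)
    site = site or ("X", int(abs(mg).sum() * 100) % 10_000, "CLA")
    comp = "CLA" if kind == "chl_a" else "KC2"
    site = (site[0], site[1], comp)
    return Chlorophyll(site_id=site, kind=kind, mg=mg, nb=mg - 2.05 * d, nd=mg + 2.05 * d)
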