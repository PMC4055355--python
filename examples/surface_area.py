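"""Accessible and buried surface area of the label in its two environments.

Shrake-Rupley areas with deterministic golden-spiral quadrature: the total
is the side chain's area in its own chain's context alone, the buried part
is what a neighbouring chain takes away.  At a crystal contact most of the
label surface is buried; at an open site almost none is.
"""

from spinlabel import buried_sasa
from spinlabel.synthetic import make_open_site, make_tight_site

for fx in (make_open_site(seed=0), make_tight_site(seed=0)):
    chain = fx.model.chain("A")
    res = chain.residue(fx.site[1])
    side = [a for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
    rep = buried_sasa(side, chain, fx.model)
    print(f"{fx.regime:>5s} site: R1 side-chain ASA {rep.total_asa:6.1f} A^2, "
          f"buried {rep.buried_asa:6.1f} A^2 "
          f"({100 * rep.buried_asa / rep.total_asa:.0f}%)")
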