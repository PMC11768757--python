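"""Build the six flocculant polymers and inspect their charge states.

At pH 11 cellulose, guar gum and PAM are neutral; alginate, HPAM and PAA
carry one negative charge per (acrylate/uronate) monomer and therefore
need Na+ counterions for electroneutrality.
"""

import polysurf as ps
from polysurf.polymers import DEFAULT_N_MONOMERS

print(f"{'polymer':<10} {'monomers':>8} {'sites':>6} {'charge/e':>9} "
      f"{'counterions':>12} {'length/nm':>10}")
for name in ps.POLYMER_NAMES:
    n = DEFAULT_N_MONOMERS[name]
    chain = ps.build_chain(name, n, seed=0)
    print(f"{name:<10} {n:>8} {chain.n_sites:>6} {chain.net_charge:>+9.0f} "
          f"{ps.counterion_count(chain):>12} {chain.linear_extent:>10.2f}")

# Both families start near 12 nm linear length: 12 pyranose units at
# ~1.0 nm/monomer versus 48 vinyl units at ~0.25 nm/monomer.  HPAM is the
# strictly periodic 3:1 acrylamide:acrylate copolymer, so a 48-mer carries
# exactly -12 e.
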