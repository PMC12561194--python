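"""Pre-reaction-state (near-attack) statistics for glycosyl transfer.

Compares a PRS-rich system (acceptor O8 planted near both the anomeric
carbon and the catalytic nitrogen in 60% of frames) with a PRS-poor one
(10%) — the comparison that rationalises why an engineered variant shows
higher regioselective turnover: it spends more time in conformations
poised for nucleophilic attack.
"""

import pocketshaper as ps
from pocketshaper.core import resolve_selection
from pocketshaper.prs import PRSConfig, compare_prs, prs_population
from pocketshaper.synthetic import (
    ACCEPTOR_O8_SEL, ANOMERIC_C_SEL, CATALYTIC_N_SEL,
    EnsembleSpec, toy_reference_frames,
)

ref, _ = toy_reference_frames()


def analyse(rate, seed):
    spec = EnsembleSpec(
        n_frames=1000, basin_occupancies=(1.0,), basin_reference_frames=(ref,),
        planted_prs=(0, rate), seed=seed,
    )
    ens, _ = ps.synthetic.generate_two_basin_ensemble(spec)
    topo = ens.topology
    cfg = PRSConfig(
        acceptor_O=resolve_selection(topo, ACCEPTOR_O8_SEL),
        anomeric_C=resolve_selection(topo, ANOMERIC_C_SEL),
        catalytic_N=resolve_selection(topo, CATALYTIC_N_SEL),
        threshold=3.5,
    )
    return prs_population(ens, cfg)


variant = analyse(0.60, seed=3)
wild_type = analyse(0.10, seed=4)

for name, rep in (("variant", variant), ("wild-type", wild_type)):
    d = rep.to_dict()
    print(f"{name:10s} PRS fraction {rep.prs_fraction:.3f}  "
          f"attack freq (→C) {rep.attack_frequency_donor:.3f}  "
          f"attack freq (→N) {rep.attack_frequency_base:.3f}  "
          f"median d(O→C) {d['median_d_donor']:.2f} Å")

verdict = compare_prs(variant, wild_type, labels=("variant", "wild-type"))
print(f"\nhigher PRS population: {verdict['higher_prs_fraction']}; "
      f"smaller acceptor→anomeric-C median distance: "
      f"{verdict['smaller_median_d_donor']}")
print("(both distances must be < 3.5 Å simultaneously to count as a PRS)")
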