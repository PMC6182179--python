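"""Step-response times (T90) of the three circuits.

Simulates induction steps from an empty cell and reports the time to
reach 90% of the steady-state output.  aTc-tuning of the plain
autorepressor couples output level to response time; the sRNA dial spans
a comparable output range at nearly constant T90; and engaging the
closed-loop sRNA feedback (u2 > 0) makes the response much faster than
the open-loop cascade.
"""

import srnafb as sf
from srnafb.dynamics import response_time_t90, simulate_timecourse

cal = sf.default_params(sf.SRNA_TUNED_AUTOREPRESSOR)
t_end = 50.0 / cal.delta_p

print("autorepressor, aTc tuning (output and T90 rise together):")
for u1 in (5.0, 20.0, 80.0):
    traj = simulate_timecourse(sf.AUTOREPRESSOR, cal, sf.InducerInput(u1=u1),
                               t_end=t_end)
    print(f"  u1={u1:5.0f} ng/ml: p* = {traj.observable('p')[-1]:7.0f}, "
          f"T90 = {response_time_t90(traj):6.1f} min")

print("sRNA-tuned autorepressor at saturating aTc (decoupled T90):")
for u2 in (0.0, 5e-5, 2e-4, 1e-3):
    traj = simulate_timecourse(sf.SRNA_TUNED_AUTOREPRESSOR, cal,
                               sf.InducerInput(u1=100.0, u2=u2), t_end=t_end)
    print(f"  u2={u2:6g} mg/ml: p* = {traj.observable('p')[-1]:7.0f}, "
          f"T90 = {response_time_t90(traj):6.1f} min")

clp = sf.default_params(sf.CLOSED_LOOP_INDUCIBLE)
print("closed-loop circuit at u3 = 0.5 mM (feedback speeds the response):")
for u2, label in ((0.0, "open loop "), (2.0, "with sRNA ")):
    traj = simulate_timecourse(sf.CLOSED_LOOP_INDUCIBLE, clp,
                               sf.InducerInput(u2=u2, u3=0.5),
                               t_end=50.0 / clp.delta_p)
    print(f"  {label} (u2={u2}): p* = {traj.observable('p')[-1]:7.0f}, "
          f"T90 = {response_time_t90(traj):6.1f} min")
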