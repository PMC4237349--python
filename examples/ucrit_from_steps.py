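"""Critical swimming speed from a stepwise fatigue trial.

Speed rises 0.1 m/s every 20 min until the fish fatigues; Brett's
formula interpolates within the failing step.
"""

from dragtag import UcritProtocol, compute_ucrit
from dragtag.respirometry import BlockingContext
from dragtag.ucrit import ucrit_from_steps

protocol = UcritProtocol(speed_increment=0.1, interval=20.0, start_speed=0.3)

# the animal completed 0.8 m/s and endured 10 of 20 min at 0.9 m/s
res = compute_ucrit(last_completed_speed=0.8, fatigue_time=10.0, protocol=protocol)
print(f"U_crit = {res.u_crit:.2f} m/s (half the failing step is credited)")

# same trial as a raw step log
log_speeds = [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
log_minutes = [20, 20, 20, 20, 20, 20, 10]
res = ucrit_from_steps(log_speeds, log_minutes, protocol)
print(f"from step log: U_crit = {res.u_crit:.2f} m/s")

# the solid-blocking correction scales speeds up slightly because the
# fish narrows the tunnel cross-section
ctx = BlockingContext(fish_area=150.5, tunnel_area=17671.0)
res_corr = compute_ucrit(0.8, 10.0, protocol, ctx)
print(f"blocking-corrected: {res_corr.u_crit:.4f} m/s "
      f"(+{100 * ctx.epsilon_s:.2f}%)")
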