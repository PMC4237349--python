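"""Predict the burden of a real telemetry tag before deploying it.

The evaluation tool maps a tag's drag force (N at the reference speed)
to the expected percent change of two energetic endpoints via the
through-origin quadratic E = aF + bF^2, plus a fixed increment if the
tag sits at the centre of mass (site B) instead of the low-oscillation
anterior site (site A).
"""

from dragtag import TagScenario, combined_site_effect, predict_impairment
from dragtag.impairment import COTMIN_COEFFS, UCRIT_COEFFS, reference_fits, endpoint_divergence

# a commercial pop-up satellite tag measured at ~0.159 N of drag
drag = 0.159
red_u = predict_impairment(*UCRIT_COEFFS, drag)
inc_c = predict_impairment(*COTMIN_COEFFS, drag)
print(f"tag drag {drag} N at site A:")
print(f"  U_crit reduction : {red_u:6.2f} %")
print(f"  COT_min increase : {inc_c:6.2f} %")

scen = TagScenario(tag_drag=drag, site="B")
print("attached at the centre of mass (site B) instead:")
print(f"  total U_crit reduction : {combined_site_effect(red_u, scen, 'ucrit'):6.2f} %")
print(f"  total COT_min increase : {combined_site_effect(inc_c, scen, 'cotmin'):6.2f} %")

fu, fc = reference_fits()
print("\nwhere the two endpoints stop agreeing:")
print(endpoint_divergence(fu, fc, [0.05, 0.1, 0.15, 0.2]).to_string(index=False))
print("\nBelow ~0.1 N a fatigue (U_crit) test is a fair proxy for the")
print("energetic cost; above it the COT_min penalty grows much faster.")
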