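"""Test a field's directional rate modulation three ways.

Per-pass normalized rates grouped by travel direction are compared with
a Mann-Whitney test, summarized by the signed directionality index
(positive = north/east), and tested with a Gamma-GLM likelihood ratio:
the base model explains rate (+1, inverse link) with a 3-df natural
time spline, the alternative adds binary current direction — so a
directional effect must beat slow drift.
"""

from placerep import directionality_index, glm_direction_lrt, mw_direction_test
from placerep.synthetic import DriftSpec, simulate_pass_table

# a field firing 2x stronger northbound, on top of a decaying envelope
table = simulate_pass_table(
    n_per_direction=40,
    gain=2.0,
    drift=DriftSpec(family="exp_decay", onset_s=0.0, tau_s=1800.0),
    seed=3,
)
u, p_mw, delta = mw_direction_test(table)
di = directionality_index(table)
glm = glm_direction_lrt(table)
print(f"Mann-Whitney U={u:.0f}, p={p_mw:.2g}; |rate difference|={delta:.2f} (normalized)")
print(f"directionality index: {di:+.2f}  (positive = north preferred)")
print(f"GLM LRT: stat={glm.lrt_stat:.1f}, p={glm.p:.2g}; "
      f"RMSE {glm.rmse_base:.3f} -> {glm.rmse_alt:.3f} with direction")
# all three agree: the field is directional even though its overall
# rate decays over the session (the spline absorbs the drift)
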