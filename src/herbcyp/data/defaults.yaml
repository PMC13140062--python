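# Default pipeline settings. Flat key-value mapping; every key may be
# overridden from a user config file.

# BOILED-Egg ellipse constants in (TPSA [A^2], WLOGP) space, digitized from
# the original publication's best-fit ellipses. Angles are in degrees;
# width/height are full axis lengths. Boundary points count as inside.
egg_white_cx: 71.051
egg_white_cy: 2.292
egg_white_width: 142.081
egg_white_height: 8.740
egg_white_angle_deg: -1.031325
egg_yolk_cx: 38.117
egg_yolk_cy: 3.177
egg_yolk_width: 82.061
egg_yolk_height: 5.557
egg_yolk_angle_deg: -0.171887

# Rule-of-five cutoffs. The lipophilicity criterion uses the Moriguchi
# topological estimator with its conventional 4.15 cutoff.
mw_lipinski_cutoff: 500.0
mlogp_lipinski_cutoff: 4.15
hbd_lipinski_cutoff: 5
hba_lipinski_cutoff: 10
# "pass" for the Abbott bioavailability score means <= this many violations
lipinski_pass_max_violations: 1

# CYP interaction probability handling (percent scale)
activity_threshold_percent: 50.0

# Integrated risk bands (percent scale): HIGH strictly above the high
# boundary, MODERATE from the moderate boundary upward, LOW below it.
risk_high_mean_percent: 50.0
risk_moderate_mean_percent: 30.0
# a moderate-band compound predicted to inhibit at least this many of the
# five isoforms (with high GI absorption and zero violations) escalates HIGH
risk_breadth_escalation_isoforms: 4

# Rounding used in tabular output
mw_decimals: 1
tpsa_decimals: 1
logp_decimals: 2
mean_decimals: 1
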