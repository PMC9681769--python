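# Default electrostatic-routing model coefficients (versioned data).
#
# Actuated sorting success follows a logistic surface in applied potential
# V (V_RMS) and spacer-oil flow Q (nL/s) with an interaction term and a
# droplet-volume term centred at 1 nL:
#
#   logit P(success) = beta0 + beta_v*V + beta_q*Q + beta_vq*V*Q
#                      + beta_vol*(volume - 1)
#
# The coefficients are pinned to two calibration anchors -- P = 0.5 at
# (27.4 V_RMS, 51.5 nL/s, 1 nL) and P = 0.99 at (40 V_RMS, 60 nL/s) -- with
# the two remaining degrees of freedom (beta_vq and the flow slope at the
# threshold voltage) chosen so the success region has the observed
# topology: efficient sorting needs both sufficient potential and
# sufficient flow, low potential fails at high flow (drag dominates), and
# high potential at low flow fails by stalling/merging.
version: 1
beta0: 1.1784854052628768
beta_v: -0.15578413887820716
beta_q: -0.1592
beta_vq: 0.008
beta_vol: -3.0
# passive routing fidelity (probability an unpulsed droplet takes the wide
# main channel), anchored at the two characterised flow rates and
# interpolated linearly in flow between/beyond them
passive_fidelity_60: 0.992
passive_fidelity_80: 0.995
# regime thresholds used to classify failure modes
v_low: 27.4        # V_RMS; below this a failed pulse is drag-dominated (E1)
q_low: 51.5        # nL/s; below this a failed pulse stalls/merges (E2/E3)
low_flow_knee: 10.0  # nL/s; passive fidelity degrades linearly below this
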