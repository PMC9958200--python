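# Ageing-scenario presets: literature-informed parameter perturbations.
# Multipliers are applied to the control (young plantar-flexor) values;
# pCa50 deltas are in pCa units (negative = desensitised).
#
# A 30% (50%) reduction in the Ca2+ removal *rate constant* corresponds to
# tau2 x 1/0.7 (x 2); a 40% reduction to tau2 x 1/0.6.

identity: {}

# instantaneous Ca2+ availability (release deficit)
ca_release_minus30: {release_scale: 0.7}
ca_release_minus50: {release_scale: 0.5}

# SR Ca2+ uptake (removal rate constant)
uptake_minus30: {tau2_multiplier: 1.4285714285714286}
uptake_minus50: {tau2_multiplier: 2.0}

# Ca2+ sensitivity of force
pca50_minus0p05: {delta_pca50: -0.05}
pca50_minus0p10: {delta_pca50: -0.10}

# cooperativity of activation
nH_minus1: {delta_nH: -1.0}
nH_plus1: {delta_nH: 1.0}

# intrinsic shortening speed and force-velocity curvature
vmax_minus30: {vmax_multiplier: 0.7}
vmax_minus50: {vmax_multiplier: 0.5}
aP0_plus0p05: {aP0_delta: 0.05}

# series-elastic stiffness
ksee_minus30: {k_see_multiplier: 0.7}
ksee_plus50: {k_see_multiplier: 1.5}

# type I fibre fractional area (composite recomputation of 1/tau2, pCa50,
# nH and Vmax from slow/fast fibre differences)
typeI_0p70: {p_slow_new: 0.70}
typeI_0p80: {p_slow_new: 0.80}

# combined adaptations
combo_release30_pca05: {release_scale: 0.7, delta_pca50: -0.05}
combo_release50_pca05: {release_scale: 0.5, delta_pca50: -0.05}
combo_release50_pca10: {release_scale: 0.5, delta_pca50: -0.10}
combo_release30_uptake40: {release_scale: 0.7, tau2_multiplier: 1.6666666666666667}
combo_uptake30_pca10: {tau2_multiplier: 1.4285714285714286, delta_pca50: -0.10}
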