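# Generative species profiles for the simulated-strike trial generator.
#
# One entry per species tested with the rattlesnake strike simulator.
# Moments are mean +/- standard error with the per-metric sample size they
# were estimated from; the generator recovers SDs as se * sqrt(n).
# jump_propensity is the observed fraction of trials ending in a jump.
# Species codes: DIME = Merriam's kangaroo rat, DIDE = desert kangaroo rat,
# DISP = banner-tailed kangaroo rat, CHPE = desert pocket mouse,
# NEAL = white-throated woodrat, OTBE = California ground squirrel.
# Woodrats and ground squirrels almost never jumped, so they carry no
# jump-performance moments (speed/angle null).
species:
  - species_code: DIME
    mass_mean_g: 40.0
    mass_se_g: 1.0
    jump_propensity: 0.625          # 30 jumps / 48 trials
    reaction_mean_ms: 22.8
    reaction_se_ms: 1.2
    takeoff_mean_ms: 103.1
    takeoff_se_ms: 8.3
    takeoff_speed_mean_ms1: 2.1
    takeoff_speed_se_ms1: 0.1
    angle_mean_deg: 39.7
    angle_se_deg: 3.4
    fps: 240
    n_reference: {mass: 48, reaction: 39, takeoff: 38, speed: 29, angle: 29}
    # Merriam's kangaroo rats take off faster when they jump than when they
    # scramble; mode-specific means reproduce that contrast.
    takeoff_jump_mean_ms: 88.0
    takeoff_scramble_mean_ms: 126.0
  - species_code: DIDE
    mass_mean_g: 89.0
    mass_se_g: 5.0
    jump_propensity: 0.926          # 25 / 27
    reaction_mean_ms: 18.8
    reaction_se_ms: 1.5
    takeoff_mean_ms: 77.8
    takeoff_se_ms: 6.0
    takeoff_speed_mean_ms1: 2.6
    takeoff_speed_se_ms1: 0.1
    angle_mean_deg: 35.3
    angle_se_deg: 3.8
    fps: 250                        # includes the 500 fps subset down-sampled to 250
    n_reference: {mass: 27, reaction: 24, takeoff: 24, speed: 25, angle: 25}
  - species_code: DISP
    mass_mean_g: 116.0
    mass_se_g: 3.0
    jump_propensity: 0.739          # 34 / 46
    reaction_mean_ms: 29.4
    reaction_se_ms: 1.4
    takeoff_mean_ms: 101.9
    takeoff_se_ms: 13.5
    takeoff_speed_mean_ms1: 2.4
    takeoff_speed_se_ms1: 0.1
    angle_mean_deg: 31.6
    angle_se_deg: 3.1
    fps: 240
    n_reference: {mass: 46, reaction: 24, takeoff: 20, speed: 27, angle: 27}
  - species_code: CHPE
    mass_mean_g: 18.0
    mass_se_g: 1.0
    jump_propensity: 0.909          # 20 / 22
    reaction_mean_ms: 28.4
    reaction_se_ms: 2.2
    takeoff_mean_ms: 58.2
    takeoff_se_ms: 10.5
    takeoff_speed_mean_ms1: 2.2
    takeoff_speed_se_ms1: 0.1
    angle_mean_deg: 39.2
    angle_se_deg: 3.2
    fps: 240
    n_reference: {mass: 22, reaction: 21, takeoff: 20, speed: 19, angle: 19}
  - species_code: NEAL
    mass_mean_g: 177.0
    mass_se_g: 21.0
    jump_propensity: 0.071          # 1 / 14
    reaction_mean_ms: 19.1
    reaction_se_ms: 1.0
    takeoff_mean_ms: 152.5
    takeoff_se_ms: 12.3
    fps: 240
    n_reference: {mass: 14, reaction: 13, takeoff: 13}
  - species_code: OTBE
    mass_mean_g: 523.0
    mass_se_g: 37.0
    jump_propensity: 0.087          # 2 / 23
    reaction_mean_ms: 36.8
    reaction_se_ms: 2.1
    takeoff_mean_ms: 157.7
    takeoff_se_ms: 12.2
    fps: 120                        # earlier ground-squirrel study recorded at 120 fps
    n_reference: {mass: 23, reaction: 21, takeoff: 19}

# Field-realistic trial-loss rates. Hit-by-cork and premature rates follow
# the observed study-wide frequencies (20 and 2 of 180 trials); off-screen
# and poor-video rates are plausible field values.
censoring:
  p_hit_by_cork: 0.11
  p_premature_react: 0.011
  p_offscreen: 0.05
  p_poor_video: 0.05
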