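"""Reconstruct a jump's take-off kinematics from two field measurements.

A kangaroo rat's evasive leap is scored from high-speed video as a
horizontal displacement (tape measure between take-off and landing spots)
and an airborne time (seconds between the take-off and landing frames).
Level-ground ballistics turns those two numbers into take-off velocity,
angle and jump height.
"""

from escapekin import JumpObservation, compute_kinematics, forward_ballistics

# a typical evasive leap: 0.4 m covered in 0.2 s airborne
obs = JumpObservation(horizontal_displacement_m=0.4, airborne_time_s=0.2)
kin = compute_kinematics(obs)

print(f"horizontal velocity : {kin.v_horizontal:.3f} m/s")
print(f"vertical velocity   : {kin.v_vertical:.3f} m/s")
print(f"take-off speed      : {kin.takeoff_speed:.3f} m/s")
print(f"take-off angle      : {kin.takeoff_angle_deg:.2f} deg")
print(f"jump height         : {kin.jump_height_m * 100:.1f} cm")

# The forward model is the exact inverse: projecting the reconstructed
# (speed, angle) returns the measured displacement and hang time.
back = forward_ballistics(kin.takeoff_speed, kin.takeoff_angle_deg)
print(
    f"round trip          : d={back.horizontal_displacement_m:.6f} m, "
    f"t={back.airborne_time_s:.6f} s (inputs were 0.4 m, 0.2 s)"
)
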