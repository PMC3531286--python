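"""Swim the default uniform body and print its headline kinematics.

Builds the 60-segment, 12 cm, 14 g body, runs three steady undulation
cycles at A/lambda = 0.2 and f = 2 Hz with the top surface 3.9 cm deep,
and reports wave efficiency, speed oscillation, yaw and energetics.
"""

from sandswim import SwimConfig, energetics, oscillation_metrics, simulate, wave_efficiency

traj = simulate(SwimConfig())
eta = wave_efficiency(traj)
om = oscillation_metrics(traj)
en = energetics(traj)

print(f"wavelength               {traj.wavelength * 100:.2f} cm")
print(f"wave efficiency eta      {eta:.3f}")
print(f"forward speed            {en.forward_speed * 100:.2f} cm/s")
print(f"speed p2p / mean         {om.speed_peak_to_peak_ratio:.2f}")
print(f"max yaw excursion        {om.max_yaw_deg:.1f} deg")
print(f"total mechanical power   {en.total_power * 1000:.1f} mW")
print(f"head-drag power fraction {en.head_fraction:.2f}")
print(f"cost of transport        {en.cost_of_transport:.1f}")
print()
print("eta is the forward speed over the backward wave speed f*lambda; the")
print("speed oscillates at twice the undulation frequency because the head")
print("drag surges twice per cycle; the CoT is power/(weight*speed).")
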