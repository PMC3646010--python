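"""How loud is a bat call by the time it reaches a moth?

Builds the propagation model for a typical summer field night and walks
one 40 kHz call from the bat's mouth (source level referenced to 10 cm)
out to a moth 2 m away, splitting the loss into spherical spreading and
excess atmospheric attenuation, then shows the volume of air one call
ensonifies above a 90 dB SPL threshold.
"""

import numpy as np

from echorisk import (
    BeamModel,
    Environment,
    atmos_atten_coeff,
    beam_gain,
    ensonified_volume,
    spreading_loss,
    transmission_loss,
)

env = Environment(temperature_C=20.0, relative_humidity_pct=50.0)
f_khz = 40.0
alpha = atmos_atten_coeff(f_khz, env)
print(f"atmospheric attenuation at {f_khz:.0f} kHz, 20 C / 50% RH: {alpha:.2f} dB/m")

sl = 110.0  # dB peSPL re 20 uPa at 10 cm
d = 2.0
spread = spreading_loss(d, 0.1)
tl = transmission_loss(d, f_khz, env)
print(f"source level {sl:.1f} dB at 10 cm, moth at {d:.1f} m:")
print(f"  spreading loss      {spread:.2f} dB")
print(f"  atmospheric loss    {tl - spread:.2f} dB")
print(f"  level at the moth   {sl - tl:.2f} dB (on the beam axis)")

# a moth 40 degrees off a search/approach beam sits at the -6 dB edge
print(f"  40 deg off axis     {sl - tl + beam_gain(40.0, 'approach'):.2f} dB")

vol = ensonified_volume(sl, BeamModel(), "search", 90.0, f_khz, env)
vol_buzz = ensonified_volume(sl, BeamModel(), "buzz", 90.0, f_khz, env)
print(f"volume ensonified above 90 dB: search beam {vol:.2f} m^3, "
      f"buzz beam {vol_buzz:.2f} m^3")
print("(the broader buzz beam spreads the same energy over more of the sphere)")
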