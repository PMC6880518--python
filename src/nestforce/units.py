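"""Unit helper constants.

Everything inside the simulator is strict SI (m, kg, s, K, J, Pa·s).
These constants let model code write ``5 * units.nm`` or ``120 * units.minute``
instead of raw powers of ten.
"""

# length
m = 1.0
cm = 1e-2
mm = 1e-3
um = 1e-6
nm = 1e-9

# time
s = 1.0
ms = 1e-3
us = 1e-6
ns = 1e-9
minute = 60.0
hour = 3600.0

# mass / density
kg = 1.0
g_per_cm3 = 1000.0  # kg/m^3

# energy / pressure / viscosity
J = 1.0
Pa = 1.0
Pa_s = 1.0

# temperature
K = 1.0

#: Boltzmann constant, J/K (2019 SI exact value).
KB = 1.380649e-23
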