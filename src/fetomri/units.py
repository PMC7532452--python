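"""Physical constants and unit conversions used across the package.

All internal gradient-physics computations run in CGS-flavoured MR units
(gradients in G/cm, times in seconds, gyromagnetic ratio in rad s^-1 G^-1);
b-values are reported in the field-standard s/mm^2.
"""

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_RAD_PER_S_PER_T = 2.6752218744e8

#: Proton gyromagnetic ratio, rad s^-1 G^-1 (1 T = 1e4 G).
GAMMA_RAD_PER_S_PER_G = GAMMA_RAD_PER_S_PER_T * 1e-4

#: Convert an integral of q^2 dt (q in rad/cm, t in s) to s/mm^2.
#: 1 cm^-2 = 1e-2 mm^-2.
RAD2_PER_CM2_S_TO_S_PER_MM2 = 1e-2

MS_TO_S = 1e-3
MM_TO_CM = 1e-1
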