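"""Unit conventions and physical constants.

All internal computations use micrometres (length), milliseconds (time) and
kHz = 1/ms (frequency).  Every public interface that talks about frequency
does so in Hz; conversion goes through the two helpers below so the factor
of 1000 lives in exactly one place.

Gradient amplitudes are accepted in mT/m (the unit scanner protocols are
quoted in).  ``GAMMA_INTERNAL`` is the proton gyromagnetic ratio expressed
so that ``GAMMA_INTERNAL * G[mT/m] * t[ms]`` is a dephasing wave number in
rad/um.
"""

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_SI = 2.6752e8

#: rad ms^-1 per (mT/m) per um, i.e. GAMMA_SI * 1e-3 (s->ms) * 1e-9 (mT/m -> T/um).
GAMMA_INTERNAL = GAMMA_SI * 1e-12

KHZ_PER_HZ = 1e-3
HZ_PER_KHZ = 1e3


def hz_to_khz(f):
    """Convert frequency from Hz (interface unit) to kHz (internal unit)."""
    return f * KHZ_PER_HZ


def khz_to_hz(f):
    """Convert frequency from kHz (internal unit) to Hz (interface unit)."""
    return f * HZ_PER_KHZ
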