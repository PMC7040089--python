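"""Physical constants and shared defaults."""

#: Speed of light in vacuum, mm/ps.
C_MM_PER_PS = 0.299792458

#: Laser wavelengths of the two-colour system, nm.
WAVELENGTHS_NM = (760, 830)

#: Laser repetition window (80 MHz), ps.
REPETITION_WINDOW_PS = 12500.0

#: Number of TCSPC histogram bins spanning the repetition window.
N_TIME_BINS = 1024


def speed_in_tissue(refractive_index: float) -> float:
    """Speed of light inside tissue, mm/ps (v = c/n)."""
    return C_MM_PER_PS / refractive_index
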