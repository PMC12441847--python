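"""Fixed properties of the micromechanical sensor used for nanomotion DST.

The sensor is a triangular silicon-nitride cantilever (Bruker NPO-10.B):
two prongs and a triangular tip, gold-coated on the underside for optical
readout, with cells attaching to the uncoated top surface.  These constants
are configuration fixtures for sanity checks and reporting; nothing in the
analysis depends on absolute deflection calibration.
"""

PRONG_AREA_UM2 = 4_800.0
N_PRONGS = 2
TIP_AREA_UM2 = 9_100.0

#: total area available for cell attachment (μm²)
TOTAL_ATTACHMENT_AREA_UM2 = N_PRONGS * PRONG_AREA_UM2 + TIP_AREA_UM2

NOMINAL_RESONANCE_HZ = 8_500.0
ACQUISITION_RATE_HZ = 60_000.0


def attachment_area_um2(
    prong_area_um2: float = PRONG_AREA_UM2,
    n_prongs: int = N_PRONGS,
    tip_area_um2: float = TIP_AREA_UM2,
) -> float:
    """Total cantilever attachment area from its geometric parts."""
    return n_prongs * prong_area_um2 + tip_area_um2
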