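"""Unit system and physical constants.

Internal units everywhere in the package:

* length   nm
* time     us (microseconds)
* rates    nm^3/us (3D bimolecular), nm^2/us (2D bimolecular), 1/us (unimolecular)
* energies kBT

Display/interchange units follow field convention: macroscopic 3D association
rates in uM^-1 s^-1, off-rates in s^-1, translational diffusion in um^2/s
(numerically identical to nm^2/us), rotational diffusion in rad^2/us.
All conversions happen at parse/format time so the numerics never mix units.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23

#: multiply a macroscopic 3D rate in uM^-1 s^-1 by this to get nm^3/us.
#: 1 uM^-1 s^-1 = 1e6 M^-1 s^-1 = 1e6 * (1e24 nm^3 / AVOGADRO) / 1e6 us
UM_INV_S_TO_NM3_US = 1e24 / AVOGADRO  # = 1.66054 nm^3/us

#: 1/us per s^-1
PER_S_TO_PER_US = 1e-6

#: standard-state concentration c0 = 1 M expressed in nm^-3
C0_NM3 = AVOGADRO / 1e24  # = 0.602214076 nm^-3

#: molecules per nm^3 for a 1 uM solution
UM_TO_NM3 = C0_NM3 * 1e-6  # = 6.02214076e-7 nm^-3


def kon3d_to_internal(kon_um_s: float) -> float:
    """uM^-1 s^-1  ->  nm^3/us."""
    return kon_um_s * UM_INV_S_TO_NM3_US


def kon3d_to_display(kon_nm3_us: float) -> float:
    """nm^3/us  ->  uM^-1 s^-1."""
    return kon_nm3_us / UM_INV_S_TO_NM3_US


def rate1_to_internal(k_per_s: float) -> float:
    """s^-1  ->  us^-1."""
    return k_per_s * PER_S_TO_PER_US


def rate1_to_display(k_per_us: float) -> float:
    """us^-1  ->  s^-1."""
    return k_per_us / PER_S_TO_PER_US


def copies_to_uM(n: float, volume_nm3: float) -> float:
    """Copy number in a volume (nm^3) -> concentration in uM."""
    return n / (volume_nm3 * UM_TO_NM3)


def uM_to_copies(c_uM: float, volume_nm3: float) -> float:
    """Concentration in uM -> (real-valued) copy number in a volume (nm^3)."""
    return c_uM * volume_nm3 * UM_TO_NM3
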