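"""Unit conversion constants.

The canonical analysis unit for forces is the piconewton, so that NAMD
(kcal mol^-1 A^-1) and GROMACS (kJ mol^-1 nm^-1) traces are directly
comparable with each other and with AFM experiments.  Toy-simulator
internals are pN / Angstrom / ps.
"""

#: pN per kcal mol^-1 A^-1 (NAMD force unit)
KCAL_PER_MOL_ANGSTROM_TO_PN = 69.4786

#: pN per kJ mol^-1 nm^-1 (GROMACS force unit)
KJ_PER_MOL_NM_TO_PN = 1.66054

#: Boltzmann constant in pN A K^-1
KB_PN_ANGSTROM_PER_K = 0.0138065


def namd_force_to_pn(f: float) -> float:
    """kcal mol^-1 A^-1 -> pN."""
    return f * KCAL_PER_MOL_ANGSTROM_TO_PN


def pn_to_namd_force(f: float) -> float:
    """pN -> kcal mol^-1 A^-1."""
    return f / KCAL_PER_MOL_ANGSTROM_TO_PN


def gromacs_force_to_pn(f: float) -> float:
    """kJ mol^-1 nm^-1 -> pN."""
    return f * KJ_PER_MOL_NM_TO_PN


def pn_to_gromacs_force(f: float) -> float:
    """pN -> kJ mol^-1 nm^-1."""
    return f / KJ_PER_MOL_NM_TO_PN
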