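"""Physical constants and unit conventions.

Internal units everywhere: lengths in nm, energies in kJ/mol, times in ps,
temperatures in K, masses in amu.  With these units 1 amu·nm²/ps² = 1 kJ/mol,
so kinetic energy and velocities need no conversion factors.  Reports quote
RMSDs in Å (1 nm = 10 Å).
"""

#: Boltzmann constant in kJ·mol⁻¹·K⁻¹
KB = 0.0083144621

#: nm → Å conversion
NM_TO_ANGSTROM = 10.0

#: default simulation temperature (K)
DEFAULT_TEMPERATURE = 310.0
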