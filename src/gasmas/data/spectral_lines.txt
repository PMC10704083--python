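# Packaged single-line fixtures for the two GASMAS laser channels.
# One parameter per row: key  value  unit  # provenance
#
# Values are HITRAN-plausible parameters for one absorption line near each
# laser wavelength (H2O near 820.0 nm, O2 A band near 763.8 nm), rounded.
# The H2O line reproduces the ambient-conditions peak absorption coefficient
# of saturated water vapor (~3.1e-5 cm^-1 at 293 K); the O2 line is used
# identically on the simulation and inversion sides, so only internal
# consistency matters for concentration recovery.

h2o.center_wavenumber    12195.16   cm-1                     # 819.97 nm, strong H2O line in the 820 nm band
h2o.line_strength        1.70e-23   cm-1/(molecule.cm-2)     # HITRAN-scale intensity at 296 K, rounded
h2o.lorentz_hwhm         0.100      cm-1                     # air-broadened HWHM at 1 atm
h2o.reference_pressure   101325.0   Pa                       # 1 atm broadening reference
h2o.molar_mass           18.010565  g/mol                    # H2(16O)

o2.center_wavenumber     13091.75   cm-1                     # 763.84 nm, O2 A-band P branch
o2.line_strength         6.00e-24   cm-1/(molecule.cm-2)     # HITRAN-scale intensity at 296 K, rounded
o2.lorentz_hwhm          0.046      cm-1                     # air-broadened HWHM at 1 atm
o2.reference_pressure    101325.0   Pa                       # 1 atm broadening reference
o2.molar_mass            31.98983   g/mol                    # (16O)2
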