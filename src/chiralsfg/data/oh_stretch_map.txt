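# Electric-field spectroscopic map for the water O-H stretch.
# schema_version: 1
#
# Source lineage: transcription of the Skinner-group electric-field map
# family for the O-H stretch of liquid water (frequency, position-matrix
# and dipole-derivative polynomials in the electric field projected on
# the O-H bond at the H atom, with intramolecular O-H/O-H coupling).
# These numbers are configuration, not code: swap this file to use a
# different published parameterization.
#
# Units:
#   field E              atomic units (Hartree/(e*Bohr))
#   frequencies          cm^-1
#   position matrix x10  Angstrom (polynomial in omega_10 / cm^-1)
#   dipole derivative    arbitrary consistent units (polynomial in E)
#   coupling             omega_12 = (c0 + c1*(E1+E2)) * x10(1) * x10(2),
#                        coefficients in cm^-1/Angstrom^2
#   field_cutoff         Angstrom
#   isotope masses       amu
#
# freq_poly: omega_10(E) = a0 + a1*E + a2*E^2   (ascending powers)
freq_poly: 3760.2 -3541.7 -152677.0
# position_matrix_poly: x10(omega) = b0 + b1*omega
position_matrix_poly: 0.19285 -1.7261e-5
# dipole_poly: mu'(E) = c0 + c1*E + c2*E^2
dipole_poly: 0.1646 11.39 63.41
# coupling_params: c0 c1  (omega_12 = (c0 + c1*(E1+E2)) * x1 * x2)
coupling_params: -1361.0 27165.0
# transverse/parallel bond polarizability-derivative ratio
polarizability_ratio: 0.17857142857142858
field_cutoff: 7.831
isotope_mass_O: 17.999159
mass_O16: 15.994915
mass_H: 1.0078250319
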