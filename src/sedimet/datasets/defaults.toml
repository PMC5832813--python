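# Default configuration for the sedimet pipeline.
#
# Species-specific size->mass conversion coefficients are lab calibrations that
# are not in the public domain; the entries below are placeholders calibrated to
# the packaged dataset (power-law fit through the printed size/mass pairs) and
# should be replaced with proper calibrations for new data.

[constants]
boltzmann_ev_per_k = 8.617e-5
activation_energy_ev = 0.65
energy_density_j_per_mg = 21.5
reference_temperature_c = 18.0

[control]
mode = "global_mean"
value_g_m2 = 32.25
ci95_g_m2 = 1.73

[metabolic_model]
form = "allometric"
a = 1.0
b = 0.75

# M (mg AFDW) = p * size^q; size in mm (bivalves) or mg wet weight (A. marina)
[mass_conversion."A. marina"]
p = 0.0817071
q = 1.04395
[mass_conversion."A. alba"]
p = 0.0051230
q = 3.0
[mass_conversion."L. balthica"]
p = 0.0100681
q = 3.0
[mass_conversion."S. plana"]
p = 0.0147015
q = 2.62516
[mass_conversion."R. philippinarum"]
p = 0.0102106
q = 3.0
[mass_conversion."C. edule"]
p = 0.0061077
q = 3.23614

[[scenarios]]
label = "winter"
t_target_c = 7.2
[[scenarios]]
label = "reference"
t_target_c = 18.0
[[scenarios]]
label = "warming_plus3"
t_target_c = 21.0
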