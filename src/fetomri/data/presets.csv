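# Tissue-parameter presets for the digital fetoplacental phantoms.
# One row per (model, compartment). Units: adc and adc_slope in mm^2/s (slope per
# gestational day past E14.5); adc_cv / adc_cv_slope are fractional coefficients of
# variation (per day for the slope); t1,t2 in ms; perfusion_f and kep in 1/s;
# vb is the blood-volume fraction used for a non-extravasating agent;
# unit_cv is the between-unit biological spread of the compartment mean.
# Absolute magnitudes are literature-plausible choices; only the orderings between
# compartments/models/days are treated as fixed facts of the emulated study.
model,compartment,adc,adc_slope,adc_cv,adc_cv_slope,t1,t2,proton_density,perfusion_f,kep,vb,extravasation,unit_cv
wildtype,amniotic_fluid,3.00e-3,0.0,0.03,0.0,3000,500,1.00,0.0,0.0,0.0,0,0.01
wildtype,maternal_background,0.70e-3,0.0,0.10,0.0,900,35,0.80,0.002,0.005,0.03,1,0.03
wildtype,decidua,1.60e-3,0.0,0.10,0.0,1400,40,0.90,0.010,0.005,0.15,1,0.05
wildtype,trophoblast,0.85e-3,0.0,0.10,0.0,1350,38,0.88,0.012,0.005,0.10,1,0.05
wildtype,labyrinth,1.55e-3,0.0,0.10,0.0,1450,42,0.92,0.030,0.005,0.25,1,0.05
wildtype,fetal_brain,1.45e-3,-0.080e-3,0.12,-0.014,1700,50,0.95,0.0,0.0,0.0,0,0.04
wildtype,fetal_liver,1.00e-3,0.0,0.10,0.0,1200,30,0.85,1.5e-4,0.005,0.0,1,0.05
enos_ko,amniotic_fluid,3.00e-3,0.0,0.03,0.0,3000,500,1.00,0.0,0.0,0.0,0,0.01
enos_ko,maternal_background,0.70e-3,0.0,0.10,0.0,900,35,0.80,0.002,0.005,0.03,1,0.03
enos_ko,decidua,1.28e-3,0.0,0.10,0.0,1400,40,0.90,0.008,0.005,0.12,1,0.05
enos_ko,trophoblast,0.68e-3,0.0,0.10,0.0,1350,38,0.88,0.008,0.005,0.08,1,0.05
enos_ko,labyrinth,1.24e-3,0.0,0.10,0.0,1450,42,0.92,0.009,0.005,0.15,1,0.05
enos_ko,fetal_brain,1.38e-3,-0.066e-3,0.12,-0.005,1700,50,0.95,0.0,0.0,0.0,0,0.04
enos_ko,fetal_liver,1.00e-3,0.0,0.10,0.0,1200,30,0.85,8.0e-4,0.005,0.0,1,0.05
il10_ko,amniotic_fluid,3.00e-3,0.0,0.03,0.0,3000,500,1.00,0.0,0.0,0.0,0,0.01
il10_ko,maternal_background,0.70e-3,0.0,0.10,0.0,900,35,0.80,0.002,0.005,0.03,1,0.03
il10_ko,decidua,1.30e-3,0.0,0.10,0.0,1400,40,0.90,0.008,0.005,0.12,1,0.05
il10_ko,trophoblast,0.70e-3,0.0,0.10,0.0,1350,38,0.88,0.008,0.005,0.08,1,0.05
il10_ko,labyrinth,1.26e-3,0.0,0.10,0.0,1450,42,0.92,0.009,0.005,0.15,1,0.05
il10_ko,fetal_brain,1.38e-3,-0.066e-3,0.12,-0.005,1700,50,0.95,0.0,0.0,0.0,0,0.04
il10_ko,fetal_liver,1.00e-3,0.0,0.10,0.0,1200,30,0.85,8.0e-4,0.005,0.0,1,0.05
lname,amniotic_fluid,3.00e-3,0.0,0.03,0.0,3000,500,1.00,0.0,0.0,0.0,0,0.01
lname,maternal_background,0.70e-3,0.0,0.10,0.0,900,35,0.80,0.002,0.005,0.03,1,0.03
lname,decidua,1.33e-3,0.0,0.40,0.0,1400,40,0.90,0.008,0.005,0.12,1,0.05
lname,trophoblast,0.70e-3,0.0,0.40,0.0,1350,38,0.88,0.008,0.005,0.08,1,0.05
lname,labyrinth,1.28e-3,0.0,0.40,0.0,1450,42,0.92,0.009,0.005,0.15,1,0.05
lname,fetal_brain,1.38e-3,-0.066e-3,0.12,-0.005,1700,50,0.95,0.0,0.0,0.0,0,0.04
lname,fetal_liver,1.00e-3,0.0,0.10,0.0,1200,30,0.85,8.0e-4,0.005,0.0,1,0.05
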