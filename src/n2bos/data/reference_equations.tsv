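# Synthetic default reference equations: predicted = intercept + age_coef*age_years + height_coef*height_cm
# These coefficients are invented, physiologically plausible placeholders (supported range:
# age 18-65 years, height 145-200 cm). Substitute your laboratory's published equations.
# Units: fev1/fvc/tlc/frc/rv in L BTPS, co_uptake in mmol.min-1.kPa-1, n2_slope in %N2 per L.
variable	sex	intercept	age_coef	height_coef
fev1	M	-2.49	-0.029	0.0430
fev1	F	-2.60	-0.025	0.0395
fvc	M	-4.34	-0.026	0.0576
fvc	F	-2.89	-0.026	0.0443
tlc	M	-6.93	0.003	0.0759
tlc	F	-5.72	0.003	0.0661
frc	M	-4.85	0.012	0.0459
frc	F	-4.07	0.012	0.0406
rv	M	-2.20	0.021	0.0192
rv	F	-1.90	0.021	0.0177
co_uptake	M	-6.00	-0.050	0.0940
co_uptake	F	-5.00	-0.050	0.0820
n2_slope	M	0.35	0.017	0.0
n2_slope	F	0.35	0.017	0.0
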