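# Default parameter preset.
#
# Published constants: the baseline branch proportions of fixed carbon
# (lambda values) and the nucleotide catalytic constants (k_cn, k_ne,
# k_nn).  The remaining entries are this package's calibration
# constants, documented in docs/methods.md:
#   k_fix      = ln(2) * (k_m + rho*) / lambda_aa1  with rho* = lambda_aa1/lambda_fa,
#                so the null model (no nucleotide catalysis) divides
#                exactly once per day;
#   k_m        = membrane-site half-saturation, in AA1:FA count ratio;
#   k_sat      = half-saturation of pathway catalysis in nucleotide
#                concentration;
#   vol_per_fa = cell volume per fatty-acid molecule (concentration scale);
#   fa_div     = division threshold, 10x the default initial fatty-acid count.

lambda_fa = 0.376
lambda_aa1 = 0.282
lambda_aa2 = 0.282
lambda_s = 0.05
lambda_e = 0.01

k_fix = 9.21738272021204
co2 = 1.0
k_m = 3.0

k_cn = 1000.0
k_sat = 0.03

k_ne = 2.0
k_nn = 2.0

alpha = 0.0

vol_per_fa = 0.05
fa_div = 1000.0

[k_in]
fa = 0.0
aa1 = 0.0
aa2 = 0.0
s = 0.0
e = 0.0

[n_c2]
fa = 1
aa1 = 1
aa2 = 1
s = 1
e = 1
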