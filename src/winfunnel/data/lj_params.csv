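# element, sigma_angstrom, epsilon_kcal_per_mol  (generic OPLS-like values)
H,2.50,0.030
C,3.40,0.086
N,3.25,0.170
O,3.00,0.210
S,3.55,0.250
P,3.74,0.200
F,2.95,0.060
Cl,3.40,0.270
Br,3.60,0.390
I,3.80,0.500
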