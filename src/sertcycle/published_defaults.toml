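# Published parameterization of the SERT transport-cycle model.
# Rates: bimolecular kon in M^-1 s^-1, everything else in s^-1.
# Conditions: micromolar (the user-surface unit).

[rates]
kon_K = 1e6
koff_K = 5000.0
kon_Na = 1e6
koff_Na = 1000.0
kon_S = 1e7
koff_S = 500.0
k_ToNaS_TiNaS = 60.0
k_TiNaS_ToNaS = 75.0
k_TiK_ToK = 5.0
k_ToK_TiK = 4.0

[conditions]
Na_out = 120000.0   # 120 mM, uptake-buffer Na+
K_out = 3000.0      # 3 mM, uptake-buffer K+
S_out = 0.0
Na_in = 6000.0      # 6 mM cytosolic Na+
K_in = 133000.0     # 133 mM cytosolic K+
S_in = 0.0
I_out = 0.0
I_in = 0.0
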