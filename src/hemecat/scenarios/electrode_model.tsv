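# Electrode-wired heme/Cu mimic.  Columns: state, Raman-observable class,
# rate (s^-1) of the step leaving the state, step label.
# Rate provenance: peroxo protonation 5000 s^-1 (the reported model rds);
# all electron-transfer steps, including the direct Fe(III)-OH reduction
# shunt, set fast (1e5 s^-1) because the heme is wired to the electrode;
# effective O2 binding 5e4 s^-1, constrained by the absence of a high-spin
# ferrous marker band during turnover; O-O cleavage 2e4 s^-1 and ferryl
# reduction 1e4 s^-1 (fast, not rate limiting; the ferryl reduction is the
# slower of the two, consistent with visible ferryl accumulation).
FeIII-resting	HS-FeIII	1e5	resting-FeIII reduction (ET)
FeII	HS-FeII	5e4	O2 binding
FeII-O2	LS-FeIII	1e5	oxy reduction to peroxo (ET)
FeIII-O2(2-)	LS-FeIII	5000	peroxo protonation
FeIII-OOH	LS-FeIII	2e4	O-O cleavage
FeIV=O	FeIV=O	1e4	ferryl reduction (ET/PT)
FeIII-OH	HS-FeIII	1e5	hydroxide reduction (ET shunt)
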