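# Native oxidase in solution under the fast-electron-supply thought
# experiment.  Columns: state, Raman-observable class, rate (s^-1) of the
# step leaving the state, step label.
# Rate provenance: hydroxide dissociation 500 s^-1 (reported for the bovine
# enzyme); O2 binding 2600 s^-1 = 1e7 M^-1 s^-1 x 0.26 mM air-saturated O2;
# electron-transfer steps set fast (1e5 s^-1) by construction of the thought
# experiment; remaining chemical steps set to 1e4 s^-1 (fast, not rate
# limiting) as modelling choices.
FeIII-resting	HS-FeIII	1e5	resting-FeIII reduction (ET)
FeII	HS-FeII	2600	O2 binding
FeII-O2	LS-FeIII	1e4	oxy reduction to peroxo (ET)
FeIII-O2(2-)	LS-FeIII	5000	peroxo protonation
FeIII-OOH	LS-FeIII	1e4	O-O cleavage
FeIV=O	FeIV=O	1e4	ferryl reduction (ET/PT)
FeIII-OH	HS-FeIII	500	hydroxide dissociation
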