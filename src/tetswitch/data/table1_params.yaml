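# Best-fit model constants for the CHO Tet-OFF positive-feedback-loop circuit.
# Units: concentrations nM, time minutes.
theta: 4.81        # activation coefficient of the CMV-TET promoter [nM]
alpha0: 1.13e-05   # basal (leaky) activity of the CMV-TET promoter [-]
v1: 7.54e-02       # maximal CMV-TET transcription rate [nM/min]
kp: 2.71e-02       # general translation rate [1/min]
d1: 1.01e-02       # tTA(-IRES-d2EYFP) mRNA degradation rate [1/min]
d2: 1.00e-02       # tTA protein degradation rate [1/min]
d3: 3.24e-03       # d2EYFP protein degradation rate [1/min]
n: 3.16            # Hill coefficient of the CMV-TET promoter [-]
k_dox: 1.00        # Doxycycline/CMV-TET affinity [nM]
h: 6.03e-02        # Hill coefficient of the Doxycycline response [-]
Kf: 1.24e-03       # d2EYFP folding (maturation) rate [1/min]
rho_tTA: 13.69     # constitutive tTA protein level in the open-loop circuit [nM]
s_obs: 1.0         # fluorescence units per nM of folded reporter
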