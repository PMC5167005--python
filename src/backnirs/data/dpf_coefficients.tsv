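# Coefficients of the general equation for the age- and wavelength-dependent
# differential pathlength factor (DPF) of the adult human head:
#   DPF(lambda, A) = alpha + beta*A^gamma + delta*lambda^3 + epsilon*lambda^2 + zeta*lambda
# with age A in years and wavelength lambda in nm, valid for lambda in 690-950 nm.
# Transcribed from F. Scholkmann and M. Wolf, "General equation for the
# differential pathlength factor of the frontal human head depending on
# wavelength and age", J. Biomed. Opt. 18(10), 105004 (2013).
coefficient	value
alpha	223.3
beta	0.05624
gamma	0.8493
delta	-5.723e-7
epsilon	0.001245
zeta	-0.9025
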