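name,Dp_nm,Ra_nm,S_pct,zeta_mV,K_kcalmol,K_derived
CTA,0.851,5.4,0,-38,-5.3,true
PAES-PVP,8.24,10.4,3.83,-64,-6.0,true
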