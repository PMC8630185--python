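row,S_lo,S_lo_open,S_hi,S_hi_open,K_lo,K_lo_open,K_hi,K_hi_open,Ra_lo,Ra_lo_open,Ra_hi,Ra_hi_open,zeta_lo,zeta_lo_open,zeta_hi,zeta_hi_open,Dp_lo,Dp_lo_open,Dp_hi,Dp_hi_open,C5a,IL1beta,IL1alpha,IL6,serpin,properdin,C5b9,verified
1,0,false,0.12,true,-5.6,true,-5.2,false,5.4,false,12,false,-41.5,true,-2.5,false,0.851,false,8,false,9.24E+04,2.36,3.38,11.39,1.75E+06,-4.90E+06,2503.04,true
2,0,false,0.12,true,-6,false,-5.6,false,9,true,10,false,-42,false,-41.5,false,6,false,8,false,1.16E+05,0.27,3.38,12.06,1.75E+06,-6.12E+06,1137.75,true
3,0.12,false,3.83,true,-6.7,false,-6,true,9,true,10,false,-45,true,-42,false,6,false,8,true,1.39E+05,0.01,3.38,13.74,1.75E+06,-4.90E+06,3640.79,true
4,3.83,false,inf,true,-6,false,-5.6,false,9,true,10.4,false,-68,false,-45,false,7,true,8.24,false,1.16E+05,0.27,3.38,12.06,1.75E+06,-6.12E+06,1137.75,true
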