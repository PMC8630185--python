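t_min,Qb_lo,Qb_lo_open,Qb_hi,Qb_hi_open,C5a,IL1beta,IL1alpha,IL6,vWF,serpin,properdin,C5b9,unverified_cells
30,200,true,300,false,1.39E+05,0.01,3.38,13.7,350,1.75E+06,-4.90E+06,3.64E+03,IL6;vWF
30,300,true,400,false,-2.89E+04,-0.32,1.08,8.04,-561.26,2.45E+08,-4.28E+06,-3.64E+03,
30,400,true,500,true,-2.89E+04,-0.32,1.08,10.05,-883.98,-3.94E+07,-1.22E+07,-2.28E+03,
90,200,true,300,false,4.62E+04,-0.5015,0.58328,0.737,-175.3925,3.63E+08,-1.18E+07,-2.28E+03,IL1beta;IL1alpha;IL6
90,300,true,400,false,3.47E+03,-0.89,2.54,9.38,-420.94,6.13E+08,-1.47E+07,-8.19E+03,
90,400,true,500,false,3.47E+03,-0.89,2.16,12.06,-561.26,7.01E+08,-2.26E+07,-7.74E+03,
240,200,true,300,false,4.62E+04,-1.18,2.0288,1.608,-175.3925,1.66E+09,-3.67E+07,-9.10E+03,IL1beta;IL1alpha;IL6
240,300,true,400,false,9.24E+04,-2.66,3.93,14.07,-1.40,1.82E+09,-5.45E+07,-1.87E+04,
240,400,true,500,true,9.24E+04,-4.13,6.34,14.07,-456.02,2.36E+09,-7.96E+07,-2.23E+04,
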