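equation_id,family,biomarker,intercept,b_prop,b_Qb,b_t,b_propQb,b_propT,b_QbT,prop_sign
1,pore_size,C5a,62887.95,-808.46,102.68,-304.16,0,0,0,signed
2,pore_size,properdin,1.125E7,0,7680.83,-42987.50,0,0,713.90,signed
3,pore_size,C5b9,1553.94,36.04,-1.80,-18.27,1.41,0,0.22,signed
4,pore_size,serpin,1.59E8,0,4.58E5,-1.78E6,0,0,-17722.05,signed
5,pore_size,IL1beta,2.84,-0.0066,-0.00082,-0.0095,0,0,0.000052,signed
6,pore_size,IL1alpha,1.36,-0.0024,-0.0017,0.039,0,-0.0024,-7.9E-5,signed
7,pore_size,IL6,1.48,0.00068,0.005933,-0.0073,-0.00031,0,0,signed
8,pore_size,vWF,367.77,15.67,1.48,0,0,0,0,signed
9,roughness,C5a,68651.52,-1194.74,102.68,-304.16,0,0,0,signed
10,roughness,properdin,1.125E7,0,7680.83,-42987.50,0,0,713.90,signed
11,roughness,C5b9,1297.03,53.25,-11.84,-18.27,2.08,0,0.22,signed
12,roughness,serpin,1.59E8,0,4.58E5,-1.78E6,0,0,-17722.05,signed
13,roughness,IL1beta,2.89,-0.0097,-0.00082,-0.0095,0,0,0.000052,signed
14,roughness,IL1alpha,1.38,-0.0035,-0.0017,0.056,0,-0.0036,-7.9E-5,signed
15,roughness,IL6,1.47,0.0010,0.0082,-0.0073,-0.00046,0,0,signed
16,roughness,vWF,256.04,23.16,1.48,0,0,0,0,signed
17,sulfur,C5a,62199.95,-1559.71,102.68,-304.16,0,0,0,signed
18,sulfur,properdin,1.125E7,0,7680.83,-42987.50,0,0,713.90,signed
19,sulfur,C5b9,1584.61,69.52,-0.60,-18.26696,2.72,0,0.22,signed
20,sulfur,serpin,1.59E8,0,4.58E5,-1.78E6,0,0,-17722.05,signed
21,sulfur,IL1beta,2.83,-0.013,-0.00082,-0.0095,0,0,0.000052,signed
22,sulfur,IL1alpha,1.36,-0.0046,-0.0017,0.036741,0,-0.0047,-7.9E-5,signed
23,sulfur,IL6,1.37,0.0013,0.0057,0,-0.000603,0,0,signed
24,sulfur,vWF,381.11,30.24,1.48,0,0,0,0,signed
25,zeta,C5a,68173.63,-175.70,102.68,-304.16,0,0,0,magnitude
26,zeta,properdin,1.125E7,0,7680.83,-42987.50,0,0,713.90,signed
27,zeta,C5b9,1318.33,-7.83,-11.01,-18.27,-0.31,0,0.22,signed
28,zeta,serpin,1.59E8,0,4.58E5,-1.78E6,0,0,-17722.05,signed
29,zeta,IL1beta,2.88,-0.0014,-0.00082,-0.0095,0,0,0.000052,magnitude
30,zeta,IL1alpha,1.38,0.000515,-0.001725,0.055,0,0.000534,-7.9E-5,signed
31,zeta,IL6,1.47,0.00015,0.007975,-0.007292,6.8E-5,0,0,signed
32,zeta,vWF,265.30,-3.41,1.48,0,0,0,0,signed
33,affinity,C5a,1.074E5,-8533.82,102.68,-304.16,0,0,0,magnitude
34,affinity,properdin,1.125E7,0,7680.83,-42987.50,0,0,713.90,signed
35,affinity,C5b9,-431.49,-380.40,-79.40,-18.27,-14.87,0,0.22,signed
36,affinity,serpin,1.59E8,0,4.58E5,-1.78E6,0,0,-17722.05,signed
37,affinity,IL1beta,3.20,0.069,-0.00082,-0.009472,0,0,0.000052,signed
38,affinity,IL1alpha,1.49,0.025,-0.0017,0.17,0,0.026,-7.9E-5,signed
39,affinity,IL6,1.44,-0.0071,0.023,-0.0073,0.0033,0,0,signed
40,affinity,vWF,-495.72,-165.44,1.48,0,0,0,0,signed
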