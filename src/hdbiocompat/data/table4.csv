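membrane,Qb,t,biomarker,predicted,actual,pct_error,transcription_confidence
PAES-PVP,0,30,C5a,4.71E+04,5.24E+04,10.17,high
PAES-PVP,0,30,IL1beta,2.50,2.52,0.71,high
PAES-PVP,0,30,IL1alpha,1.90,1.93,1.38,low
PAES-PVP,0,30,IL6,1.26,1.23,2.69,low
PAES-PVP,0,30,serpin,1.06E+08,9.48E+07,11.59,low
PAES-PVP,0,30,properdin,9.95E+06,9.33E+06,6.64,high
PAES-PVP,0,30,C5b9,1302.88,1436.01,9.27,high
CTA,0,30,C5a,5.31E+04,5.23E+04,1.41,high
CTA,0,30,IL1beta,2.55,2.53,0.70,high
CTA,0,30,IL1alpha,2.46,2.43,1.09,high
CTA,0,30,IL6,1.26,1.22,3.12,low
CTA,0,30,serpin,1.06E+08,1.17E+08,9.41,high
CTA,0,30,properdin,9.95E+06,1.06E+07,5.86,low
CTA,0,30,C5b9,1036.60,903.46,14.74,high
PVDF,0,30,C5a,1.46E+05,1.57E+05,6.83,low
PVDF,0,30,IL1beta,4.92,4.59,7.11,high
PVDF,0,30,IL1alpha,5.92,5.47,8.27,high
PVDF,0,30,IL6,12.65,12.83,1.42,high
PVDF,0,30,serpin,1.08E+08,1.13E+08,4.61,low
PVDF,0,30,properdin,5.05E+06,4.93E+06,2.55,high
PVDF,0,30,C5b9,3501.60,3457.32,1.28,high
PAN,0,30,C5a,1.66E+05,1.61E+05,3.22,high
PAN,0,30,IL1beta,2.79,2.74,1.98,low
PAN,0,30,IL1alpha,5.60,4.69,19.30,high
PAN,0,30,IL6,13.32,13.41,0.67,high
PAN,0,30,serpin,1.08E+08,8.73E+07,23.27,low
PAN,0,30,properdin,3.83E+06,3.80E+06,0.71,high
PAN,0,30,C5b9,2288.46,2571.55,11.01,high
PES,0,30,C5a,1.63E+05,1.66E+05,1.78,high
PES,0,30,IL1beta,2.77,3.36,17.66,high
PES,0,30,IL1alpha,5.28,6.34,16.79,high
PES,0,30,IL6,13.32,12.62,5.57,high
PES,0,30,serpin,1.08E+08,2.95E+08,63.49,high
PES,0,30,properdin,3.83E+06,5.92E+06,35.34,high
PES,0,30,C5b9,2440.62,2146.03,13.73,high
PVDF-ZW,0,30,C5a,1.80E+05,1.75E+05,2.85,high
PVDF-ZW,0,30,IL1beta,2.46,2.13,15.56,high
PVDF-ZW,0,30,IL1alpha,4.72,5.59,15.56,high
PVDF-ZW,0,30,IL6,15.00,14.99,0.09,high
PVDF-ZW,0,30,serpin,1.08E+08,1.44E+08,25.55,low
PVDF-ZW,0,30,properdin,5.05E+06,7.18E+06,29.57,high
PVDF-ZW,0,30,C5b9,5209.94,5011.32,3.96,high
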