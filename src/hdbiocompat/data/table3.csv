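membrane,Qb,t,biomarker,predicted,actual,pct_error,transcription_confidence
CTA,300,30,C5a,83900.0,92300.0,9.1,high
CTA,300,30,IL1beta,2.8,2.8,1.3,low
CTA,300,30,IL1alpha,1.2,1.3,1.8,low
CTA,300,30,IL6,3.0,3.1,3.3,high
CTA,300,30,C5a,83900.0,49200.0,70.3,low
CTA,300,30,IL1beta,2.8,3.0,7.1,low
CTA,300,30,IL1alpha,1.2,1.1,16.3,low
CTA,300,30,IL6,3.0,1.2,148.5,low
CTA,300,30,C5a,83900.0,135000,38.0,high
CTA,300,30,IL1beta,2.8,2.6,5.2,low
CTA,300,30,IL1alpha,1.2,1.5,15.0,low
CTA,300,30,IL6,3.0,4.9,40.0,low
PAES-PVP,300,30,C5a,77900.0,64900.0,20.0,high
PAES-PVP,300,30,IL1beta,2.7,2.7,1.1,low
PAES-PVP,300,30,IL1alpha,0.7,0.6,4.8,low
PAES-PVP,300,30,IL6,2.3,2.2,1.3,low
PAES-PVP,300,30,C5a,77900.0,80000.0,2.6,high
PAES-PVP,300,30,IL1beta,2.7,2.8,2.4,low
PAES-PVP,300,30,IL1alpha,0.7,0.6,4.8,low
PAES-PVP,300,30,IL6,2.3,1.4,57.6,low
PAES-PVP,300,30,C5a,77900.0,49800.0,56.3,high
PAES-PVP,300,30,IL1beta,2.7,2.6,4.9,low
PAES-PVP,300,30,IL1alpha,0.7,0.6,4.8,low
PAES-PVP,300,30,IL6,2.3,3.0,25.3,low
PAES-PVP,200,90,C5a,49400.0,14000.0,253.4,low
PAES-PVP,200,90,IL1beta,2.7,2.5,9.6,low
PAES-PVP,200,90,IL1alpha,1.2,0.6,95.0,low
PAES-PVP,200,90,IL6,1.5,2.9,48.4,high
CTA,300,90,C5a,65600.0,107000,38.8,high
CTA,300,90,IL1beta,3.1,2.8,13.1,low
CTA,300,90,IL1alpha,2.0,1.4,39.4,low
CTA,300,90,IL6,2.5,2.9,12.7,low
PAES-PVP,300,90,C5a,59700.0,88400.0,32.5,high
PAES-PVP,300,90,IL1beta,3.1,2.9,8.3,low
PAES-PVP,300,90,IL1alpha,0.4,1.0,61.6,low
PAES-PVP,300,90,IL6,1.8,2.6,29.1,low
PAES-PVP,400,90,C5a,69900.0,83800.0,16.5,high
PAES-PVP,400,90,IL1beta,3.5,2.5,39.1,low
PAES-PVP,400,90,IL1alpha,-0.5,2.3,122.7,low
PAES-PVP,400,90,IL6,2.2,10.5,79.3,low
PAES-PVP,500,90,C5a,80200.0,89200.0,10.1,high
PAES-PVP,500,90,IL1beta,3.9,2.8,40.1,low
PAES-PVP,500,90,IL1alpha,-1.4,0.9,265.0,low
PAES-PVP,500,90,IL6,2.5,12.6,80.1,high
PAES-PVP,200,240,C5a,3760.0,100000,96.2,high
PAES-PVP,200,240,IL1beta,2.8,2.5,12.4,low
PAES-PVP,200,240,IL1alpha,1.7,2.5,32.4,low
PAES-PVP,200,240,IL6,0.4,13.0,96.9,high
PAES-PVP,300,240,C5a,14000.0,69300.0,79.7,high
PAES-PVP,300,240,IL1beta,4.0,2.7,49.6,low
PAES-PVP,300,240,IL1alpha,-0.4,1.6,125.3,low
PAES-PVP,300,240,IL6,0.7,2.3,68.4,low
CTA,300,240,C5a,20000.0,98500.0,79.7,high
CTA,300,240,IL1beta,4.1,2.4,72.2,low
CTA,300,240,IL1alpha,4.0,2.5,57.8,low
CTA,300,240,IL6,1.4,2.9,51.5,low
PAES-PVP,400,240,C5a,24300.0,128000,81.0,high
PAES-PVP,400,240,IL1beta,5.2,2.6,101.9,low
PAES-PVP,400,240,IL1alpha,-2.5,1.5,270.3,low
PAES-PVP,400,240,IL6,1.1,13.0,91.8,low
PAES-PVP,500,240,C5a,34600.0,108000,68.0,high
PAES-PVP,500,240,IL1beta,6.3,2.1,208.3,low
PAES-PVP,500,240,IL1alpha,-4.5,1.8,350.7,low
PAES-PVP,500,240,IL6,1.4,13.2,89.3,high
CTA,300,30,vWF,824.4,776.5,6.2,high
CTA,300,30,serpin,8.38E+07,1.59E+08,47.3,high
CTA,300,30,properdin,1.87E+07,2.1E+07,11.1,high
CTA,300,30,C5b9,2834.8,2580.1,9.9,high
CTA,300,30,vWF,824.4,201.8,308.5,high
CTA,300,30,serpin,8.38E+07,7.28E+06,1050.5,low
CTA,300,30,properdin,1.87E+07,1.29E+07,44.8,low
CTA,300,30,C5b9,2834.8,1254.1,126.1,high
CTA,300,30,vWF,824.4,1351.1,39.0,high
CTA,300,30,serpin,8.38E+07,3.11E+08,73.1,high
CTA,300,30,properdin,1.87E+07,2.91E+07,35.9,low
CTA,300,30,C5b9,2834.8,3906.1,27.4,high
PAES-PVP,300,30,vWF,940.2,757.4,24.1,high
PAES-PVP,300,30,serpin,8.38E+07,8.47E+06,888.7,low
PAES-PVP,300,30,properdin,1.87E+07,1.63E+07,14.3,low
PAES-PVP,300,30,C5b9,6223.3,6478.1,3.9,high
PAES-PVP,300,30,vWF,940.2,480.3,95.8,high
PAES-PVP,300,30,serpin,8.38E+07,1.25E+07,572.5,low
PAES-PVP,300,30,properdin,1.87E+07,2E+07,6.7,low
PAES-PVP,300,30,C5b9,6223.3,5998.9,3.7,high
PAES-PVP,300,30,vWF,940.2,1034.5,9.1,high
PAES-PVP,300,30,serpin,8.38E+07,4.49E+06,1766.3,high
PAES-PVP,300,30,properdin,1.87E+07,1.27E+07,47.6,low
PAES-PVP,300,30,C5b9,6223.3,6957.3,10.5,high
PAES-PVP,200,90,vWF,792.4,365.0,117.1,high
PAES-PVP,200,90,serpin,-2.28E+08,1.07E+08,313.5,low
PAES-PVP,200,90,properdin,2.18E+07,9.14E+06,138.1,low
PAES-PVP,200,90,C5b9,6126.0,4073.5,50.4,high
CTA,300,90,vWF,824.4,939.8,12.3,high
CTA,300,90,serpin,-3.42E+08,4.67E+08,173.3,high
CTA,300,90,properdin,2.9E+07,1.74E+07,66.6,high
CTA,300,90,C5b9,8819.3,2901.4,204.0,high
PAES-PVP,300,90,vWF,940.2,775.6,21.2,high
PAES-PVP,300,90,serpin,-3.42E+08,2.11E+07,1718.2,low
PAES-PVP,300,90,properdin,2.9E+07,1.71E+07,69.3,low
PAES-PVP,300,90,C5b9,9085.6,8207.3,10.7,high
PAES-PVP,400,90,vWF,1087.9,681.3,59.7,high
PAES-PVP,400,90,serpin,-4.56E+08,1.18E+08,485.8,low
PAES-PVP,400,90,properdin,3.61E+07,1.54E+07,134.4,high
PAES-PVP,400,90,C5b9,12045.2,3851.6,212.7,high
PAES-PVP,500,90,vWF,1235.7,569.3,117.0,high
PAES-PVP,500,90,serpin,-5.69E+08,8.96E+07,735.3,low
PAES-PVP,500,90,properdin,4.33E+07,1.71E+07,152.7,low
PAES-PVP,500,90,C5b9,15004.7,7019.8,113.8,high
CTA,300,240,vWF,824.4,828.4,0.5,high
CTA,300,240,serpin,-1.41E+09,5.71E+08,346.2,low
CTA,300,240,properdin,5.46E+07,2.05E+07,166.4,high
CTA,300,240,C5b9,15975.0,2310.3,591.5,high
PAES-PVP,300,240,vWF,940.2,692.1,35.8,high
PAES-PVP,300,240,serpin,-1.41E+09,2.65E+08,630.4,low
PAES-PVP,300,240,properdin,5.46E+07,1.81E+07,202.3,low
PAES-PVP,300,240,C5b9,16241.3,6681.4,143.1,high
PAES-PVP,200,240,vWF,792.4,1388.9,42.9,high
PAES-PVP,200,240,serpin,-1.03E+09,7.59E+08,235.3,low
PAES-PVP,200,240,properdin,3.67E+07,2.15E+07,71.0,low
PAES-PVP,200,240,C5b9,9983.2,7020.7,42.2,high
PAES-PVP,400,240,vWF,1087.9,1290.4,15.7,high
PAES-PVP,400,240,serpin,-1.79E+09,3.39E+07,5363.9,low
PAES-PVP,400,240,properdin,7.25E+07,1.35E+07,438.0,low
PAES-PVP,400,240,C5b9,22499.5,3801.4,491.9,high
PAES-PVP,500,240,vWF,1235.7,1263.2,2.2,high
PAES-PVP,500,240,serpin,-2.17E+09,1.45E+08,1597.6,low
PAES-PVP,500,240,properdin,9.04E+07,1.18E+07,666.1,high
PAES-PVP,500,240,C5b9,28757.7,6575.3,337.4,high
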