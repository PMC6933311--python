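seal_id,season,at_sea_fmr,mass_change_adj,water_influx,trip_duration,pct_dive,mean_max_depth,fa_cluster,tag_fsa
1,fall,7.79,4.1,184.4,2.8,10.7,45.4,1,7.3
3,fall,5.18,5.7,160.3,5.2,10.5,45.9,1,12.0
9,summer,6.48,1.9,202.9,7.0,8.8,84.8,3,16.7
13,summer,6.14,-0.2,135.9,5.8,19.0,52.1,3,17.8
13,fall,6.36,12.1,140.9,9.3,12.5,34.8,3,17.8
16,fall,6.89,8.3,197.2,8.7,10.8,12.4,1,12.0
18,summer,8.80,4.4,138.7,5.5,14.5,34.8,3,16.7
18,fall,7.91,10.9,119.1,6.3,13.2,24.4,2,16.7
22,fall,6.75,7.4,174.9,7.6,12.7,21.4,3,16.7
25,summer,6.84,0.5,142.1,6.8,20.8,42.4,3,13.8
35,fall,7.00,5.0,124.8,2.8,10.7,18.1,3,17.79
60,fall,7.42,8.8,118.0,8.7,16.4,16.6,3,7.28
61,fall,6.62,2.4,195.1,8.1,15.3,23.9,2,7.28
67,fall,7.29,1.0,173.7,9.1,23.9,12.6,1,7.28
70,fall,6.67,4.9,128.6,7.6,11.3,68.7,2,7.28
74,fall,6.99,6.4,143.0,9.8,11.1,12.5,3,7.4
77,fall,6.47,7.2,149.1,6.4,14.2,32.3,2,7.4
343,summer,7.51,2.7,173.0,6.5,7.8,12.5,1,12.0
343,fall,6.90,4.6,157.2,4.8,12.8,52.6,2,7.3
344,fall,6.46,3.7,183.7,7.2,12.1,11.8,1,12.0
345,summer,6.47,3.8,168.5,7.1,9.9,7.6,1,7.3
345,fall,7.01,8.0,128.6,8.1,16.8,15.5,3,7.3
349,summer,6.70,5.5,143.5,8.6,12.5,29.2,2,16.5
349,fall,6.90,2.9,119.9,6.9,13.8,14.4,3,16.5
350,summer,6.20,3.7,168.9,5.7,12.1,36.2,1,16.5
350,fall,7.08,6.8,201.6,7.5,18.1,11.6,1,16.5
355,summer,7.09,5.5,181.9,6.0,9.7,32.0,2,7.3
355,fall,6.76,5.2,154.7,6.2,12.6,18.9,3,7.3
356,summer,6.61,3.9,187.3,7.8,6.9,10.2,1,12.0
357,fall,6.80,1.7,176.2,5.2,9.2,28.7,2,13.8
360,summer,7.44,3.4,196.6,3.9,15.0,38.5,2,12.0
360,fall,,4.5,154.3,6.3,13.0,13.9,3,12.0
361,summer,5.52,2.9,157.5,5.6,13.2,42.1,2,16.45
361,fall,7.61,5.9,204.8,6.5,15.4,57.9,2,16.45
362,summer,5.50,6.9,254.1,7.9,5.7,10.5,1,7.3
362,fall,7.98,4.0,225.7,7.7,8.1,8.0,1,7.3
367,summer,5.54,6.5,212.5,6.7,16.3,11.9,1,13.8
367,fall,7.06,6.5,217.4,8.4,9.8,6.0,1,13.8
370,summer,5.93,1.4,194.5,6.2,20.4,12.6,1,7.3
370,fall,6.48,3.7,212.0,8.0,13.4,9.2,1,7.3
371,fall,7.30,5.3,110.8,6.9,15.3,22.3,2,13.8
374,summer,6.77,0.0,144.0,5.0,14.8,14.5,1,7.3
374,fall,8.69,7.6,141.3,6.4,10.6,15.7,3,7.3
375,summer,6.94,4.2,153.5,6.1,15.7,17.6,1,16.5
375,fall,9.68,0.3,126.7,3.3,8.1,37.3,2,16.5
376,summer,7.54,2.4,168.5,4.7,20.2,26.0,1,12.0
376,fall,7.55,1.7,166.6,5.8,12.8,36.1,2,12.0
380,summer,6.26,5.5,174.0,6.8,16.2,12.8,1,16.5
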