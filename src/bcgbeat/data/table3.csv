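participant_id,total_r_peaks,true_positives,false_positives,undetected,accuracy_percent,snr_db
1,73,72,0,1,98.6,36.3
2,84,80,2,2,95.2,33.5
3,81,77,1,3,95,43
4,69,46,19,4,66.6,19.9
5,69,61,5,3,88.4,25.7
6,77,77,0,0,100,38.2
7,74,60,8,6,81,26.6
8,67,67,0,0,100,41.2
9,76,73,1,2,96,30.7
10,73,71,1,1,97.2,34.8
11,71,67,3,1,94.3,26.4
12,73,71,1,1,97.2,28.8
13,70,67,1,2,95.7,35.5
14,60,59,0,1,98.3,43.5
15,78,60,16,2,76.9,19.6
16,58,56,2,0,96.5,27.9
17,74,71,3,0,95.9,28.8
18,62,50,11,1,80.6,25.9
19,58,57,1,0,98.2,37.4
20,63,48,15,0,76.1,30.1
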