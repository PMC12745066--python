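x,y
0.00000000,6.45000000
1.72420689,6.43482773
3.60384753,6.24204702
5.42620185,5.42620185
6.49230721,3.74833532
6.77689962,1.81586478
6.80000000,0.00000000
6.77689962,-1.81586478
6.49230721,-3.74833532
5.42620185,-5.42620185
3.60384753,-6.24204702
1.72420689,-6.43482773
0.00000000,-6.45000000
-1.72420689,-6.43482773
-3.60384753,-6.24204702
-5.42620185,-5.42620185
-6.49230721,-3.74833532
-6.77689962,-1.81586478
-6.80000000,-0.00000000
-6.77689962,1.81586478
-6.49230721,3.74833532
-5.42620185,5.42620185
-3.60384753,6.24204702
-1.72420689,6.43482773
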