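x,y,z
28.00000000,0.00000000,0.00000000
-28.00000000,0.00000000,0.00000000
0.00000000,22.00000000,0.00000000
0.00000000,-22.00000000,0.00000000
0.00000000,0.00000000,16.00000000
0.00000000,0.00000000,-16.00000000
27.04592314,5.69401899,0.00000000
19.79898987,15.55634919,0.00000000
7.24693326,21.25036818,0.00000000
-7.24693326,21.25036818,0.00000000
-19.79898987,15.55634919,0.00000000
-27.04592314,5.69401899,0.00000000
-27.04592314,-5.69401899,0.00000000
-19.79898987,-15.55634919,0.00000000
-7.24693326,-21.25036818,0.00000000
7.24693326,-21.25036818,0.00000000
19.79898987,-15.55634919,0.00000000
27.04592314,-5.69401899,0.00000000
17.14642820,7.77817459,11.31370850
0.00000000,15.55634919,11.31370850
-17.14642820,7.77817459,11.31370850
-17.14642820,-7.77817459,11.31370850
-0.00000000,-15.55634919,11.31370850
17.14642820,-7.77817459,11.31370850
17.14642820,7.77817459,-11.31370850
0.00000000,15.55634919,-11.31370850
-17.14642820,7.77817459,-11.31370850
-17.14642820,-7.77817459,-11.31370850
-0.00000000,-15.55634919,-11.31370850
17.14642820,-7.77817459,-11.31370850
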