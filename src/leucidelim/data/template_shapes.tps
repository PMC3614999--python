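LM=21
-0.289662 0.014417
-0.263358 0.034146
-0.171292 0.074918
-0.243629 0.036776
-0.263358 -0.005311
-0.177868 -0.042926
-0.15814 0.014417
-0.151564 0.001265
-0.138412 -0.03635
-0.138412 -0.056079
-0.000313 0.08807
0.065448 0.074918
0.31534 0.0302
0.275884 0.0302
0.341645 0.001265
0.275884 -0.021094
0.31534 -0.021094
0.170666 -0.049502
0.124633 -0.056079
0.104905 -0.049502
0.006263 -0.062655
ID=Sl
LM=21
-0.289493 0.014145
-0.26309 0.033947
-0.170678 0.066951
-0.243287 0.033947
-0.26309 -0.005658
-0.177279 -0.038662
-0.157477 0.014145
-0.150876 0.000943
-0.137674 -0.032061
-0.137674 -0.051864
-0.012259 0.080153
0.05375 0.066951
0.317782 0.033947
0.278177 0.033947
0.344186 0.000943
0.278177 -0.02546
0.317782 -0.02546
0.172564 -0.045263
0.126359 -0.051864
0.106556 -0.045263
0.007544 -0.058464
ID=Ss
LM=21
-0.286428 0.01483
-0.260236 0.034474
-0.168564 0.085548
-0.240592 0.039712
-0.260236 -0.004814
-0.175112 -0.048555
-0.155468 0.01483
-0.14892 0.001734
-0.135824 -0.042007
-0.135824 -0.061651
-0.01927 0.098644
0.04621 0.085548
0.315987 0.031854
0.276699 0.031854
0.342179 0.001734
0.276699 -0.021839
0.315987 -0.021839
0.171932 -0.055103
0.126096 -0.061651
0.106452 -0.055103
0.008232 -0.068199
ID=Tm
LM=21
-0.286676 0.015213
-0.260575 0.034789
-0.169222 0.092211
-0.241 0.038704
-0.260575 -0.004363
-0.175747 -0.051866
-0.156171 0.015213
-0.149646 0.002163
-0.136595 -0.045341
-0.136595 -0.064917
-0.007395 0.105262
0.057857 0.092211
0.313647 0.028264
0.274496 0.028264
0.339749 0.002163
0.274496 -0.017413
0.313647 -0.017413
0.170092 -0.058392
0.124415 -0.064917
0.104839 -0.058392
0.00696 -0.071442
ID=Rr
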