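freq_khz,0.1,0.2,0.3,0.4,0.5,0.6,0.7,0.8,0.9,1.0
5,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.50e3,9.20e3,1.40e4,2.85e4,4.70e4
10,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.50e3,9.20e3,1.40e4,2.62e4,3.90e4
20,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.50e3,9.20e3,1.40e4,2.10e4,2.80e4
30,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.50e3,9.20e3,1.40e4,1.75e4,2.10e4
40,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.40e3,9.20e3,1.35e4,1.50e4,1.70e4
50,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.30e3,8.80e3,1.30e4,1.33e4,1.40e4
60,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.20e3,8.60e3,1.25e4,1.23e4,1.20e4
70,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.10e3,8.43e3,1.20e4,1.15e4,1.10e4
80,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,7.00e3,8.26e3,1.15e4,1.05e4,1.00e4
90,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,6.85e3,8.09e3,1.11e4,9.70e3,9.00e3
100,5.00e3,5.20e3,5.50e3,5.90e3,6.30e3,6.70e3,7.92e3,1.07e4,9.20e3,8.50e3
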