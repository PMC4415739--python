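freq_khz,0.1,0.2,0.3,0.4,0.5,0.6,0.7,0.8,0.9,1.0
5,2.25e-4,2.60e-4,2.95e-4,3.60e-4,4.25e-4,5.90e-4,8.85e-4,1.70e-3,4.80e-3,7.64e-3
10,4.25e-4,4.80e-4,5.55e-4,6.60e-4,7.75e-4,1.09e-3,1.64e-3,3.30e-3,9.95e-3,1.53e-2
20,7.30e-4,8.20e-4,9.55e-4,1.10e-3,1.32e-3,1.90e-3,2.88e-3,6.10e-3,1.85e-2,2.80e-2
30,1.10e-3,1.20e-3,1.40e-3,1.60e-3,1.92e-3,2.75e-3,4.18e-3,8.80e-3,2.43e-2,3.60e-2
40,1.60e-3,1.70e-3,2.00e-3,2.30e-3,2.65e-3,3.70e-3,5.50e-3,1.14e-2,2.83e-2,4.10e-2
50,2.30e-3,2.40e-3,2.80e-3,3.20e-3,3.55e-3,4.80e-3,7.00e-3,1.41e-2,3.18e-2,4.35e-2
60,3.20e-3,3.30e-3,3.80e-3,4.20e-3,4.70e-3,6.30e-3,8.73e-3,1.71e-2,3.60e-2,4.55e-2
70,4.20e-3,4.30e-3,4.90e-3,5.40e-3,6.00e-3,7.80e-3,1.06E-02,1.98e-2,3.90e-2,4.93e-2
80,5.40e-3,5.50e-3,6.20e-3,6.90e-3,7.50e-3,9.50e-3,1.27e-2,2.28e-2,4.10e-2,5.13e-2
90,6.70e-3,6.80e-3,7.70e-3,8.40e-3,9.10e-3,1.11e-2,1.49e-2,2.56e-2,4.30e-2,5.20e-2
100,8.20e-3,8.30e-3,9.30e-3,1.01e-2,1.09e-2,1.31e-2,1.72e-2,2.86e-2,4.59e-2,5.49e-2
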