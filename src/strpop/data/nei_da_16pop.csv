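,Gorkha,Nepalese,Tibet,Tamang,Newar,Kathmandu,Bhil_Guj,Bhil_MP,Tamil,Brahmin,Raju,Komati,Chinese,Nepal,Korea,Sherpa
Gorkha,0.000,0.015,0.027,0.027,0.032,0.023,0.020,0.028,0.025,0.032,0.029,0.038,0.023,0.016,0.021,0.038
Nepalese,0.015,0.000,0.012,0.012,0.021,0.016,0.022,0.033,0.033,0.038,0.032,0.043,0.013,0.010,0.011,0.023
Tibet,0.027,0.012,0.000,0.000,0.033,0.029,0.035,0.047,0.047,0.053,0.050,0.057,0.021,0.022,0.019,0.023
Tamang,0.027,0.012,0.000,0.000,0.033,0.029,0.035,0.047,0.047,0.053,0.050,0.057,0.021,0.022,0.019,0.023
Newar,0.032,0.021,0.033,0.033,0.000,0.029,0.029,0.039,0.042,0.053,0.042,0.047,0.036,0.024,0.031,0.041
Kathmandu,0.023,0.016,0.029,0.029,0.029,0.000,0.022,0.030,0.026,0.036,0.033,0.044,0.028,0.015,0.026,0.036
Bhil_Guj,0.020,0.022,0.035,0.035,0.029,0.022,0.000,0.012,0.014,0.024,0.022,0.026,0.030,0.016,0.029,0.044
Bhil_MP,0.028,0.033,0.047,0.047,0.039,0.030,0.012,0.000,0.017,0.033,0.027,0.033,0.042,0.025,0.040,0.051
Tamil,0.025,0.033,0.047,0.047,0.042,0.026,0.014,0.017,0.000,0.023,0.021,0.029,0.039,0.022,0.037,0.055
Brahmin,0.032,0.038,0.053,0.053,0.053,0.036,0.024,0.033,0.023,0.000,0.030,0.032,0.042,0.030,0.043,0.062
Raju,0.029,0.032,0.050,0.050,0.042,0.033,0.022,0.027,0.021,0.030,0.000,0.028,0.038,0.027,0.036,0.057
Komati,0.038,0.043,0.057,0.057,0.047,0.044,0.026,0.033,0.029,0.032,0.028,0.000,0.044,0.036,0.044,0.061
Chinese,0.023,0.013,0.021,0.021,0.036,0.028,0.030,0.042,0.039,0.042,0.038,0.044,0.000,0.020,0.006,0.033
Nepal,0.016,0.010,0.022,0.022,0.024,0.015,0.016,0.025,0.022,0.030,0.027,0.036,0.020,0.000,0.018,0.033
Korea,0.021,0.011,0.019,0.019,0.031,0.026,0.029,0.040,0.037,0.043,0.036,0.044,0.006,0.018,0.000,0.027
Sherpa,0.038,0.023,0.023,0.023,0.041,0.036,0.044,0.051,0.055,0.062,0.057,0.061,0.033,0.033,0.027,0.000
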