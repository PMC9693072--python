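tag,d_doxh,alpha_doxh,beta,d_gra_1,alpha_gra_1,d_gra_2,alpha_gra_2,energy,type
II-1,9.5669,14.32,174.93,4.5856,6.91,4.5947,7.41,-4.7197,B1
II-2,8.3056,1.69,0.89,4.6019,7.56,4.5674,5.91,-4.8595,B2
II-3,8.2438,1.83,1.03,4.6308,8.91,4.5893,7.13,-4.8559,B2
II-4,8.2883,1.45,0.78,4.6132,8.40,4.5827,6.98,-4.8565,B2
II-5,8.3903,6.91,3.15,4.5351,1.29,4.5964,7.87,-4.8096,B2
II-6,8.3082,1.57,0.84,4.5997,7.56,4.5671,6.02,-4.8592,B2
II-7,8.2799,2.16,1.15,4.5709,6.15,4.6147,8.27,-4.8605,B2
II-8,8.3143,4.26,2.08,4.5451,4.01,4.6106,8.20,-4.8531,B2
II-9,8.4782,5.30,2.42,4.5777,6.27,4.5368,1.27,-4.7656,B2
II-10,7.5203,12.28,175.96,4.5692,5.95,4.5747,6.32,-4.9018,B1
II-11,7.5246,13.03,175.53,4.5795,6.44,4.5804,6.59,-4.9033,B1
II-12,7.5283,5.77,179.13,4.5420,1.32,4.5435,4.65,-4.8280,B1
II-13,9.5403,15.53,174.35,4.5962,7.45,4.6075,8.08,-4.7194,B1
II-14,8.2786,2.64,1.37,4.6177,8.43,4.5664,5.83,-4.8607,B2
II-15,8.2860,2.55,1.33,4.6144,8.24,4.5642,5.74,-4.8607,B2
III-1,8.2827,2.54,1.32,4.6150,8.30,4.5659,5.82,-4.8608,B2
III-2,7.2275,13.63,175.31,4.5843,6.83,4.5839,6.80,-4.8904,B1
III-3,8.3175,1.84,0.98,4.5967,7.33,4.5604,5.54,-4.8583,B2
III-4,8.3901,6.90,3.14,4.5965,7.86,4.5350,1.29,-4.8096,B2
III-5,7.2301,13.27,175.49,4.5812,6.68,4.5801,6.59,-4.8904,B1
III-6,8.2888,2.81,1.45,4.5608,5.49,4.6138,8.25,-4.8605,B2
III-7,7.5324,13.19,175.45,4.5834,6.76,4.5805,6.42,-4.9032,B1
III-8,8.2871,2.77,1.43,4.6145,8.28,4.5617,5.56,-4.8606,B2
III-9,7.2297,13.41,175.42,4.5819,6.69,4.5821,6.72,-4.8904,B1
III-10,8.2896,2.47,1.29,4.6115,8.15,4.5648,5.73,-4.8607,B2
III-11,7.5227,12.16,176.01,4.5683,6.13,4.5708,6.03,-4.9017,B1
III-12,8.2924,2.07,1.09,4.6060,7.93,4.5666,5.91,-4.8604,B2
III-13,8.2927,2.13,1.02,4.6055,7.93,4.5670,5.82,-4.8602,B2
III-14,7.2314,13.15,175.54,4.5793,6.49,4.5805,6.65,-4.8903,B1
III-15,9.5455,15.31,174.45,4.6037,7.84,4.5956,7.47,-4.7201,B1
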