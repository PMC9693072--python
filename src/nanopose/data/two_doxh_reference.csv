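tag,d_doxh,alpha_doxh,beta,energy,type
II-1,4.2801,4.70,47.14,-1.3675,A2
II-2,5.8028,176.88,28.11,-1.2040,failure
II-3,4.2841,4.51,46.96,-1.3677,A2
II-4,6.3702,178.64,167.28,-1.2228,A1
II-5,6.3704,178.63,167.27,-1.2228,A1
II-6,4.3152,3.39,44.64,-1.3663,A2
II-7,4.0874,174.24,88.23,-1.4729,A3
II-8,4.2851,4.34,46.84,-1.3678,A2
II-9,4.2920,2.72,45.59,-1.3607,A2
II-10,6.3809,178.08,167.16,-1.2226,A1
II-11,4.2895,4.33,46.56,-1.3677,A2
II-12,4.2712,5.30,47.93,-1.3662,A2
II-13,4.2796,4.50,47.22,-1.3677,A2
II-14,4.9067,2.37,20.16,-1.2768,failure
II-15,4.2737,4.21,47.30,-1.3674,A2
III-1,4.2797,4.10,46.91,-1.3675,A2
III-2,4.2852,4.34,46.83,-1.3678,A2
III-3,4.0587,174.27,89.24,-1.4778,A3
III-4,4.2775,3.49,46.64,-1.3652,A2
III-5,4.2889,4.26,46.58,-1.3677,A2
III-6,4.2851,4.20,46.74,-1.3677,A2
III-7,4.2558,4.67,48.41,-1.3670,A2
III-8,4.0571,174.19,89.33,-1.4777,A3
III-9,4.2927,3.93,46.31,-1.3675,A2
III-10,4.2932,3.94,46.04,-1.3675,A2
III-11,4.2856,4.29,46.78,-1.3677,A2
III-12,4.2971,3.90,45.98,-1.3674,A2
III-13,4.2903,4.00,46.40,-1.3676,A2
III-14,4.3148,3.57,45.12,-1.3666,A2
III-15,5.0104,1.41,21.25,-1.2404,failure
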