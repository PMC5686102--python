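{
 "albedo_nodes": [
  0.6,
  0.7,
  0.78,
  0.84,
  0.88,
  0.91,
  0.935,
  0.955,
  0.97,
  0.985
 ],
 "v_nodes": [
  0.0,
  0.025,
  0.05,
  0.08,
  0.115,
  0.155,
  0.2,
  0.25,
  0.31,
  0.38,
  0.5,
  0.7,
  1.0
 ],
 "correction": [
  [
   0.639,
   0.63641,
   0.62946,
   0.61822,
   0.60598,
   0.59825,
   0.6005,
   0.61645,
   0.65119,
   0.70742,
   0.82845,
   1.06581,
   1.45958
  ],
  [
   0.7261,
   0.72247,
   0.71276,
   0.69698,
   0.67921,
   0.66589,
   0.66306,
   0.67467,
   0.70492,
   0.75589,
   0.87187,
   1.11276,
   1.4975
  ],
  [
   0.7993,
   0.79468,
   0.78235,
   0.76238,
   0.73943,
   0.72042,
   0.71184,
   0.71811,
   0.74339,
   0.79067,
   0.90467,
   1.14203,
   1.52491
  ],
  [
   0.85782,
   0.85234,
   0.83784,
   0.81452,
   0.78754,
   0.7641,
   0.75062,
   0.75205,
   0.77346,
   0.81901,
   0.92942,
   1.16124,
   1.56569
  ],
  [
   0.89681,
   0.8902,
   0.87285,
   0.84523,
   0.81337,
   0.78577,
   0.76999,
   0.77103,
   0.79266,
   0.83859,
   0.94763,
   1.1714,
   1.55053
  ],
  [
   0.92799,
   0.92086,
   0.90259,
   0.87441,
   0.84263,
   0.81468,
   0.79775,
   0.79593,
   0.81255,
   0.85378,
   0.95785,
   1.19642,
   1.59222
  ],
  [
   0.95599,
   0.94841,
   0.92919,
   0.89989,
   0.86696,
   0.83733,
   0.81774,
   0.8138,
   0.82835,
   0.86798,
   0.96847,
   1.19378,
   1.57342
  ],
  [
   0.97844,
   0.97056,
   0.95064,
   0.92028,
   0.88649,
   0.85723,
   0.83867,
   0.83456,
   0.84917,
   0.88733,
   0.99142,
   1.21716,
   1.60476
  ],
  [
   0.99204,
   0.98406,
   0.96378,
   0.93292,
   0.89717,
   0.86446,
   0.84347,
   0.8378,
   0.8538,
   0.89216,
   0.99937,
   1.23963,
   1.66754
  ],
  [
   1.00655,
   0.99859,
   0.97712,
   0.94284,
   0.90499,
   0.87275,
   0.85632,
   0.85386,
   0.86767,
   0.90589,
   1.01114,
   1.21246,
   1.66172
  ]
 ],
 "stderr": [
  [
   0.00182,
   0.00183,
   0.00187,
   0.00197,
   0.00213,
   0.00238,
   0.00273,
   0.0032,
   0.00386,
   0.00474,
   0.0065,
   0.01003,
   0.01651
  ],
  [
   0.00166,
   0.00168,
   0.00173,
   0.00183,
   0.00201,
   0.00228,
   0.00266,
   0.00315,
   0.00383,
   0.00473,
   0.0065,
   0.01002,
   0.01646
  ],
  [
   0.00152,
   0.00154,
   0.0016,
   0.00171,
   0.00192,
   0.00222,
   0.00262,
   0.00314,
   0.00385,
   0.00478,
   0.00659,
   0.01016,
   0.01665
  ],
  [
   0.00139,
   0.00142,
   0.00148,
   0.00163,
   0.00186,
   0.00219,
   0.00263,
   0.00318,
   0.00392,
   0.00489,
   0.00676,
   0.01042,
   0.01702
  ],
  [
   0.00163,
   0.00166,
   0.00176,
   0.00197,
   0.0023,
   0.00276,
   0.00336,
   0.00409,
   0.00506,
   0.00632,
   0.00874,
   0.01348,
   0.02199
  ],
  [
   0.0015,
   0.00154,
   0.00167,
   0.00191,
   0.00229,
   0.00278,
   0.00341,
   0.00418,
   0.0052,
   0.0065,
   0.00901,
   0.01389,
   0.02267
  ],
  [
   0.00137,
   0.00142,
   0.00158,
   0.00187,
   0.00228,
   0.00282,
   0.00348,
   0.00429,
   0.00534,
   0.00669,
   0.00927,
   0.01425,
   0.0231
  ],
  [
   0.00124,
   0.0013,
   0.0015,
   0.00184,
   0.0023,
   0.00288,
   0.00358,
   0.00442,
   0.00553,
   0.00692,
   0.00959,
   0.01476,
   0.02395
  ],
  [
   0.00143,
   0.00154,
   0.00185,
   0.00235,
   0.003,
   0.00379,
   0.00474,
   0.00587,
   0.00734,
   0.00921,
   0.01277,
   0.0196,
   0.03176
  ],
  [
   0.00117,
   0.00135,
   0.00177,
   0.00236,
   0.00308,
   0.00393,
   0.00493,
   0.00612,
   0.00765,
   0.00959,
   0.01329,
   0.02038,
   0.033
  ]
 ],
 "g": 0.9,
 "n": 1.4,
 "seed": 20170,
 "quick": false
}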