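study,label,dq_yes,dq_no,p1,n21,n11,n22,n12
I-Question,Drug use1-Q1,,,0.2,249,112,150,223
I-Question,Drug use1-Q2,,,0.2,188,185,183,178
I-Question,Drug use1-Q3,,,0.2,197,164,174,199
I-Question,Drug use1-Q4,,,0.2,275,98,120,241
I-Statement,Drug use1-S1,,,0.2,233,143,166,229
I-Statement,Drug use1-S2,,,0.2,197,198,171,205
I-Statement,Drug use1-S3,,,0.2,187,189,208,187
I-Statement,Drug use1-S4,,,0.2,304,91,120,256
II-Factual,Covid-F1,37,341,0.2,249,145,186,247
II-Factual,Covid-F2,52,326,0.2,284,149,164,230
II-Factual,Covid-F3,128,250,0.2,233,161,181,252
II-Factual,Covid-F4,65,313,0.2,271,162,146,248
II-Judgmental,Covid-J1,44,359,0.2,262,158,149,225
II-Judgmental,Covid-J2,53,350,0.2,233,141,154,266
II-Judgmental,Covid-J3,103,300,0.2,237,183,151,223
II-Judgmental,Covid-J4,28,375,0.2,210,164,155,265
III-Question,Drug use2-Q1,121,469,0.2,438,163,232,378
III-Question,Drug use2-Q2,274,316,0.2,330,280,285,316
III-Question,Drug use2-Q3,230,360,0.2,302,299,300,310
III-Question,Drug use2-Q4,26,564,0.2,478,132,138,463
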