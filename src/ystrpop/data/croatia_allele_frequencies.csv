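locus,allele,frequency
DYF387S1a,34,0.018
DYF387S1a,35,0.144
DYF387S1a,36,0.15
DYF387S1a,37,0.274
DYF387S1a,38,0.353
DYF387S1a,39,0.059
DYF387S1a,40,0.002
DYF387S1b,35,0.034
DYF387S1b,36,0.049
DYF387S1b,37,0.089
DYF387S1b,38,0.363
DYF387S1b,39,0.391
DYF387S1b,40,0.063
DYF387S1b,41,0.012
DYS19,9,0.002
DYS19,12,0.002
DYS19,13,0.126
DYS19,14,0.134
DYS19,15,0.249
DYS19,16,0.4
DYS19,17,0.083
DYS19,18,0.004
DYS385a,10,0.028
DYS385a,11,0.27
DYS385a,12,0.028
DYS385a,13,0.114
DYS385a,14,0.394
DYS385a,15,0.059
DYS385a,16,0.085
DYS385a,17,0.022
DYS385b,11,0.006
DYS385b,12,0.002
DYS385b,13,0.036
DYS385b,14,0.32
DYS385b,15,0.406
DYS385b,16,0.049
DYS385b,17,0.075
DYS385b,18,0.081
DYS385b,19,0.018
DYS385b,20,0.008
DYS389I,11,0.002
DYS389I,12,0.144
DYS389I,13,0.704
DYS389I,14,0.146
DYS389I,15,0.002
DYS389I,16,0.002
DYS389II,27,0.004
DYS389II,28,0.075
DYS389II,29,0.178
DYS389II,30,0.329
DYS389II,31,0.321
DYS389II,32,0.087
DYS389II,33,0.004
DYS389II,34,0.002
DYS390,21,0.004
DYS390,22,0.069
DYS390,23,0.148
DYS390,24,0.527
DYS390,25,0.237
DYS390,26,0.016
DYS391,9,0.02
DYS391,10,0.485
DYS391,11,0.483
DYS391,12,0.01
DYS391,13,0.002
DYS392,11,0.862
DYS392,12,0.041
DYS392,13,0.065
DYS392,14,0.012
DYS392,15,0.018
DYS392,16,0.002
DYS393,12,0.081
DYS393,13,0.854
DYS393,14,0.059
DYS393,15,0.006
DYS437,13,0.002
DYS437,14,0.432
DYS437,15,0.465
DYS437,16,0.101
DYS438,7,0.002
DYS438,9,0.079
DYS438,10,0.602
DYS438,11,0.256
DYS438,12,0.057
DYS438,13,0.004
DYS439,9,0.006
DYS439,10,0.162
DYS439,11,0.235
DYS439,12,0.333
DYS439,13,0.235
DYS439,14,0.03
DYS448,17,0.002
DYS448,18,0.008
DYS448,19,0.357
DYS448,20,0.556
DYS448,21,0.073
DYS448,22,0.002
DYS448,23,0.002
DYS449,25,0.002
DYS449,26,0.002
DYS449,27,0.014
DYS449,28,0.073
DYS449,29,0.144
DYS449,30,0.168
DYS449,31,0.233
DYS449,32,0.191
DYS449,33,0.128
DYS449,34,0.043
DYS449,35,0.002
DYS456,12,0.006
DYS456,13,0.02
DYS456,14,0.077
DYS456,15,0.509
DYS456,16,0.223
DYS456,17,0.15
DYS456,18,0.016
DYS458,13,0.008
DYS458,14,0.032
DYS458,15,0.249
DYS458,16,0.231
DYS458,17,0.331
DYS458,18,0.112
DYS458,19,0.036
DYS458,20,0.002
DYS460,8,0.006
DYS460,9,0.097
DYS460,10,0.584
DYS460,11,0.262
DYS460,12,0.051
DYS481,20,0.004
DYS481,21,0.083
DYS481,22,0.15
DYS481,23,0.178
DYS481,24,0.077
DYS481,25,0.063
DYS481,26,0.016
DYS481,27,0.037
DYS481,28,0.045
DYS481,29,0.059
DYS481,30,0.164
DYS481,31,0.103
DYS481,32,0.018
DYS481,33,0.004
DYS518,35,0.002
DYS518,36,0.018
DYS518,37,0.051
DYS518,38,0.124
DYS518,39,0.292
DYS518,40,0.254
DYS518,41,0.16
DYS518,42,0.067
DYS518,43,0.028
DYS518,44,0.004
DYS533,9,0.012
DYS533,10,0.014
DYS533,11,0.124
DYS533,12,0.517
DYS533,13,0.321
DYS533,14,0.012
DYS570,15,0.006
DYS570,16,0.041
DYS570,17,0.178
DYS570,18,0.391
DYS570,19,0.217
DYS570,20,0.11
DYS570,21,0.041
DYS570,22,0.016
DYS576,15,0.022
DYS576,16,0.095
DYS576,17,0.28
DYS576,18,0.416
DYS576,19,0.128
DYS576,20,0.045
DYS576,21,0.01
DYS576,22,0.004
DYS627,15,0.014
DYS627,16,0.077
DYS627,17,0.136
DYS627,18,0.063
DYS627,19,0.105
DYS627,20,0.306
DYS627,21,0.187
DYS627,22,0.073
DYS627,23,0.032
DYS627,24,0.008
DYS635,20,0.024
DYS635,21,0.116
DYS635,22,0.235
DYS635,23,0.499
DYS635,24,0.103
DYS635,25,0.022
DYS635,26,0.002
YGATAH4,10,0.039
YGATAH4,11,0.531
YGATAH4,12,0.361
YGATAH4,13,0.069
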