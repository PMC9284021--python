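locus,allele
DYF387S1a,34
DYF387S1a,35
DYF387S1a,36
DYF387S1a,37
DYF387S1a,38
DYF387S1a,39
DYF387S1a,40
DYF387S1b,35
DYF387S1b,36
DYF387S1b,37
DYF387S1b,38
DYF387S1b,39
DYF387S1b,40
DYF387S1b,41
DYS19,9
DYS19,12
DYS19,13
DYS19,14
DYS19,15
DYS19,16
DYS19,17
DYS19,18
DYS385a,10
DYS385a,11
DYS385a,12
DYS385a,13
DYS385a,14
DYS385a,15
DYS385a,16
DYS385a,17
DYS385b,11
DYS385b,12
DYS385b,13
DYS385b,14
DYS385b,15
DYS385b,16
DYS385b,17
DYS385b,18
DYS385b,19
DYS385b,20
DYS389I,11
DYS389I,12
DYS389I,13
DYS389I,14
DYS389I,15
DYS389I,16
DYS389II,27
DYS389II,28
DYS389II,29
DYS389II,30
DYS389II,31
DYS389II,32
DYS389II,33
DYS389II,34
DYS390,21
DYS390,22
DYS390,23
DYS390,24
DYS390,25
DYS390,26
DYS391,9
DYS391,10
DYS391,11
DYS391,12
DYS391,13
DYS392,11
DYS392,12
DYS392,13
DYS392,14
DYS392,15
DYS392,16
DYS393,12
DYS393,13
DYS393,14
DYS393,15
DYS437,13
DYS437,14
DYS437,15
DYS437,16
DYS438,7
DYS438,9
DYS438,10
DYS438,11
DYS438,12
DYS438,13
DYS439,9
DYS439,10
DYS439,11
DYS439,12
DYS439,13
DYS439,14
DYS448,17
DYS448,18
DYS448,19
DYS448,20
DYS448,21
DYS448,22
DYS448,23
DYS449,25
DYS449,26
DYS449,27
DYS449,28
DYS449,29
DYS449,30
DYS449,31
DYS449,32
DYS449,33
DYS449,34
DYS449,35
DYS456,12
DYS456,13
DYS456,14
DYS456,15
DYS456,16
DYS456,17
DYS456,18
DYS458,13
DYS458,14
DYS458,15
DYS458,16
DYS458,17
DYS458,18
DYS458,19
DYS458,20
DYS460,8
DYS460,9
DYS460,10
DYS460,11
DYS460,12
DYS481,20
DYS481,21
DYS481,22
DYS481,23
DYS481,24
DYS481,25
DYS481,26
DYS481,27
DYS481,28
DYS481,29
DYS481,30
DYS481,31
DYS481,32
DYS481,33
DYS518,35
DYS518,36
DYS518,37
DYS518,38
DYS518,39
DYS518,40
DYS518,41
DYS518,42
DYS518,43
DYS518,44
DYS533,9
DYS533,10
DYS533,11
DYS533,12
DYS533,13
DYS533,14
DYS570,15
DYS570,16
DYS570,17
DYS570,18
DYS570,19
DYS570,20
DYS570,21
DYS570,22
DYS576,15
DYS576,16
DYS576,17
DYS576,18
DYS576,19
DYS576,20
DYS576,21
DYS576,22
DYS627,15
DYS627,16
DYS627,17
DYS627,18
DYS627,19
DYS627,20
DYS627,21
DYS627,22
DYS627,23
DYS627,24
DYS635,20
DYS635,21
DYS635,22
DYS635,23
DYS635,24
DYS635,25
DYS635,26
YGATAH4,10
YGATAH4,11
YGATAH4,12
YGATAH4,13
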