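congener,tef
"2,3,7,8-TCDD",1.0
"1,2,3,7,8-PECDD",1.0
"1,2,3,4,7,8-HXCDD",0.1
"1,2,3,6,7,8-HXCDD",0.1
"1,2,3,7,8,9-HXCDD",0.1
"1,2,3,4,6,7,8-HPCDD",0.01
OCDD,0.0003
"2,3,7,8-TCDF",0.1
"1,2,3,7,8-PECDF",0.03
"2,3,4,7,8-PECDF",0.3
"1,2,3,4,7,8-HXCDF",0.1
"1,2,3,6,7,8-HXCDF",0.1
"1,2,3,7,8,9-HXCDF",0.1
"2,3,4,6,7,8-HXCDF",0.1
"1,2,3,4,6,7,8-HPCDF",0.01
"1,2,3,4,7,8,9-HPCDF",0.01
OCDF,0.0003
PCB-77,0.0001
PCB-81,0.0003
PCB-126,0.1
PCB-169,0.03
PCB-105,0.00003
PCB-114,0.00003
PCB-118,0.00003
PCB-123,0.00003
PCB-156,0.00003
PCB-157,0.00003
PCB-167,0.00003
PCB-189,0.00003
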