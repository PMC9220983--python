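item,stage,phase,age_group,value
screen,,,,149
fp_imaging,,,,152
fp_biopsy_fraction,,,,0.106
fp_biopsy,,,50-64,1455
fp_biopsy,,,65-74,1463
fp_biopsy,,,75-100,1550
tp_diagnostics,,,50-64,2316
tp_diagnostics,,,65-74,2329
tp_diagnostics,,,75-100,1964
care,in_situ,initial,,14848
care,in_situ,continuous,,1336
care,in_situ,terminal,,56995
care,in_situ,terminal_ocd,,7879
care,local,initial,,24240
care,local,continuous,,2306
care,local,terminal,,59550
care,local,terminal_ocd,,6332
care,regional,initial,,41352
care,regional,continuous,,4474
care,regional,terminal,,64516
care,regional,terminal_ocd,,10762
care,distant,initial,,55985
care,distant,continuous,,19212
care,distant,terminal,,81656
care,distant,terminal_ocd,,20081
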