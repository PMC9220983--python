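event,stage,phase,utility,duration_weeks
screening,,,0.994,1
workup,,,0.895,5
care,in_situ,initial,0.90,
care,in_situ,continuous,0.93,
care,in_situ,terminal,0.49,
care,in_situ,terminal_ocd,0.93,
care,local,initial,0.90,
care,local,continuous,0.93,
care,local,terminal,0.49,
care,local,terminal_ocd,0.93,
care,regional,initial,0.75,
care,regional,continuous,0.78,
care,regional,terminal,0.49,
care,regional,terminal_ocd,0.78,
care,distant,initial,0.60,
care,distant,continuous,0.62,
care,distant,terminal,0.49,
care,distant,terminal_ocd,0.62,
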