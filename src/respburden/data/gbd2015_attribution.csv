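stratum,env_only_pct,joint_pct,beh_only_pct,unattributed_pct
high,7.0,15.1,54.8,23.2
high_middle,23.5,20.3,27.1,29.2
middle,32.5,21.3,17.5,28.7
low_middle,37.0,26.3,12.7,24.0
low,40.4,17.8,7.9,34.0
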