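cause,stratum,deaths_thousands,prevalence_thousands,yll_thousands,yld_thousands,daly_thousands
copd,global,3188,174483,51803,12047,63850
copd,high,482,43105,5914,2214,8128
copd,high_middle,626,44923,9058,2500,11661
copd,middle,1110,52209,17918,4050,21812
copd,low_middle,907,30058,17444,2954,20399
copd,low,61,4223,1433,374,1806
asthma,global,397,358198,10270,15899,26169
asthma,high,22,63883,384,2818,3203
asthma,high_middle,54,76935,1227,3419,4766
asthma,middle,120,91375,2912,4061,6855
asthma,low_middle,159,90605,4327,4020,8350
asthma,low,41,35011,1402,1563,2961
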