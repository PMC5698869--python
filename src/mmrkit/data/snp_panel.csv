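rsid,gene,risk_allele,source
rs16973771,ATP2C2,G,dyslexia_candidate
rs2875891,ATP2C2,C,dyslexia_candidate
rs8053211,ATP2C2,T,dyslexia_candidate
rs3935802,CMIP,A,dyslexia_candidate
rs6564903,CMIP,T,dyslexia_candidate
rs7201632,CMIP,G,dyslexia_candidate
rs10246256,CNTNAP2,,dyslexia_candidate
rs759178,CNTNAP2,C,dyslexia_candidate
rs1419228,DCDC2,,dyslexia_candidate
rs7765678,DCDC2,T,dyslexia_candidate
rs793862,DCDC2,A,dyslexia_candidate
rs807701,DCDC2,C,dyslexia_candidate
rs17819126,DYX1C1,T,dyslexia_candidate
rs3743204,DYX1C1,G,dyslexia_candidate
rs3743205,DYX1C1,,dyslexia_candidate
rs685935,DYX1C1,C,dyslexia_candidate
rs12533005,FOXP2,G,dyslexia_candidate
rs2143340,KIAA0319,G,dyslexia_candidate
rs2179515,KIAA0319,A,dyslexia_candidate
rs6935076,KIAA0319,T,dyslexia_candidate
rs761100,KIAA0319,C,dyslexia_candidate
rs9461045,KIAA0319,,dyslexia_candidate
rs1000585,MRPL19-C2ORF3,,dyslexia_candidate
rs555879,MYO5B,A,dyslexia_candidate
rs12606138,NEDD4L,G,dyslexia_candidate
rs11100040,intergenic,A,mmr_candidate
rs4234898,intergenic,T,mmr_candidate
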