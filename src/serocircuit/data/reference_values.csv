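condition,treatment,variant,region,observable,mean,sem
control,none,baseline,PFC,serotonin_nM,66.35,0.35
mild,none,baseline,PFC,serotonin_nM,56.69,0.29
moderate,none,baseline,PFC,serotonin_nM,54.77,0.28
severe,none,baseline,PFC,serotonin_nM,43.48,0.22
control,none,baseline,SCC,serotonin_nM,65.21,1.32
mild,none,baseline,SCC,serotonin_nM,56.63,0.82
moderate,none,baseline,SCC,serotonin_nM,54.16,0.66
severe,none,baseline,SCC,serotonin_nM,42.25,0.40
control,none,baseline,PFC,rate_hz,4.61,0.02
mild,none,baseline,PFC,rate_hz,4.50,0.02
moderate,none,baseline,PFC,rate_hz,4.46,0.02
severe,none,baseline,PFC,rate_hz,4.29,0.02
control,none,baseline,SCC,rate_hz,3.79,0.02
mild,none,baseline,SCC,rate_hz,4.00,0.03
moderate,none,baseline,SCC,rate_hz,4.01,0.03
severe,none,baseline,SCC,rate_hz,4.16,0.02
mild,ssri,baseline,PFC,serotonin_nM,70.26,0.36
moderate,ssri,baseline,PFC,serotonin_nM,67.72,0.35
severe,ssri,baseline,PFC,serotonin_nM,53.63,0.26
mild,ssri,baseline,SCC,serotonin_nM,66.01,0.93
moderate,ssri,baseline,SCC,serotonin_nM,60.92,0.76
severe,ssri,baseline,SCC,serotonin_nM,50.80,0.55
mild,ssri,baseline,PFC,rate_hz,4.68,0.02
moderate,ssri,baseline,PFC,rate_hz,4.63,0.02
severe,ssri,baseline,PFC,rate_hz,4.46,0.02
mild,ssri,baseline,SCC,rate_hz,3.96,0.03
moderate,ssri,baseline,SCC,rate_hz,3.88,0.03
severe,ssri,baseline,SCC,rate_hz,4.21,0.03
mild,antiinflammatory,baseline,PFC,serotonin_nM,62.35,0.32
moderate,antiinflammatory,baseline,PFC,serotonin_nM,61.23,0.33
severe,antiinflammatory,baseline,PFC,serotonin_nM,56.53,0.29
mild,antiinflammatory,baseline,SCC,serotonin_nM,60.91,1.08
moderate,antiinflammatory,baseline,SCC,serotonin_nM,59.45,0.83
severe,antiinflammatory,baseline,SCC,serotonin_nM,55.24,0.77
mild,antiinflammatory,baseline,PFC,rate_hz,4.56,0.02
moderate,antiinflammatory,baseline,PFC,rate_hz,4.53,0.02
severe,antiinflammatory,baseline,PFC,rate_hz,4.49,0.02
mild,antiinflammatory,baseline,SCC,rate_hz,3.82,0.03
moderate,antiinflammatory,baseline,SCC,rate_hz,3.84,0.03
severe,antiinflammatory,baseline,SCC,rate_hz,3.94,0.03
severe,combined,baseline,PFC,serotonin_nM,70.07,0.39
severe,combined,baseline,SCC,serotonin_nM,61.06,0.77
severe,combined,baseline,PFC,rate_hz,4.68,0.02
severe,combined,baseline,SCC,rate_hz,3.80,0.02
mild,ssri,nmda_excitotoxicity,SCC,serotonin_nM,63.34,0.82
moderate,ssri,nmda_excitotoxicity,SCC,serotonin_nM,62.19,0.84
severe,ssri,nmda_excitotoxicity,SCC,serotonin_nM,50.15,0.56
mild,ssri,nmda_excitotoxicity,SCC,rate_hz,3.87,0.02
moderate,ssri,nmda_excitotoxicity,SCC,rate_hz,3.94,0.03
severe,ssri,nmda_excitotoxicity,SCC,rate_hz,4.18,0.03
mild,antiinflammatory,nmda_excitotoxicity,SCC,serotonin_nM,61.41,0.89
moderate,antiinflammatory,nmda_excitotoxicity,SCC,serotonin_nM,61.63,1.02
severe,antiinflammatory,nmda_excitotoxicity,SCC,serotonin_nM,55.02,0.77
mild,antiinflammatory,nmda_excitotoxicity,SCC,rate_hz,3.87,0.03
moderate,antiinflammatory,nmda_excitotoxicity,SCC,rate_hz,3.90,0.03
severe,antiinflammatory,nmda_excitotoxicity,SCC,rate_hz,3.97,0.03
mild,combined,nmda_excitotoxicity,SCC,serotonin_nM,74.84,1.28
moderate,combined,nmda_excitotoxicity,SCC,serotonin_nM,69.46,0.94
severe,combined,nmda_excitotoxicity,SCC,serotonin_nM,63.55,0.86
mild,combined,nmda_excitotoxicity,SCC,rate_hz,3.91,0.03
moderate,combined,nmda_excitotoxicity,SCC,rate_hz,3.82,0.03
severe,combined,nmda_excitotoxicity,SCC,rate_hz,3.91,0.02
mild,none,receptor_reduction,SCC,serotonin_nM,66.64,0.96
moderate,none,receptor_reduction,SCC,serotonin_nM,62.18,0.81
severe,none,receptor_reduction,SCC,serotonin_nM,49.16,0.48
mild,none,receptor_reduction,SCC,rate_hz,4.40,0.03
moderate,none,receptor_reduction,SCC,rate_hz,4.38,0.02
severe,none,receptor_reduction,SCC,rate_hz,4.66,0.03
mild,ssri,receptor_reduction,SCC,serotonin_nM,76.11,1.13
moderate,ssri,receptor_reduction,SCC,serotonin_nM,73.35,1.02
severe,ssri,receptor_reduction,SCC,serotonin_nM,55.37,0.60
mild,ssri,receptor_reduction,SCC,rate_hz,4.39,0.03
moderate,ssri,receptor_reduction,SCC,rate_hz,4.36,0.03
severe,ssri,receptor_reduction,SCC,rate_hz,4.50,0.03
mild,antiinflammatory,receptor_reduction,SCC,serotonin_nM,72.61,1.28
moderate,antiinflammatory,receptor_reduction,SCC,serotonin_nM,68.88,1.10
mild,antiinflammatory,receptor_reduction,SCC,rate_hz,4.27,0.03
moderate,antiinflammatory,receptor_reduction,SCC,rate_hz,4.24,0.03
severe,antiinflammatory,receptor_reduction,SCC,rate_hz,4.35,0.03
mild,combined,receptor_reduction,SCC,serotonin_nM,80.49,1.30
moderate,combined,receptor_reduction,SCC,serotonin_nM,78.27,1.24
severe,combined,receptor_reduction,SCC,serotonin_nM,71.53,1.06
mild,combined,receptor_reduction,SCC,rate_hz,4.11,0.03
moderate,combined,receptor_reduction,SCC,rate_hz,4.12,0.03
severe,combined,receptor_reduction,SCC,rate_hz,4.21,0.03
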