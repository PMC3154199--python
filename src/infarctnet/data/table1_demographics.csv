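Pt,Age/Gender,Stroke Location,Ischemic Stroke Subtype,Onset-Acute MRI (hours),Onset-Outcome MRI (days)
1,42/M,Left frontal,Large vessel atherosclerosis,11.8,90
2,68/M,Left basal ganglia-internal capsule,Small vessel disease,9.3,95
3,42/M,Left corona radiata - internal capsule,Small vessel disease,10.6,103
4,59/M,Left corona radiata-thalamus,Cryptogenic,13.4,93
5,45/M,Right frontal-parietal-temporal,Cardioembolism,8.2,93
6,59/F,Left internal capsule-thalamus,Small vessel disease,8.2,104
7,68/M,Right frontal-parietal,Large vessel atherosclerosis,10.9,82
8,45/M,Right parietal,Cryptogenic,10.1,102
9,64/F,Left frontal-parietal,Cryptogenic,18.4,130
10,71/F,Right frontal-parietal,Large vessel atherosclerosis,5.4,39
11,67/F,Right frontal-parietal,Cardioembolism,20.7,124
12,45/M,Right occipital-temporal,Cryptogenic,8.9,94
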