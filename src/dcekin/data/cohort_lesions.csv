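patient_id,lesion_id,organ,progression
P01,0,nodal,no
P02,0,spleen,no
P02,1,stomach,no
P03,0,nodal,no
P04,0,liver,yes
P04,1,liver,yes
P05,0,nodal,yes
P06,0,kidney,no
P07,0,kidney,no
P08,0,kidney,no
P09,0,kidney,no
P10,0,renal_bed,no
P10,1,nodal,no
P11,0,nodal,no
P11,1,nodal,no
P12,0,kidney,no
P12,1,kidney,no
P12,2,liver,no
P12,3,pancreas,no
P12,4,pancreas,no
P13,0,kidney,yes
P13,1,pancreas,yes
P14,0,kidney,no
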