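name	value
total_lead_snps	398
unique_lead_snps	312
single_pair_lead_snps	244
multi_pair_lead_snps	68
immune_nearest_genes	32
immport_flagged	16
enrichr_flagged	20
dual_flagged	4
cancer_cases	240540
cancer_controls	317000
autoimmune_cases	112631
autoimmune_controls	895386
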