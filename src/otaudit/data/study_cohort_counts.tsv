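sample	group	relationship	quality_snvs_gatk	quality_indels_gatk	quality_snvs_bcftools	quality_indels_bcftools	candidate_snvs_gatk	candidate_indels_gatk	candidate_snvs_bcftools	candidate_indels_bcftools	final_snvs	final_indels
M01	edited_strain_A	founder	129169	113307	130516	117545	325	165	647	301	141	21
M02	edited_strain_A	offspring	128666	116517	126096	123203	203	100	464	231	37	1
M03	edited_strain_A	offspring	130771	114722	127508	120029	189	91	464	229	28	3
P01	edited_strain_B	founder	130152	115350	135322	116818	312	158	708	312	155	12
P02	edited_strain_B	offspring	128514	110186	126265	111366	219	105	392	221	46	5
P03	edited_strain_B	offspring	129970	102837	126670	94039	197	80	399	162	45	4
WT1	control	none	130319	109723	134782	110693	526	351	1447	439	200	23
WT2	control	none	128871	109005	124798	109253	366	225	935	320	168	11
WT3	control	none	130665	112541	131262	111405	402	311	1064	385	188	18
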