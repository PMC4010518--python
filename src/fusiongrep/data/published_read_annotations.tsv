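read_id	category	kat6a_span	crebbp_span
read01	WILDTYPE		238-338 (exon 1-2)
read02	WILDTYPE		272-372 (exon 1-2)
read03	FUSION	3732-3764 (exon 16)	290-357 (exon 2)
read04	WILDTYPE		215-315 (exon 1-2)
read05	FUSION	3756-3764 (exon 16)	290-357 (exon 2)
read06	FUSION	3748-3764 (exon 16)	290-373 (exon 2)
read07	FUSION	3744-3764 (exon 16)	290-369 (exon 2)
read08	FUSION	3745-3764 (exon 16)	290-370 (exon 2)
read09	WILDTYPE		212-312 (exon 1-2)
read10	WILDTYPE		280-380 (exon 1-2)
read11	WILDTYPE		251-351 (exon 1-2)
read12	WILDTYPE		220-320 (exon 1-2)
read13	WILDTYPE		246-341 (exon 1-2)
read14	FUSION	3737-3764 (exon 16)	290-350 (exon 2)
read15	WILDTYPE		247-347 (exon 1-2)
read16	FUSION	3692-3764 (exon 16)	290-317 (exon 2)
read17	WILDTYPE		216-316 (exon 1-2)
read18	WILDTYPE		242-342 (exon 1-2)
read19	FUSION	3701-3764 (exon 16)	290-326 (exon 2)
read20	WILDTYPE		247-347 (exon 1-2)
read21	WILDTYPE		241-341 (exon 1-2)
read22	WILDTYPE		247-343 (exon 1-2)
read23	FUSION	3686-3764 (exon 16)	290-311 (exon 2)
read24	FUSION	3753-3764 (exon 16)	290-359 (exon 2)
read25	OTHER		290-344 (exon 2)
read26	FUSION	3752-3764 (exon 16)	290-377 (exon 2)
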