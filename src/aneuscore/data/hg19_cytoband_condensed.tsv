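# Condensed hg19 cytoBand-style table: one p and one q band per chromosome,
# with the p/q boundary at the UCSC hg19 acen transition. Same column layout
# as UCSC cytoBand.txt (chrom, chromStart, chromEnd, name, gieStain).
chr1	0	125000000	p10	gneg
chr1	125000000	249250621	q10	gneg
chr2	0	93300000	p10	gneg
chr2	93300000	243199373	q10	gneg
chr3	0	91000000	p10	gneg
chr3	91000000	198022430	q10	gneg
chr4	0	50400000	p10	gneg
chr4	50400000	191154276	q10	gneg
chr5	0	48400000	p10	gneg
chr5	48400000	180915260	q10	gneg
chr6	0	61000000	p10	gneg
chr6	61000000	171115067	q10	gneg
chr7	0	59900000	p10	gneg
chr7	59900000	159138663	q10	gneg
chr8	0	45600000	p10	gneg
chr8	45600000	146364022	q10	gneg
chr9	0	49000000	p10	gneg
chr9	49000000	141213431	q10	gneg
chr10	0	40200000	p10	gneg
chr10	40200000	135534747	q10	gneg
chr11	0	53700000	p10	gneg
chr11	53700000	135006516	q10	gneg
chr12	0	35800000	p10	gneg
chr12	35800000	133851895	q10	gneg
chr13	0	17900000	p10	gneg
chr13	17900000	115169878	q10	gneg
chr14	0	17600000	p10	gneg
chr14	17600000	107349540	q10	gneg
chr15	0	19000000	p10	gneg
chr15	19000000	102531392	q10	gneg
chr16	0	36600000	p10	gneg
chr16	36600000	90354753	q10	gneg
chr17	0	24000000	p10	gneg
chr17	24000000	81195210	q10	gneg
chr18	0	17200000	p10	gneg
chr18	17200000	78077248	q10	gneg
chr19	0	26500000	p10	gneg
chr19	26500000	59128983	q10	gneg
chr20	0	27500000	p10	gneg
chr20	27500000	63025520	q10	gneg
chr21	0	13200000	p10	gneg
chr21	13200000	48129895	q10	gneg
chr22	0	14700000	p10	gneg
chr22	14700000	51304566	q10	gneg
chrX	0	60600000	p10	gneg
chrX	60600000	155270560	q10	gneg
chrY	0	12500000	p10	gneg
chrY	12500000	59373566	q10	gneg
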