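##fileformat=VCFv4.2
##contig=<ID=s1,length=100000>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	A	B	C	D	E	F	G	H
s1	100	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	200	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50
s1	300	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	400	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	500	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95
s1	600	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50
s1	700	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	800	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:10	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	900	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	1/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	1000	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	1100	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/0:5:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	1200	.	A	C	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/0:30:50	0/0:30:.	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	1300	.	A	C	1000	.	MQ=60;QD=1.0;FS=1.5;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	1400	.	A	C	1000	.	MQ=60;QD=25;FS=70.0;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
s1	1500	.	A	ACC	1000	.	MQ=60;QD=25;FS=1.5;MQRankSum=0;ReadPosRankSum=-25	GT:DP:GQ	0/1:30:95	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50	0/0:30:50
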