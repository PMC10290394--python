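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
##FORMAT=<ID=RGQ,Number=1,Type=Integer,Description="Genotype quality at reference sites">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	A	B	C
s1	100	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/1:30:95:.	0/0:30:.:80
s1	200	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/0:30:.:80	0/0:30:.:80
s1	300	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	1/1:30:95:.	0/1:30:95:.	0/0:30:.:80
s1	400	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/1:30:95:.	0/1:30:95:.
s1	500	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	1/1:30:95:.	1/1:30:95:.	1/1:30:95:.
s1	600	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	./.:0:.:.	0/0:30:.:80
s1	700	.	A	C,G	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	1/2:30:95:.	0/1:30:95:.	0/0:30:.:80
s1	800	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:3:50:.	0/0:30:.:80	0/0:30:.:80
s1	900	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:10:0:.	0/0:30:.:80	0/0:30:.:80
s1	1000	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/0:30:.:80	0/0:4:.:50
s1	1100	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:150:95:.	0/0:30:.:80	0/0:30:.:80
s1	1200	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/0:200:.:80	0/0:30:.:80
s1	1300	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/0:30:.:80	0/0:30:.:80
s1	1400	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	1/1:30:95:.	0/1:30:95:.	0/0:30:.:80
s1	1500	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/0:30:.:80	0/0:30:.:80	0/0:30:.:80
s1	1600	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/0:30:.:80	0/0:30:.:80	0/0:30:.:80
s1	1700	.	A	C	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/0:30:.:80	0/0:30:.:80	0/0:30:.:80
s1	1800	.	A	C	1000	.	MQ=59;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/0:30:.:80	0/0:30:.:80
s1	1900	.	A	C	1000	.	QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/0:30:.:80	0/0:30:.:80
s1	2000	.	A	AC	1000	.	MQ=60;QD=25;FS=1;MQRankSum=0;ReadPosRankSum=0	GT:DP:GQ:RGQ	0/1:30:95:.	0/0:30:.:80	0/0:30:.:80
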