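event_id	coordinates	length	dm1_direction
MBNL1	chr3:152446704-152446757	54	increased
ADD1	chr4:2926642-2926675	34	increased
TACC2	chr10:122245065-122245073	9	increased
MBNL2a	chr13:97356796-97356849	54	increased
MBNL2b	chr13:97366459-97366553	95	increased
MBNL2c	chr13:97366459-97366553	95	increased
TCF3	chr19:1615285-1615485	201	increased
PLA2G6	chr22:38128269-38128430	162	increased
SOS1	chr2:38989270-38989314	45	decreased
ATP1B3	chr3:141902136-141902227	92	decreased
LRRFIP2	chr3:37091467-37091538	72	decreased
PALLD	chr4:168925233-168925278	46	decreased
PACRGL	chr4:20702141-20702221	81	decreased
SEPT11	chr4:77036773-77036837	65	decreased
GABRG2	chr5:162151730-162151753	24	decreased
NRCAM	chr7:108166921-108167073	153	decreased
GOLGA2	chr9:128272785-128272865	81	decreased
SORBS1a	chr10:95351209-95351376	168	decreased
SORBS1b	chr10:95351216-95351376	161	decreased
SORBS1c	chr10:95375973-95376056	84	decreased
NUMA1	chr11:72012401-72012442	42	decreased
CAMKK2	chr12:121244573-121244615	43	decreased
DNM1L	chr12:32705825-32705863	39	decreased
PPHLN1	chr12:42384940-42384996	57	decreased
DCLK1	chr13:35788212-35788285	74	decreased
PACS2	chr14:105385685-105385717	33	decreased
TJP1	chr15:29719777-29720016	240	decreased
KIFC3	chr16:57759125-57759153	29	decreased
MTSS1L	chr16:70679315-70679323	9	decreased
ARHGAP44	chr17:12973302-12973319	18	decreased
MAPT	chr17:45971859-45971945	87	decreased
CSNK1D	chr17:82245976-82246039	64	decreased
DLGAP1	chr18:3656084-3656113	30	decreased
DMD	chrX:31126642-31126673	32	decreased
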