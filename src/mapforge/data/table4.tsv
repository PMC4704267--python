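# assembly_total_mb=949.2
chromosome	het_start_mb	het_end_mb	length_mb
Chr01	8.1	47.4	56.8
Chr02	16.0	38.2	48.6
Chr03	6.9	33.4	45.8
Chr04	10.4	43.5	52.4
Chr05	6.4	30.2	42.2
Chr06	18.2	44.4	51.4
Chr07	17.7	34.6	44.6
Chr08	22.9	40.4	47.8
Chr09	6.4	38.8	50.2
Chr10	6.9	36.9	51.5
Chr11	11.4	30.0	34.7
Chr12	8.2	32.4	40.0
Chr13	0	13.3	45.8
Chr14	9.7	43.7	49.0
Chr15	18.3	43.0	51.7
Chr16	8.3	26.8	37.8
Chr17	14.3	35.8	41.6
Chr18	20.5	43.3	58.0
Chr19	8.9	34.3	50.7
Chr20	3.2	33.7	47.9
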