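seq_id	Rome-Italy 1	Assisi-Italy 1	Assisi-Italy 2 (1)	Assisi-Italy 2 (2)	Assisi-Italy 3	Czechia 3	France	Madagascar 2	RHBTV	RSV	MSTV
Rome-Italy 1	0.0	7.5	7.5	7.5	7.5	23.1	23.1	23.0	56.3	56.7	55.1
Assisi-Italy 1	7.5	0.0	0.0	0.0	0.0	20.6	22.6	22.6	56.3	56.5	55.4
Assisi-Italy 2 (1)	7.5	0.0	0.0	0.0	0.0	22.6	22.6	22.6	56.3	56.5	55.4
Assisi-Italy 2 (2)	7.5	0.0	0.0	0.0	0.0	21.3	20.6	21.3	54.9	54.9	54.4
Assisi-Italy 3	7.5	0.0	0.0	0.0	0.0	22.6	22.6	22.6	56.2	56.5	55.4
Czechia 3	23.1	20.6	22.6	21.3	22.6	0.0	0.0	1.7	56.2	56.7	55.4
France	23.1	22.6	22.6	20.6	22.6	0.0	0.0	1.7	55.3	56.1	54.8
Madagascar 2	23.0	22.6	22.6	21.3	22.6	1.7	1.7	0.0	56.0	56.8	55.4
RHBTV	56.3	56.3	56.3	54.9	56.2	56.2	55.3	56.0	0.0	39.5	39.3
RSV	56.7	56.5	56.5	54.9	56.5	56.7	56.1	56.8	39.5	0.0	30.7
MSTV	55.1	55.4	55.4	54.4	55.4	55.4	54.8	55.4	39.3	30.7	0.0
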