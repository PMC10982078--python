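seq_id	group
Rome-Italy 1	Italy
Assisi-Italy 1	Italy
Assisi-Italy 2 (1)	Italy
Assisi-Italy 2 (2)	Italy
Assisi-Italy 3	Italy
Czechia 3	Rest of the World
France	Rest of the World
Madagascar 2	Rest of the World
RHBTV	Outgroup
RSV	Outgroup
MSTV	Outgroup
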