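sample	pct_virus	pct_wolbachia
Czechia 1	0.02	0.74
Czechia 2	3.88	0.35
Czechia 3	0.09	1.39
Harlan Strain-USA 1	0.00	0.40
Harlan Strain-USA 2	2.18	0.30
Harlan Strain-USA 3	0.00	0.19
France	0.34	0.43
Rome-Italy 1	0.01	0.76
Rome-Italy 2	0.00	0.41
Rome-Italy 3	0.00	0.34
Assisi-Italy 1	0.01	0.27
Assisi-Italy 2	0.09	0.75
Assisi-Italy 3	0.02	0.23
Madagascar 1	0.03	1.25
Madagascar 2	0.03	0.87
Madagascar 3	0.08	3.26
Ohio-USA 1	0.00	14.90
Ohio-USA 2	0.00	3.35
Ohio-USA 3	0.00	1.64
United Kingdom 1	0.37	3.09
United Kingdom 2	0.31	1.08
United Kingdom 3	0.13	0.99
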