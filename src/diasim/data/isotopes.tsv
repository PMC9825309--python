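# Stable-isotope masses (Da) and natural abundances (mole fraction).
# Values from the IUPAC Commission on Isotopic Abundances and Atomic Weights
# (CIAAW 2021 standard atomic weights / AME2020 atomic masses), rounded to
# the precision shown.
# columns: element	nucleons	mass	abundance
H	1	1.0078250319	0.999885
H	2	2.0141017779	0.000115
C	12	12.0000000000	0.9893
C	13	13.0033548380	0.0107
N	14	14.0030740052	0.99636
N	15	15.0001088984	0.00364
O	16	15.9949146221	0.99757
O	17	16.9991315650	0.00038
O	18	17.9991604000	0.00205
P	31	30.9737615120	1.0
S	32	31.9720706900	0.9499
S	33	32.9714585000	0.0075
S	34	33.9678668300	0.0425
S	36	35.9670809000	0.0001
Na	23	22.9897696700	1.0
K	39	38.9637069000	0.932581
K	40	39.9639986700	0.000117
K	41	40.9618259700	0.067302
Cl	35	34.9688527100	0.7576
Cl	37	36.9659026000	0.2424
Se	74	73.9224766000	0.0089
Se	76	75.9192141000	0.0937
Se	77	76.9199146000	0.0763
Se	78	77.9173095000	0.2377
Se	80	79.9165218000	0.4961
Se	82	81.9166995000	0.0873
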