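# Standard atomic isotope table: symbol, exact mass (Da), natural abundance (fraction)
# Values from the CODATA/IUPAC standard compilations of isotopic masses and abundances.
H	1.00782503207	0.999885
H	2.01410177785	0.000115
He	3.01602931914	0.00000134
He	4.00260325415	0.99999866
Li	6.015122795	0.0759
Li	7.01600455	0.9241
B	10.0129370	0.199
B	11.0093054	0.801
C	12.0000000	0.9893
C	13.0033548378	0.0107
N	14.0030740048	0.99636
N	15.0001088982	0.00364
O	15.99491461956	0.99757
O	16.99913170	0.00038
O	17.99916100	0.00205
F	18.99840322	1.0
Ne	19.9924401754	0.9048
Ne	20.99384668	0.0027
Ne	21.991385114	0.0925
Na	22.9897692809	1.0
Mg	23.9850417000	0.7899
Mg	24.98583692	0.1000
Mg	25.982592929	0.1101
Al	26.98153863	1.0
Si	27.9769265325	0.92223
Si	28.9764947000	0.04685
Si	29.97377017	0.03092
P	30.97376163	1.0
S	31.97207100	0.9499
S	32.97145876	0.0075
S	33.96786690	0.0425
S	35.96708076	0.0001
Cl	34.96885268	0.7576
Cl	36.96590259	0.2424
Ar	35.967545106	0.003365
Ar	37.9627324	0.000632
Ar	39.9623831225	0.996003
K	38.96370668	0.932581
K	39.96399848	0.000117
K	40.96182576	0.067302
Ca	39.96259098	0.96941
Ca	41.95861801	0.00647
Ca	42.95876660	0.00135
Ca	43.95548180	0.02086
Ca	45.95369260	0.00004
Ca	47.95253400	0.00187
Fe	53.9396105	0.05845
Fe	55.9349375	0.91754
Fe	56.9353940	0.02119
Fe	57.9332756	0.00282
Cu	62.9295975	0.6915
Cu	64.9277895	0.3085
Kr	77.9203648	0.00355
Kr	79.9163790	0.02286
Kr	81.9134836	0.11593
Kr	82.9141360	0.11500
Kr	83.9115070	0.56987
Kr	85.91061073	0.17279
Xe	123.9058930	0.000952
Xe	125.9042740	0.000890
Xe	127.9035313	0.019102
Xe	128.9047794	0.264006
Xe	129.9035080	0.040710
Xe	130.9050824	0.212324
Xe	131.9041535	0.269086
Xe	133.9053945	0.104357
Xe	135.9072190	0.088573
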