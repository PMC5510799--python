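# Most-abundant-isotope exact masses, Da.
# Source values: AME2020 atomic mass evaluation, rounded to 1e-7 Da.
# version: 2020.1
H	1.0078250
He	4.0026032
Li	7.0160034
Be	9.0121831
B	11.0093054
C	12.0000000
N	14.0030740
O	15.9949146
F	18.9984032
Ne	19.9924402
Na	22.9897693
Mg	23.9850417
Al	26.9815385
Si	27.9769265
P	30.9737615
S	31.9720707
Cl	34.9688527
Ar	39.9623831
K	38.9637065
Ca	39.9625909
Sc	44.9559083
Ti	47.9479420
V	50.9439570
Cr	51.9405062
Mn	54.9380439
Fe	55.9349363
Co	58.9331943
Ni	57.9353424
Cu	62.9295977
Zn	63.9291420
Ga	68.9255735
Ge	73.9211778
As	74.9215946
Se	79.9165218
Br	78.9183376
Kr	83.9114977
Rb	84.9117897
Sr	87.9056125
Y	88.9058403
Zr	89.9046977
Nb	92.9063730
Mo	97.9054048
Ru	101.9043441
Rh	102.9054980
Pd	105.9034804
Ag	106.9050916
Cd	113.9033651
In	114.9038788
Sn	119.9022016
Sb	120.9038120
Te	129.9062227
I	126.9044719
Xe	131.9041551
Cs	132.9054520
Ba	137.9052470
La	138.9063563
Ce	139.9054431
W	183.9509309
Re	186.9557501
Os	191.9614770
Ir	192.9629216
Pt	194.9647917
Au	196.9665688
Hg	201.9706434
Tl	204.9744278
Pb	207.9766525
Bi	208.9803991
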