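array	code
AAAA	0
AAAB	1
AAAC	2
AAAD	3
AABA	4
AABB	5
AABC	6
AABD	7
AACA	8
AACB	9
AACC	10
AACD	11
AADA	12
AADB	13
AADC	14
AADD	15
ABAA	16
ABAB	17
ABAC	18
ABAD	19
ABBA	20
ABBB	21
ABBC	22
ABBD	23
ABCA	24
ABCB	25
ABCC	26
ABCD	27
ABDA	28
ABDB	29
ABDC	30
ABDD	31
ACAA	32
ACAB	33
ACAC	34
ACAD	35
ACBA	36
ACBB	37
ACBC	38
ACBD	39
ACCA	40
ACCB	41
ACCC	42
ACCD	43
ACDA	44
ACDB	45
ACDC	46
ACDD	47
ADAA	48
ADAB	49
ADAC	50
ADAD	51
ADBA	52
ADBB	53
ADBC	54
ADBD	55
ADCA	56
ADCB	57
ADCC	58
ADCD	59
ADDA	60
ADDB	61
ADDC	62
ADDD	63
BAAA	64
BAAB	65
BAAC	66
BAAD	67
BABA	68
BABB	69
BABC	70
BABD	71
BACA	72
BACB	73
BACC	74
BACD	75
BADA	76
BADB	77
BADC	78
BADD	79
BBAA	80
BBAB	81
BBAC	82
BBAD	83
BBBA	84
BBBB	85
BBBC	86
BBBD	87
BBCA	88
BBCB	89
BBCC	90
BBCD	91
BBDA	92
BBDB	93
BBDC	94
BBDD	95
BCAA	96
BCAB	97
BCAC	98
BCAD	99
BCBA	100
BCBB	101
BCBC	102
BCBD	103
BCCA	104
BCCB	105
BCCC	106
BCCD	107
BCDA	108
BCDB	109
BCDC	110
BCDD	111
BDAA	112
BDAB	113
BDAC	114
BDAD	115
BDBA	116
BDBB	117
BDBC	118
BDBD	119
BDCA	120
BDCB	121
BDCC	122
BDCD	123
BDDA	124
BDDB	125
BDDC	126
BDDD	127
CAAA	128
CAAB	129
CAAC	130
CAAD	131
CABA	132
CABB	133
CABC	134
CABD	135
CACA	136
CACB	137
CACC	138
CACD	139
CADA	140
CADB	141
CADC	142
CADD	143
CBAA	144
CBAB	145
CBAC	146
CBAD	147
CBBA	148
CBBB	149
CBBC	150
CBBD	151
CBCA	152
CBCB	153
CBCC	154
CBCD	155
CBDA	156
CBDB	157
CBDC	158
CBDD	159
CCAA	160
CCAB	161
CCAC	162
CCAD	163
CCBA	164
CCBB	165
CCBC	166
CCBD	167
CCCA	168
CCCB	169
CCCC	170
CCCD	171
CCDA	172
CCDB	173
CCDC	174
CCDD	175
CDAA	176
CDAB	177
CDAC	178
CDAD	179
CDBA	180
CDBB	181
CDBC	182
CDBD	183
CDCA	184
CDCB	185
CDCC	186
CDCD	187
CDDA	188
CDDB	189
CDDC	190
CDDD	191
DAAA	192
DAAB	193
DAAC	194
DAAD	195
DABA	196
DABB	197
DABC	198
DABD	199
DACA	200
DACB	201
DACC	202
DACD	203
DADA	204
DADB	205
DADC	206
DADD	207
DBAA	208
DBAB	209
DBAC	210
DBAD	211
DBBA	212
DBBB	213
DBBC	214
DBBD	215
DBCA	216
DBCB	217
DBCC	218
DBCD	219
DBDA	220
DBDB	221
DBDC	222
DBDD	223
DCAA	224
DCAB	225
DCAC	226
DCAD	227
DCBA	228
DCBB	229
DCBC	230
DCBD	231
DCCA	232
DCCB	233
DCCC	234
DCCD	235
DCDA	236
DCDB	237
DCDC	238
DCDD	239
DDAA	240
DDAB	241
DDAC	242
DDAD	243
DDBA	244
DDBB	245
DDBC	246
DDBD	247
DDCA	248
DDCB	249
DDCC	250
DDCD	251
DDDA	252
DDDB	253
DDDC	254
DDDD	255
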