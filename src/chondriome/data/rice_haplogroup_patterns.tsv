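accession	CW_02	CW_19	LD_12	LD_24	LD_29	LD_30	CW-orf307	atp6-orf79	orf288
A	-	-	-	-	-	-	-	-	+
B	-	-	-	-	-	-	-	-	-
C	-	+	-	-	-	-	-	-	-
D	-	-	+	-	+	+	-	+	-
E	-	-	-	-	+	+	-	-	-
F	-	+	-	-	-	-	-	-	+
G	-	-	-	-	-	+	-	-	+
H	-	-	+	-	-	+	-	+	-
I	-	-	-	-	+	+	-	-	+
J	-	-	+	-	+	-	-	+	-
K	-	+	-	-	+	+	-	-	+
L	-	-	-	-	+	+	-	+	-
CW	+	+	-	-	-	-	+	-	-
LD	-	-	+	+	+	+	-	+	+
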