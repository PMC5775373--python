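allele	epitope
A*03:01	A3/11
A*11:01	A3/11
A3	A3/11
A11	A3/11
A*23:01	Bw4
A*24:02	Bw4
A*25:01	Bw4
A*32:01	Bw4
B*13:02	Bw4
B*27:05	Bw4
B*37:01	Bw4
B*38:01	Bw4
B*44:02	Bw4
B*44:03	Bw4
B*49:01	Bw4
B*51:01	Bw4
B*52:01	Bw4
B*53:01	Bw4
B*57:01	Bw4
B*58:01	Bw4
B27	Bw4
B57	Bw4
B58	Bw4
B*46:01	C1
B*73:01	C1
C*01:02	C1
C*03:02	C1
C*03:03	C1
C*03:04	C1
C*07:01	C1
C*07:02	C1
C*07:04	C1
C*08:01	C1
C*08:02	C1
C*12:02	C1
C*12:03	C1
C*14:02	C1
C*16:01	C1
Cw1	C1
Cw3	C1
Cw7	C1
Cw8	C1
C*02:02	C2
C*04:01	C2
C*05:01	C2
C*06:02	C2
C*15:02	C2
C*17:01	C2
C*18:01	C2
Cw2	C2
Cw4	C2
Cw5	C2
Cw6	C2
A*01:01	none
A*02:01	none
A*26:01	none
A*29:02	none
A*68:01	none
B*07:02	none
B*08:01	none
B*14:02	none
B*15:01	none
B*18:01	none
B*35:01	none
B*40:01	none
B*40:02	none
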