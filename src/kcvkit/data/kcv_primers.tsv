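name	sequence	orientation	position
Kcv6_Frw	CTTTAGYYTTYYTCKGVC	forward	-366
Kcv7_Frw	CTTTAGYYTTYYTCKGVCG	forward	-366
Kcv8_Frw	GAAGCAGGYACCACTTTAG	forward	-379
Kcv9_Frw	GCAGGYACCACTTTAG	forward	-376
Kcv6_Rvs	CRCRGMATRTRTCATTTGWCCC	reverse	256
Kcv7_Rvs	CTTACRCRGMATRTRTCATTTG	reverse	259
Kcv8_Rvs	CTTACRCRGMATRTRTC	reverse	264
Kcv9_Rvs	HKBYMCGATCTTATACAC	reverse	292
Kcv10_Rvs	CATTTCTTACRCRGMATRTRTC	reverse	264
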