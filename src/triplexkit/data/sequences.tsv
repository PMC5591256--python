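name	kind	length_nt	notation
ON1	oligo	15	5′-ccttttcttttttct-3′
ON2	oligo	15	5′-CcTtTtCtTtTtTcT-3′
ON2-Cy3	oligo	15	5′-Cy3-cCtTtTcTtTtTtCt-3′
ON2-5′DNA	oligo	15	5′-cCtTtTcTtTtTtCt-3′
ON2-3′LNA⦁reduced	oligo	15	5′-CcTtTtCtTttttct-3′
ON2-5′LNA⦁reduced	oligo	15	5′-ccttttCtTtTtTcT-3′
ON2-5′-penultimate-TINA	oligo	15	5′-C**P**cTtTtCtTtTtTcT-3′
ON2-center-TINA	oligo	15	5′-CcTtTtC**P**tTtTtTcT-3′
ON2-3′-penultimate-TINA	oligo	15	5′-CcTtTtCtTtTtTc**P**T-3′
ON3	oligo	13	5′-CtTtTcTtTtTtC-3′
ON3-3′LNA⦁reduced	oligo	13	5′-CtTtTcTtTtttc-3′
ON3-5′LNA⦁reduced	oligo	13	5′-ctttTcTtTtTtC-3′
ON3-3′LNA⦁reduced-c>t	oligo	13	5′-TtTtTcTtTtttt-3′
ON3-5′LNA⦁reduced-c>t	oligo	13	5′-ttttTcTtTtTtT-3′
ON3-5′-penultimate-TINA	oligo	13	5′-C**P**tTtTcTtTtTtC-3′
ON3-3′-penultimate-TINA	oligo	13	5′-CtTtTcTtTtTt**P**C-3′
ON3-5′-ultimate-TINA	oligo	13	5′-**P**CtTtTcTtTtTtC-3′
ON3-3′-ultimate-TINA	oligo	13	5′-CtTtTcTtTtTtC**P**-3′
ON3-5′-3′-TINA	oligo	13	5′-**P**CtTtTcTtTtTtCP-3′
ON4-3′LNA⦁reduced	oligo	15	5′-CtTcTtCtTcttctt-3′
ON4-5′LNA⦁reduced	oligo	15	5′-cttcttCtTcTtCtT-3′
WC29	oligo	29	5′-Cy5-tCtTtTtTcTtTtCcCccAcgCccTctGc-3′
bisLNA49	oligo	49	5′-Cy3-CcTtTtCtTtTtTcT-tctct-tCtTtTtTcTtTtCcCccAcgCccTctGc-3′
c-MYC_DS45	duplex	45	5′-agcagagggcgtggg**ggaaaagaaaaaaga**tccaccggtcgccac-3′/3′-tcgtctcccgcaccc**ccttttcttttttct**aggtggccagcggtg-5′
c-MYC_DS29Hetero	duplex	29	5′-gcagagggcgtggg**ggaaaagaaaaaaga**-3′/3′-cGtcTccCgcAccC**cCtTtTcTtTtTtCt**-Cy5-5′
c-MYC_DS19	duplex	19	5′-gg**ggaaaagaaaaaaga**tc-3′/3′-cc**ccttttcttttttct**ag-5′
FXN_DS19	duplex	19	5′-gg**gaagaagaagaagaa**tc-3′/3′-cc**cttcttcttcttctt**ag-5′
c-MYC_DS19Hetero	duplex	19	5′-gg**ggaaaagaaaaaaga**tc-3′/3′-cC**cCtTtTcTtTtTtCt**Ag-5′
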