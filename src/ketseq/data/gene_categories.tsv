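# Editable annotation of pharmacology-relevant gene categories used for the consensus
# category panels. A gene may carry multiple categories (one row each).
gene	category
Il6r	receptor
Fkbp5	receptor
Mc4r	receptor
Oxtr	receptor
Sstr3	receptor
Ret	receptor
Hsp90ab1	heat_shock
Hsp90aa1	heat_shock
Hspa8	heat_shock
Hspb1	heat_shock
Hsph1	heat_shock
Cacng3	ion_channel
Kcnv1	ion_channel
Kcnq2	ion_channel
C1qa	complement
C1qb	complement
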