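>L1Hs_3prime_synthetic 400-bp synthetic stand-in for the L1Hs 3'-end consensus; primer28 at 300, diagnostic G at 380 (0-based)
TCGTGTTTACCAATTTCGCTATTTTTGGTACGCTAAATAACGTATTCAGGAATGTATAAA
TGGGGCTACAATGTGGTGGGGCGCGCTGATTCTTCATTCATGAAAGGGCCGGGGTTCTAT
GCTGTCGGATAAATCAAGACAGACCTCACCGACGCTCTCCGGTTCCGTATCAATAAGTCG
CTTCTACGTGCTTTCTAAATTCGATAGTTGGCATATCAAGCACTTCCTGGTGGCTTCTAC
GATATCTCTGCGTTCATAAGAAGAATTCCAGAGACTCTGACGCACTGCCCCGTAGAATGG
GGGAGATATACCTAATGCTAGATGACACGAATCTTGTACAAACAGTGAATCATTGAAGTA
TATGCTTAATTTAGCGATAAGTCACCGGCGGCATCATAAT
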