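@read_000000
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTAACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000001
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTTGAAAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000002
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTTAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000003
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTCAACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000004
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTTGAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000005
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTAACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000006
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000007
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTAACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000008
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTCAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000009
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000010
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTAACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000011
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTTAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000012
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTCAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000013
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000014
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTCAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000015
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTAAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000016
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTTAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000017
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000018
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000019
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTCAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000020
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTCAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000021
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000022
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTCAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000023
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000024
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTACAACAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000025
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000026
GACGTGTGCTCTTCCGATCTTTTTTTTTTTTTTTTTTTTTTTTTTTTAGAGACCGCGCAAGAGCACGCGGACCCACCGACGGAGACTGTCTCTTATACACATCT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000027
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGTTGAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000028
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGAAAAAAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@read_000029
AGATGTGTATAAGAGACAGTCTCCGTCGGTGGGTCCGCGTGCTCTTGCGCGGTCTCTGAAAAAAAAAAAAAAAAAAAAGATCGGAAGAGCACACGTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
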