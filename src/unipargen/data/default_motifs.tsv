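haplogroup	variant
A2	146C
A2	153A
A2	235T
A2	663G
A2	1736G
A2	4248C
A2	4824G
A2	8027G
A2	8794T
A2	16111G
A2	16223T
A2	16290G
A2	16319C
A2	16362C
B2	3547T
B2	4977C
B2	6473C
B2	8281-8289d
B2	9950T
B2	11177C
B2	16217A
C1	249d
C1	493G
C1	3552T
C1	9545C
C1	13263T
C1	14318C
C1	16223T
C1	16298G
C1	16325T
C1	16327G
D1	2092G
D1	4883T
D1	5178T
D1	8414A
D1	14668G
D1	16223T
D1	16325T
D1	16362C
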