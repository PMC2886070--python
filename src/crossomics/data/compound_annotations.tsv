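compound	full_name	chain_class	alkenyl
allyl	2-propenyl glucosinolate	C3	1
3MTP	3-methylthiopropyl glucosinolate	C3	0
3MSOP	3-methylsulfinylpropyl glucosinolate	C3	0
3-butenyl	3-butenyl glucosinolate	C4	1
S-2OH3-butenyl	S-2-hydroxy-3-butenyl glucosinolate	C4	1
4MTB	4-methylthiobutyl glucosinolate	C4	0
4MSOB	4-methylsulfinylbutyl glucosinolate	C4	0
6MSOH	6-methylsulfinylhexyl glucosinolate	long-chain	0
7MTH	7-methylthioheptyl glucosinolate	long-chain	0
7MSOH	7-methylsulfinylheptyl glucosinolate	long-chain	0
8MSOO	8-methylsulfinyloctyl glucosinolate	long-chain	0
1MOI3M	1-methoxy-indolyl-3-methyl glucosinolate	indolic	0
4OHI3M	4-hydroxy-indolyl-3-methyl glucosinolate	indolic	0
4MOI3M	4-methoxy-indolyl-3-methyl glucosinolate	indolic	0
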