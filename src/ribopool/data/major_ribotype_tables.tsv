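sample_id	species	genome	total_reads	ribotype	reads	percent
K-4480	Avena strigosa subsp. brevis var. candida	As	21927	Ad2/As3	8781	40
K-4480	Avena strigosa subsp. brevis var. candida	As	21927	Al/As2	2412	11
K-4480	Avena strigosa subsp. brevis var. candida	As	21927	As5	2325	11
K-4480	Avena strigosa subsp. brevis var. candida	As	21927	As6	1703	8
K-15025	Avena strigosa var. strigosa	As	15373	Ad2/As3	6572	43
K-15025	Avena strigosa var. strigosa	As	15373	Al/As2	1691	11
K-15025	Avena strigosa var. strigosa	As	15373	As5	1543	10
K-15025	Avena strigosa var. strigosa	As	15373	As6	1220	8
K-14943	Avena strigosa subsp. nudibrevis	As	20746	Ad2/As3	9087	44
K-14943	Avena strigosa subsp. nudibrevis	As	20746	Al/As2	2282	11
K-14943	Avena strigosa subsp. nudibrevis	As	20746	As5	2135	10
K-14943	Avena strigosa subsp. nudibrevis	As	20746	As6	1628	8
K-5233	Avena strigosa subsp. brevis var. candida	As	24714	Ad2/As3	7977	32
K-5233	Avena strigosa subsp. brevis var. candida	As	24714	As5	3707	15
K-5233	Avena strigosa subsp. brevis var. candida	As	24714	Al/As2	2962	12
K-5233	Avena strigosa subsp. brevis var. candida	As	24714	As6	1995	8
K-5195	Avena strigosa var. strigosa	As	15576	Ad2/As3	9069	58
K-5195	Avena strigosa var. strigosa	As	15576	As5	4517	29
K-5195	Avena strigosa var. strigosa	As	15576	Al/As2	3642	23
K-5195	Avena strigosa var. strigosa	As	15576	As6	2493	16
K-14826	Avena abyssinica var. schimperi	AB	14399	B5	3291	23
K-14826	Avena abyssinica var. schimperi	AB	14399	As1	3039	21
K-14826	Avena abyssinica var. schimperi	AB	14399	B6	1042	7
K-11678	Avena abyssinica var. braunii	AB	15270	As1	5337	35
K-11678	Avena abyssinica var. braunii	AB	15270	B5	2387	16
K-11678	Avena abyssinica var. braunii	AB	15270	B7	1142	5
K-11678	Avena abyssinica var. braunii	AB	15270	B6	1108	4
K-14811	Avena abyssinica var. braunii	AB	21862	As1	10877	49
K-14811	Avena abyssinica var. braunii	AB	21862	As2	4151	19
K-14811	Avena abyssinica var. braunii	AB	21862	B7	2472	11
K-14811	Avena abyssinica var. braunii	AB	21862	B5	1266	6
K-14811	Avena abyssinica var. braunii	AB	21862	B6	1012	5
K-13351	Avena byzantina	ACD	23292	D	9935	43
K-13351	Avena byzantina	ACD	23292	Aby2	2716	12
K-13351	Avena byzantina	ACD	23292	Am/Amp	2619	12
K-1785	Avena byzantina var. nigra	ACD	18956	D	7961	42
K-1785	Avena byzantina var. nigra	ACD	18956	Am/Amp	1458	8
K-1785	Avena byzantina var. nigra	ACD	18956	Al/As2	1054	6
K-1785	Avena byzantina var. nigra	ACD	18956	Aby4	1010	5
K-15252	Avena byzantina var. culta	ACD	18761	D	7425	40
K-15252	Avena byzantina var. culta	ACD	18761	Aby3	1269	7
K-14787	Avena sativa var. aurea	ACD	23663	D	7623	32
K-14787	Avena sativa var. aurea	ACD	23663	Am/Amp	3786	16
K-1180	Avena sativa var. mutica	ACD	13886	D	5971	43
K-1180	Avena sativa var. mutica	ACD	13886	Am/Amp	1138	8
K-2471	Avena sativa subsp. nudisativa var. mongolica	ACD	16539	D	8600	52
K-1795	Avena sativa subsp. nudisativa var. chinensis	ACD	19272	D	11563	60
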