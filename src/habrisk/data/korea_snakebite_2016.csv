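id,region,population_million,area_km2,snakebites,snakebites_per_10k
1,Seoul,9.93,605.24,78,0.08
2,Busan,3.50,732.46,28,0.08
3,Daegu,2.48,880.62,97,0.39
4,Incheon,2.94,350.81,45,0.15
5,Gwangju,1.47,498.01,73,0.50
6,Daejeon,1.51,539.16,85,0.56
7,Ulsan,1.17,1044.90,51,0.44
8,Sejong-si,0.24,464.86,14,0.58
9,Gyeonggi-do,12.71,10045.13,528,0.42
10,Gangwon-do,1.55,16590.84,316,2.04
11,Chungcheongbuk-do,1.59,7408.86,288,1.81
12,Chungcheongnam-do,2.10,8023.70,392,1.87
13,Jeollabuk-do,1.86,8024.87,267,1.43
14,Jeollanam-do,1.90,10374.78,526,2.76
15,Gyeongsangbuk-do,2.70,18901.51,569,2.11
16,Gyeongsangnam-do,3.37,9567.07,297,0.88
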