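fui,x,y,alpha,alpha_prime
1,0.1914,0.1669,229.5330,40.4670
2,0.1990,0.1999,224.8037,45.1963
3,0.2100,0.2399,217.1473,52.8527
4,0.2265,0.2883,202.8305,67.1695
5,0.2459,0.3353,178.7020,91.2980
6,0.2662,0.3762,147.4148,122.5852
7,0.2908,0.4115,118.5208,151.4792
8,0.3154,0.4400,99.5371,170.4629
9,0.3367,0.4617,88.5017,181.4983
10,0.3633,0.4764,78.1648,191.8352
11,0.3862,0.4866,70.9617,199.0383
12,0.4024,0.4811,64.9378,205.0622
13,0.4162,0.4737,59.4234,210.5766
14,0.4313,0.4655,53.4431,216.5569
15,0.4457,0.4576,47.8847,222.1153
16,0.4606,0.4494,42.3707,227.6293
17,0.4753,0.4410,37.1698,232.8302
18,0.4887,0.4328,32.6477,237.3523
19,0.5033,0.4246,28.2408,241.7592
20,0.5155,0.4161,24.4487,245.5513
21,0.5283,0.4083,21.0471,248.9529
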