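cluster,region,climate,top_crops,wheat_frac,arable_ha,arable_pct_of_land,yield_potential_mean,yield_potential_sd,yield_rainfed_mean,yield_rainfed_sd,success_pct,mg_potential,mg_rainfed
A,Northern Europe,Temperate maritime,wheat:37|barley:31|rapeseed:10,0.37,6124324,18.1,1.6,1.5,1.5,1.3,75,000,000
B,North-eastern Europe,Continental,wheat:45|barley:13|sunflower:8,0.45,2247233,9.1,2.0,1.9,1.8,1.6,50,0000,0000
C,Southern UK,Maritime,wheat:41|barley:26|rapeseed:12,0.41,4646324,34.7,2.5,0.8,2.4,0.7,100,000,000
D,North-eastern Europe,Humid continental,wheat:38|barley:11|rapeseed:11,0.38,6976458,18.4,3.3,1.5,2.9,1.4,90,000,000
E,Western Europe,Temperate maritime,wheat:35|barley:15|rapeseed:8,0.35,13225677,39.4,4.1,1.2,3.4,1.1,95,00,00
F,West to eastern Europe,Continental to intermediate,wheat:31|barley:13|maize:10,0.31,37826068,28.5,4.1,1.4,3.6,1.1,85,0,0
G,East Europe,Humid continental,wheat:27|maize:20|sunflower:20,0.27,13063593,31.4,4.6,1.9,3.6,1.1,90,I,00
H,Southern Europe,Mediterranean hot summer,olives:22|barley:20|wheat:15,0.15,12487126,18.6,5.1,2.9,2.2,1.5,80,I,0000
I,Southern Europe,Mediterranean humid continental,wheat:29|maize:18|sunflower:13,0.29,55649190,25.8,5.8,1.9,3.4,1.3,95,II,0000
J,Central Asia,Cold semi-arid,wheat:48|barley:14|sunflower:11,0.48,1754289,7.8,6.7,0.6,1.6,0.9,100,III,0000
K,West Asia,Dry summer subtropical,wheat:37|barley:17|olives:7,0.37,18165133,19.6,6.2,1.9,1.5,1.3,100,I,0000
L,North-eastern Europe,Sub-arctic,wheat:41|barley:16|sunflower:11,0.41,5412229,8.0,0.2,0.8,0.2,0.7,0,na,na
M,Northern Europe,Maritime sub-arctic,wheat:35|barley:31|oats:14,0.35,729597,4.2,0.2,0.7,0.2,0.7,0,na,na
N,Southwest Russia,Hot summer continental,wheat:33|barley:12|maize:10,0.33,480846,6.6,0.8,1.8,0.7,1.5,0,na,na
O,Alps,Alpine,wheat:31|maize:12|barley:10,0.31,899790,9.3,0.3,1.0,0.3,1.0,0,na,na
P,Asia Southeast Black Sea,Humid,wheat:36|barley:16|olives:4,0.36,1387943,20.4,2.6,2.4,1.4,1.5,60,0000,0000
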