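amino_acid,fish_meal,soybean_meal,insect_meal
ala,6.82,4.43,7.05
arg,7.19,7.54,5.34
asn/asp,10.02,11.87,10.07
cys,0.93,1.74,0.62
gln/glu,13.98,18.74,11.12
gly,6.88,4.19,6.67
his,2.62,2.69,3.32
ile,4.64,4.61,4.86
leu,7.91,8.02,7.76
lys,8.31,6.44,6.19
met,3.07,1.45,2.06
phe,4.29,5.22,4.31
pro,4.45,5.08,6.39
ser,4.29,4.13,4.71
thr,4.57,3.67,4.29
trp,1.13,1.58,1.61
tyr,3.40,3.60,6.85
val,5.48,5.00,6.79
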