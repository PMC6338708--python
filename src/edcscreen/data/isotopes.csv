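# Isotope exact masses (Da) and natural abundances (fraction), CIAAW/NIST 2018 values.
# Columns: element, nominal isotope, exact mass in Da, abundance fraction.
# Abundances per element sum to 1; isotopes listed in order of increasing mass.
element,isotope,mass_da,abundance
H,1,1.00782503207,0.999885
H,2,2.01410177785,0.000115
C,12,12.0,0.9893
C,13,13.00335483507,0.0107
N,14,14.00307400443,0.99636
N,15,15.00010889888,0.00364
O,16,15.99491461956,0.99757
O,17,16.99913175650,0.00038
O,18,17.99915961286,0.00205
F,19,18.99840316273,1.0
Na,23,22.98976928196,1.0
P,31,30.97376199842,1.0
S,32,31.97207100000,0.9499
S,33,32.97145876000,0.0075
S,34,33.96786700000,0.0425
S,36,35.96708100000,0.0001
Cl,35,34.96885268000,0.7576
Cl,37,36.96590259000,0.2424
K,39,38.96370648643,0.932581
K,40,39.96399816600,0.000117
K,41,40.96182525792,0.067302
Br,79,78.91833760000,0.5069
Br,81,80.91628970000,0.4931
I,127,126.90447190000,1.0
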