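# residomics element table v1 — monoisotopic masses and natural isotope
# abundances (NIST/CODATA compilation values, 6 d.p.).
# columns: element symbol, nucleon shift relative to lightest isotope,
#          isotope mass (Da), natural abundance (fraction)
element,shift,mass,abundance
C,0,12.000000,0.989300
C,1,13.003355,0.010700
H,0,1.007825,0.999885
H,1,2.014102,0.000115
N,0,14.003074,0.996360
N,1,15.000109,0.003640
O,0,15.994915,0.997570
O,1,16.999132,0.000380
O,2,17.999160,0.002050
Na,0,22.989770,1.000000
S,0,31.972071,0.949900
S,1,32.971459,0.007500
S,2,33.967867,0.042500
S,4,35.967081,0.000100
K,0,38.963707,0.932581
K,1,39.963999,0.000117
K,2,40.961826,0.067302
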