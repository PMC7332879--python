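# residomics bundled biomarker library: seven smoke-plant alkaloid/glycoside
# standards with observed m/z and retention times on the reference
# chromatographic method (BEH C18, 12.5 min gradient). Observed m/z are
# instrument values and may deviate from theory by several ppm.
# fragments: optional semicolon-separated "mz:relint" pairs (pseudo-MS/MS).
name,formula,adduct,observed_mz,rt_min,fragments
anabasine,C10H14N2,[M+H]+,163.125,1.48,
arbutin,C12H16O7,[M+Na]+,295.084,1.72,
caffeine,C8H10N4O2,[M+H]+,195.090,3.82,
cotinine,C10H12N2O,[M+H]+,177.105,1.45,
nicotine,C10H14N2,[M+H]+,163.125,1.15,
theobromine,C7H8N4O2,[M+H]+,181.078,2.67,
theophylline,C7H8N4O2,[M+H]+,181.078,3.15,
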