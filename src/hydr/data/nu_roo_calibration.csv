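# Approximate OD-stretch frequency vs O...O distance correlation.
# Synthetic default assembled from literature ice/clathrate-hydrate trends;
# replace with a laboratory calibration for quantitative distances.
R_angstrom,nu_cm-1
2.50,2170
2.55,2260
2.60,2330
2.65,2390
2.70,2440
2.75,2482
2.80,2517
2.85,2546
2.90,2570
2.95,2590
3.00,2607
3.10,2633
3.20,2652
3.30,2666
3.40,2677
3.50,2685
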