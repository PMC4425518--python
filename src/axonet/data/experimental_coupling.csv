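# Experimental coupling coefficients between dIN pairs, by soma
# separation, as summarised from paired whole-cell recordings: the
# median coefficient falls from roughly 10-15% for close pairs to
# roughly 5% for pairs 150-200 um apart.  Values are band summaries for
# overlay on model coupling-coefficient plots, not raw data points.
separation_lo_um,separation_hi_um,coefficient_lo_pct,coefficient_hi_pct
0,50,10.0,15.0
150,200,4.0,6.0
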