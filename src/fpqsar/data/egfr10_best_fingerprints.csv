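# Published best 10 positive and best 10 negative PubChem fingerprints for the
# EGFR10 benchmark (inhibitors: IC50 < 10 nM), with their percent frequency in
# inhibitors (freq_active), in non-inhibitors (freq_inactive), and the printed
# frequency difference (printed_score). Two rows (FP815, FP145) print a
# difference that disagrees with the rounded column arithmetic by 0.01 -- the
# source rounded full-precision frequencies; the printed values are kept as-is.
# The source text discusses FP186 alongside these, but the printed table lists
# FP189; both readings are noted here and the table is taken as authoritative.
descriptor,freq_active,freq_inactive,printed_score,sign
FP380,71.85,43.64,28.21,positive
FP579,75.79,52.82,22.97,positive
FP189,38.78,17.35,21.43,positive
FP388,67.52,46.41,21.11,positive
FP816,24.21,6.24,17.97,positive
FP815,32.68,16.68,15.99,positive
FP374,39.96,27.06,12.90,positive
FP613,32.87,20.95,11.92,positive
FP661,31.50,19.82,11.68,positive
FP348,40.16,29.50,10.66,positive
FP698,21.26,45.15,-23.89,negative
FP673,8.27,31.80,-23.53,negative
FP690,57.48,76.51,-19.03,negative
FP700,19.29,38.00,-18.71,negative
FP814,3.54,20.42,-16.88,negative
FP145,30.31,45.28,-14.96,negative
FP701,14.37,28.50,-14.13,negative
FP669,2.17,15.92,-13.75,negative
FP195,6.50,18.02,-11.52,negative
FP382,2.56,11.61,-9.05,negative
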