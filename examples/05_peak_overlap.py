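"""Test whether two CLIP-peak sets co-occur more than chance.

Simulates two 200-peak sets on a 2-chromosome genome with 60% of the B
peaks planted next to A peaks (two RNA-binding proteins sharing
targets), filters to significant peaks (p <= 1e-5, fold >= 8), and runs
the shuffle-based overlap permutation test.
"""

from splicescreen import (
    GenomeLayout,
    filter_peaks,
    overlap_permutation_test,
    simulate_peaks,
)

genome = GenomeLayout({"chr1": 1_000_000, "chr2": 1_000_000})
peaks_a, peaks_b, truth = simulate_peaks(
    genome, n_a=200, n_b=200, length_mean=200, cooccur_fraction=0.6, jitter=50, seed=42,
)
peaks_a, peaks_b = filter_peaks(peaks_a), filter_peaks(peaks_b)
result = overlap_permutation_test(peaks_a, peaks_b, genome, n_perm=999, seed=0)

print(f"peaks after significance filter: {len(peaks_a)} (A), {len(peaks_b)} (B)")
print(f"A peaks overlapping B:           {result['observed']}")
print(f"mean overlap after shuffling B:  {result['null_mean']:.1f}")
print(f"permutation p (999 shuffles):    {result['p']:.3g}")
# Observed overlap far above the shuffled-null mean with p = 0.001 (the
# minimum attainable) is the signature of genuinely co-occurring binding.
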