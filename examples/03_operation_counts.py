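"""Operation-count arithmetic behind the axis-restricted comparison scheme.

Comparing every cube of a decomposed volume with every other cube costs
n*(n-1) colour-difference evaluations.  Restricting each cube's comparisons
to its three axis planes replaces that with n * (3 * plane area) operations
-- one to two orders of magnitude fewer at typical MR volume sizes.
"""

from saliency3d import nominal_comparison_counts

for k in (4, 8):
    n_cubes, all_pairs, axis_plane = nominal_comparison_counts(240, 240, k)
    print(f"k={k:2d}: {n_cubes:>9,} cubes")
    print(f"      all-pairs comparisons:  {all_pairs:>15,}")
    print(f"      axis-plane comparisons: {axis_plane:>15,}"
          f"  ({all_pairs / axis_plane:.0f}x fewer)")
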