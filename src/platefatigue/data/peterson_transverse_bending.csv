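# Theoretical stress concentration factors K_t (net-section nominal stress)
# for transverse bending of a finite-width plate with a central circular
# through-hole.
#
# Rows: hole diameter over plate width (d/w).
# Columns: hole diameter over plate thickness (d/t).
#
# Provenance: smooth surrogate of the published transverse-bending curves.
# The infinite-plate backbone follows the shear-deformable (Reissner) trend
# K_t,inf(d/t) = 1.79 + 1.21 / (1 + d/t), which spans the thin-plate
# (Kirchhoff) limit 1.79 at large d/t and approaches the small-hole
# three-dimensional limit ~3.0 as d/t -> 0.  The finite-width attenuation is
# linear on the net-section nominal, K_t = 1 + (K_t,inf - 1) * (1 - d/w).
# Values are a working digitization, not a scan of the original chart; see
# docs/methods.md for accuracy notes.  Bilinear interpolation is applied
# between grid points; queries outside the grid are clamped to the boundary.
d_w,0.25,0.50,1.00,1.50,2.00,3.00,4.00
0.05,2.670,2.517,2.325,2.210,2.134,2.038,1.980
0.10,2.582,2.437,2.256,2.147,2.074,1.983,1.929
0.15,2.494,2.357,2.186,2.083,2.014,1.929,1.877
0.20,2.406,2.277,2.116,2.019,1.955,1.874,1.826
0.25,2.319,2.197,2.046,1.956,1.895,1.819,1.774
0.30,2.231,2.118,1.976,1.892,1.835,1.765,1.722
0.35,2.143,2.038,1.907,1.828,1.776,1.710,1.671
0.40,2.055,1.958,1.837,1.764,1.716,1.655,1.619
0.45,1.967,1.878,1.767,1.701,1.656,1.601,1.568
0.50,1.879,1.798,1.698,1.637,1.597,1.546,1.516
0.55,1.791,1.718,1.628,1.573,1.537,1.492,1.464
0.60,1.703,1.639,1.558,1.510,1.477,1.437,1.413
0.65,1.615,1.559,1.488,1.446,1.418,1.382,1.361
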