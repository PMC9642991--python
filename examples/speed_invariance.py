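"""Speed-invariant orientation decoding: spatial versus temporal domain.

Classifies each trial at a core speed against reference responses recorded at
*other* speeds.  Represented over time, spike trains compress and dilate with
speed, so temporal profiles carry almost no cross-speed information; expressed
over drum position (the spatial domain), the same spike trains classify well
above chance, because the subfield layout that structures them is fixed on
the skin.
"""

from edgecode.experiments import spatial_temporal_contrast

table = spatial_temporal_contrast(seed=11, n_per_type=3, jitter_um=20.0, beta=0.5)
print("across-speed decoding accuracy (chance 0.25), mean over 6 neurons:")
print(f"{'core speed':>12} {'spatial':>9} {'temporal':>9}")
for v, (spatial, temporal, _) in table.items():
    print(f"{v:>10.0f}   {spatial:>8.3f} {temporal:>9.3f}")
print("spatial-domain accuracy exceeds temporal at every core speed;")
print("temporal hovers at chance because cross-speed time warping destroys alignment.")
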