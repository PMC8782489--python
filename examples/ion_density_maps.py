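"""Groove-resolved ion densities in curvilinear helicoidal coordinates.

Builds a synthetic ion cloud concentrated in the minor groove (as basic
amino acids are around AT-rich DNA), maps every ion to (D, R, A)
coordinates about the duplex axis and reports molarities and enrichment
over the bulk.
"""

import numpy as np

import groovetherm as gt

spec = gt.IonCloudSpec(
    region_molarity={"minor_inner": 5.0, "major_inner": 0.5},
    bulk_molarity=0.1,           # mol/L far from the duplex
    n_frames=200, seed=1)
cloud = gt.gen_ion_cloud(spec)
frames = [gt.to_helicoidal(cloud.axis, f) for f in cloud.frames]

rspec = spec.region_spec
span = (0.0, cloud.axis.length)
# shift azimuths below 33 deg up by a turn so one bin covers each groove:
# minor [33, 147), major [147, 393)
shifted = [gt.HelicoidalCoords(f.D, f.R, np.where(f.A < 33.0, f.A + 360.0,
                                                  f.A)) for f in frames]
dmap = gt.density_map(shifted,
                      r_edges=np.array([0.0, rspec.inner_R, rspec.cutoff_R]),
                      a_edges=np.array([33.0, 147.0, 393.0]),
                      d_span=span, box_volume=float(np.prod(cloud.box)),
                      spec=rspec)

occ = {}
for fr in frames:
    labels = gt.assign_region(fr, rspec, span)
    for lab in set(labels):
        occ.setdefault(lab, []).append(np.sum(labels == lab))

print(f"Bulk molarity estimate: {dmap.bulk_molarity:.3f} mol/L "
      f"(generator truth 0.100)")
print("Mean ions per frame by region:")
for lab in ("minor_inner", "major_inner", "minor_outer", "major_outer"):
    print(f"  {lab:12s} {np.mean(occ.get(lab, [0])):6.2f}")

ratio, max_ratio = gt.bulk_ratio(dmap)
print(f"Maximum cell enrichment over bulk: {max_ratio:.1f}x "
      f"(generator truth 50x in the inner minor groove)")

conv = gt.convergence_series(frames, "minor_inner", rspec, span)
print(f"Minor-groove occupancy: running mean {conv.running_mean[-1]:.2f}, "
      f"block SE {conv.block_se:.2f}, drift flagged: {conv.drift_flag}")
print("High minor-groove enrichment with a flat convergence series is the "
      "signature of specific groove binding rather than diffuse screening.")
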