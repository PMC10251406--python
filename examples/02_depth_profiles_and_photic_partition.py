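"""Depth-resolved tracer localization across the photic boundary.

Simulates a bicarbonate incubation (photoautotrophic uptake decays with
light down the mat), emits noisy triplicate laser-ablation spot tables,
converts them to percent-replacement profiles, and asks: what fraction of
the freshly fixed carbon sits below the photic depth?
"""

import numpy as np

import dielmat as dm
from dielmat import io as dio
from dielmat import simulate as sim

substrate = dm.default_substrates()["bicarbonate"]
params = sim.MatSimParams(substrate=substrate, seed=42)
field = sim.simulate_replacement_field(params)
table, truth = sim.emit_spot_tables(field, sample_times=(sim.DUSK_H,))

# photic boundary from a tabulated irradiance profile: the depth where
# scalar irradiance falls to 10 umol photons PAR m-2 s-1
z = np.linspace(0, 1, 101)
irradiance = params.peak_irradiance * np.exp(-z / params.attenuation_length)
boundary = dm.boundary_from_irradiance(z, irradiance)

fracs, means = [], []
for profile in dio.spot_table_to_profiles(table):
    rp = dm.replacement_profile(profile, params.control_delta, substrate)
    means.append(dm.mean_replacement(rp).integrated)
    fracs.append(dm.partition_at_boundary(rp, boundary).fraction_below)

print(f"photic boundary (normalized depth) : {boundary:.3f}")
print(f"per-profile mean replacement (%)   : "
      + ", ".join(f"{m:.3f}" for m in means))
print(f"true (noiseless) mean replacement  : "
      f"{truth['true_mean_replacement_pct'][0]:.3f} %")
print(f"fraction of fixed C below boundary : {np.mean(fracs):.1%}")
print()
print("Reading: uptake is surface-localized, so only a small share of the")
print("tracer sits below the photic depth in this no-transport forward")
print("model; field mats redistribute freshly fixed C downward, raising")
print("that share.")
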