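"""Inter- and intra-kinetochore distances from STED-like pair images.

Renders kinetochore pairs at a known 1.37 µm separation (metaphase-like
geometry: 30 nm pixels, 60 nm PSF), measures each pair with the
Gaussian-refined KT-KT distance, and shows a normalized mean ± SEM line
profile across one pair — the two outer-marker peaks flank the broad
inner-centromere band.
"""

import numpy as np

from kinetoquant import profiles, synthgen

TRUE_SEP_UM = 1.37
scenes = synthgen.make_distance_dataset(TRUE_SEP_UM, n_pairs=20, seed=11)

values = [profiles.measure_pair_in_image(stack).value_um for stack, _ in scenes]
print(
    f"KT-KT distance over {len(values)} pairs: "
    f"mean {np.mean(values):.3f} um, SD {np.std(values, ddof=1):.3f} um "
    f"(truth {TRUE_SEP_UM} um)"
)

# profile across the first pair, all channels sampled on the same line
stack, truth = scenes[0]
mid = (truth.pairs.mid_y[0], truth.pairs.mid_x[0])
ang = truth.pairs.angle_rad[0]
half = TRUE_SEP_UM / stack.pixel_size_um / 2 + 10
p0 = (mid[0] - np.sin(ang) * half, mid[1] - np.cos(ang) * half)
p1 = (mid[0] + np.sin(ang) * half, mid[1] + np.cos(ang) * half)
prof = profiles.sample_line_profile(stack, p0, p1)

for role in ("outer_kt", "pericentric"):
    norm = profiles.normalize_profile_group(prof.samples[role][None, :])[0]
    peaks = prof.positions_px[norm > 60] * stack.pixel_size_um
    print(
        f"{role}: profile regions above 60% span "
        f"{peaks.min():.2f}-{peaks.max():.2f} um along the scan"
    )
print(
    "\nThe outer marker shows two separated peaks; the pericentric channel a\n"
    "single broad band centred between them."
)
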