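"""Recovering the inter-zonal flow from noisy synthetic measurements.

Generates a synthetic monitoring campaign (two-box truth, multiplicative
lognormal noise with GSD 1.3) and estimates beta from each replicate's
NF/FF task-average pair, illustrating how much information the NF-FF
contrast carries about air mixing.
"""

from dataclasses import replace

import numpy as np

from dustbox import (
    NoiseModel,
    SyntheticCampaign,
    generate_campaign,
    load_fixtures,
    recover_beta,
)

TRUE_BETA = 2.5

bundle = load_fixtures()
spec = bundle.emission_spec("Clay 1", "CD", "respirable")
scenario = replace(bundle.scenarios["L"], beta=TRUE_BETA)

campaign = SyntheticCampaign(
    scenario=scenario,
    emission=spec,
    noise=NoiseModel(gsd=1.3, seed=42),
    n_replicates=50,
    task_duration_min=240.0,
)
_, observations, truth = generate_campaign(campaign)
print(f"truth: beta = {TRUE_BETA} m3/min, S = {truth['emission_rate_mg_min']:.0f} mg/min,"
      f" task averages NF {truth['task_average']['c_nf_mg_m3']:.2f} /"
      f" FF {truth['task_average']['c_ff_mg_m3']:.3f} mg/m3")

nf = {o.replicate: o.measured for o in observations if o.model.endswith("nf")}
ff = {o.replicate: o.measured for o in observations if o.model.endswith("ff")}
estimates = np.array(
    [recover_beta([nf[r]], [ff[r]], bundle.scenarios["L"], spec.base_rate)[0]
     for r in nf]
)
print(f"\nper-replicate beta estimates over {len(estimates)} noisy replicates:")
print(f"  median {np.median(estimates):.2f}  "
      f"IQR [{np.percentile(estimates, 25):.2f}, {np.percentile(estimates, 75):.2f}]")
print(f"  median relative error "
      f"{100 * abs(np.median(estimates) - TRUE_BETA) / TRUE_BETA:.1f}%")
print("\nWith 30% per-minute measurement noise the task averages still pin")
print("beta to within a few percent in the median.")
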