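#!/usr/bin/env python
"""Type-I calibration of the bootstrap positive-LR p-value.

Simulates null cohorts (subgroup independent of outcome, cohort size and
prevalence matching the analysis cohort) and measures the rejection rate of
p_vs_all at alpha = 0.05 with a prespecified test direction, plus the
inflation of the data-adaptive ("auto") direction."""

import json
from pathlib import Path

import numpy as np

from gdrisk.cohort import Cohort, Participant
from gdrisk.subgroup_stats import bootstrap_lr, standard_subgroup

OUT = Path(__file__).resolve().parents[1] / "results"
N_SIMS = 500
N_BOOT = 2000


def main():
    rng = np.random.default_rng(12345)
    spec = standard_subgroup("prs_top25")
    rej = {"greater": 0, "auto": 0}
    for _ in range(N_SIMS):
        gd = rng.random(3533) < 0.037
        mem = rng.random(3533) < 0.25
        cohort = Cohort([Participant(id=f"x{i}", gd=bool(gd[i]),
                                     prs_top25=bool(mem[i]))
                         for i in range(3533)])
        for direction in rej:
            r = bootstrap_lr(cohort, spec, n_boot=N_BOOT,
                             seed=int(rng.integers(2**31)), direction=direction)
            rej[direction] += r.p_vs_all < 0.05
    rates = {k: v / N_SIMS for k, v in rej.items()}
    OUT.mkdir(exist_ok=True)
    with open(OUT / "bootstrap_calibration.json", "w") as f:
        json.dump({"n_sims": N_SIMS, "n_boot": N_BOOT, "alpha": 0.05,
                   "rejection_rate": rates}, f, indent=1)
    print(f"null rejection rate at alpha=0.05 over {N_SIMS} simulations:")
    print(f"  prespecified direction: {rates['greater']:.3f}  (nominal 0.05)")
    print(f"  data-adaptive direction: {rates['auto']:.3f}  "
          "(~2x nominal, as expected for a post-hoc one-sided test)")


if __name__ == "__main__":
    main()
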