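#!/usr/bin/env python
"""Estimator validation: parameter recovery and the style sign pattern.

Two experiments with exact ground truth:

1. recovery — 100 replicates at n=300, rho=0.3, k=8: mean bias of the
   autocorrelation estimate and 95% CI coverage;
2. sign pattern — the 12-network ada-like suite generated with positive rho
   for interactive turn-taking and negative rho for push-in networks: the
   fitted rho should carry the generating sign, significantly, in every
   network.

Writes results/tables/recovery_summary.csv and sign_pattern.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from affilex import (
    GeneratorConfig,
    fit_nam,
    generate_recovery_instance,
    generate_sign_pattern_suite,
)

SEED = 20240901
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)

    rho0, rows = 0.3, []
    seeds = np.random.SeedSequence(SEED).generate_state(100) % (2**31)
    for s in seeds:
        inst = generate_recovery_instance(
            GeneratorConfig(seed=int(s), n_users=300), rho=rho0
        )
        f = fit_nam(inst.y, inst.weight, inst.X.to_numpy(), inst.D)
        half = 1.959963984540054 * f.rho_se
        rows.append({"rho_hat": f.rho, "se": f.rho_se,
                     "covered": f.rho - half <= rho0 <= f.rho + half})
    rec = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "replicates": [len(rec)],
        "rho_true": [rho0],
        "mean_rho_hat": [rec.rho_hat.mean()],
        "mean_bias": [rec.rho_hat.mean() - rho0],
        "mean_se": [rec.se.mean()],
        "ci95_coverage": [rec.covered.mean()],
    })
    summary.to_csv(out / "recovery_summary.csv", index=False)
    print("recovery (n=300, rho=0.3, 100 replicates):")
    print(summary.to_string(index=False))

    sign_rows = []
    for (theme, style), inst in generate_sign_pattern_suite(seed=SEED).items():
        f = fit_nam(inst.y, inst.weight, inst.X.to_numpy(), inst.D)
        sign_rows.append({
            "theme": theme.value, "style": style, "n": f.n,
            "rho_true": inst.truth["rho"], "rho_hat": f.rho, "p": f.rho_p,
            "sign_ok": np.sign(f.rho) == np.sign(inst.truth["rho"]),
            "significant": f.rho_p < 0.05,
        })
    sign = pd.DataFrame(sign_rows)
    sign.to_csv(out / "sign_pattern.csv", index=False)
    ok = int((sign.sign_ok & sign.significant).sum())
    print(f"\nsign pattern: {ok}/{len(sign)} networks recover the generating "
          "sign significantly (positive for interactive turn-taking, negative "
          "for push-in)")
    print(sign.to_string(index=False))


if __name__ == "__main__":
    main()
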