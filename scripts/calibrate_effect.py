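"""Calibrate the planted between-site community effect.

Maps the site-centroid log-spread sigma_b to the mean location R^2 recovered
by a sequential Bray-Curtis PERMANOVA at reference conditions (n=120
mosquitoes, 6 sites, 40 ASVs, multinomial depth 5000, within-site Dirichlet
concentration 30).  The resulting table is frozen into
``ampliscreen.simulate._EFFECT_CALIBRATION`` so that
``simulate_cohort(site_effect_size=...)`` can invert it.

Run:  python scripts/calibrate_effect.py [--replicates 30]
"""

from __future__ import annotations

import argparse

import numpy as np

from ampliscreen import simulate as sim
from ampliscreen.community import bray_curtis
from ampliscreen.permanova import permanova

SIGMA_GRID = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.5, 2.0, 2.5]


def mean_location_r2(sigma: float, replicates: int, seed0: int = 1000) -> float:
    r2s = []
    for rep in range(replicates):
        truth = sim.simulate_cohort(
            120, n_sites=6, site_effect_size=0.0, seed=seed0 + rep, centroid_spread=sigma
        )
        counts = sim.community_counts(truth, depth=5000, seed=seed0 + rep)
        meta = sim.metadata_frame(truth)
        dm = bray_curtis(counts)
        res = permanova(dm, meta, ["location"], n_perm=0, seed=0)
        r2s.append(res.factors[0].r2)
    return float(np.mean(r2s))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=30)
    args = ap.parse_args()
    print("_EFFECT_CALIBRATION: list[tuple[float, float]] = [")
    for sigma in SIGMA_GRID:
        r2 = mean_location_r2(sigma, args.replicates)
        print(f"    ({sigma}, {r2:.4f}),", flush=True)
    print("]")


if __name__ == "__main__":
    main()
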