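"""Monte Carlo PTA under exact dosing intervals, and the dose-shift effect.

Simulates the virtual cohort 1000 times with the final-model parameters and
exact q8/q12/q24 regimens, reporting PTA of the >12 h-above-MIC-in-24 h
target per renal group across the MIC grid, and compares attainment under
the observed (nurse-round shifted) versus exact regimens with paired random
effects.
"""

import argparse
from pathlib import Path

from ceftazpk import CohortSpec, PopulationParameters
from ceftazpk.simulation import SimulationConfig, compare_shift_vs_exact, simulate_pta


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=6)
    ap.add_argument("--n", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed, n_replicates=args.n)
    res = simulate_pta(cfg)
    res.pooled.to_csv(args.out / "pta_simulated.csv", index=False)
    res.per_replicate.to_csv(args.out / "pta_simulated_replicates.csv", index=False)

    mic8 = res.pooled[res.pooled["mic"] == 8.0]
    print(f"Monte Carlo PTA ({args.n} replicates, exact intervals, MIC 8 mg/L):")
    for _, r in mic8.iterrows():
        print(f"  group {r['group']}: {100 * r['pta']:.1f}%")
    print("reference values under observed-cohort simulation: 93 / 97 / 97 %")

    from ceftazpk.cohort import sample_cohort

    _, truth = sample_cohort(CohortSpec(), seed=args.seed)
    cmp = compare_shift_vs_exact(truth, PopulationParameters())
    cmp.to_csv(args.out / "shift_vs_exact.csv", index=False)
    shifted = cmp[cmp["shifted"]]
    d = (shifted["t_above_shifted"] - shifted["t_above_exact"]).mean()
    print(f"dose-shift effect (shifted subjects, n={len(shifted)}): "
          f"mean extra time above MIC {d:.2f} h; "
          f"paired PTA {100 * cmp['attains_shifted'].mean():.0f}% (shifted regimens) "
          f"vs {100 * cmp['attains_exact'].mean():.0f}% (exact)")


if __name__ == "__main__":
    main()
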