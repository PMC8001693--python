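"""Fit the random-regression model across the scenario grid.

Runs the reduced-scale study (design 2, both longevity indicators,
censoring levels 20-80%, censored and first-penalty treatments) with the
desk-scale chain, writing heritability and contrast tables under
results/study/. Completed cells are cached, so the script can be
interrupted and resumed.

This is the long-running step (~10-15 min at the default reduced scale).
Pass a smaller scale factor as the second argument for a quicker pass,
e.g. `python analysis/03_fit_scenarios.py 7 0.005`.
"""
import sys
import time
from pathlib import Path

from longevity_rrm.datatypes import ChainConfig, SimConfig
from longevity_rrm.pipeline import RunConfig, run_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 7, scale: float = 0.01) -> None:
    run = RunConfig(
        sim=SimConfig(seed=seed),
        chain=ChainConfig(chain_length=8000, burn_in=3000, thin=5, seed=0),
        traits=("TL", "FL"),
        designs=("D2_fixed_total",),
        levels=(20, 40, 60, 80),
        treatments=("CEN", "PENm1"),
        n_replicates=1,
        scale_factor=scale,
        base_seed=seed,
        k=3,
        out_dir=str(OUT),
    )
    t0 = time.time()
    res = run_study(run, progress=True)
    print(f"\nfitted {len(res['results'])} scenario cells in "
          f"{time.time() - t0:.0f} s; tables under {OUT}")
    h = res["heritabilities"]
    com = h[(h.level == 0) & (h.age.between(2, 12))]
    print("mean h2 (ages 2-12) on complete data: "
          + ", ".join(f"{t}: {com[com.trait == t].h2.mean():.3f}"
                      for t in ("TL", "FL")))


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 7
    scale = float(sys.argv[2]) if len(sys.argv) > 2 else 0.01
    main(seed, scale)
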