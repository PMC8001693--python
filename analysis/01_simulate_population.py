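"""Simulate the base cow population and write its tables.

Generates the default synthetic population (multi-generation pedigree,
true random-regression effects, culling/calving histories), applies the
phenotypic quality-control filters, and writes pedigree and cow-history
tables under results/population/. Prints a summary of herd-life structure
so the population can be eyeballed against what beef-cow data look like.
"""
import sys
from collections import Counter
from pathlib import Path

import numpy as np

from longevity_rrm.datatypes import SimConfig, histories_to_table
from longevity_rrm.synthetic_data import (apply_quality_control,
                                          simulate_cow_histories,
                                          simulate_genetic_effects,
                                          simulate_pedigree)

OUT = Path(__file__).resolve().parent.parent / "results" / "population"


def main(seed: int = 42) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    ped = simulate_pedigree(cfg)
    eff = simulate_genetic_effects(ped, cfg)
    raw = simulate_cow_histories(ped, eff, cfg)
    hist, counts = apply_quality_control(raw, return_counts=True)

    ped.write(OUT / "pedigree.tsv")
    histories_to_table(hist).to_csv(OUT / "cow_histories.tsv", sep="\t", index=False)

    cull = np.array([h.culling_age for h in hist])
    n_calv = np.array([len(h.calving_ages) for h in hist])
    print(f"pedigree: {ped.n} animals over {cfg.n_generations + 1} generations, "
          f"{cfg.n_herds} herds")
    print(f"cows with histories after QC: {len(hist)} "
          f"(removed: {dict(counts)})")
    print(f"culling age: mean {cull.mean():.2f}, median {np.median(cull):.0f}, "
          f"past-15 survivors {(cull > 15).mean() * 100:.1f}%")
    print(f"calvings per cow: mean {n_calv.mean():.2f}")
    dist = Counter(np.clip(cull, 2, 16))
    print("culling-age distribution (16 = past 15):",
          {int(k): v for k, v in sorted(dist.items())})
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
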