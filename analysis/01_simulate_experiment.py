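#!/usr/bin/env python
"""Simulate the four-chamber, four-replica microarray experiment.

Emulates the study design: 2,000 genes probed by 1-13 redundant spots,
log-normal baseline expression (median gene = 1), per-gene biological
CV between 10% and 50%, 5% technical spot noise, and 2% of spots
violating the foreground >= 2x background quality rule. Planted truth:

* 40 genes differentially expressed at fold 4 between the atria (LA->RA)
  and 4 genes between the ventricles (LV->RV) — mirroring the finding
  that the two atria differ far more than the two ventricles;
* a 12-gene coordination module per chamber (loading 0.95);
* 30 genes synchronous between LA and RA (loading 0.995).

Also writes six synthetic pathway gene sets (sizes matching the study's
ASC/CAS/CMC/GLY/OPH/ICT selections) in GMT form; the "CMC" stand-in is
enriched for the planted atrial fold changes and "ICT" contains the
coordination modules, so downstream scripts have signal to find.

Usage: python analysis/01_simulate_experiment.py [--seed 2026] [--out results/data]
"""

import argparse
from pathlib import Path

from gfabric.synthetic import (
    PlantedFold,
    PlantedModule,
    PlantedSynchrony,
    SimulationConfig,
    generate,
)

PATHWAY_SIZES = {"ASC": 104, "CAS": 121, "CMC": 65, "GLY": 50, "OPH": 111, "ICT": 199}


def build_config(seed: int) -> SimulationConfig:
    names = [f"G{i + 1:04d}" for i in range(2000)]
    planted_de = [
        PlantedFold(g, "LA", "RA", 4.0, "up" if i % 2 == 0 else "down")
        for i, g in enumerate(names[:40])
    ] + [PlantedFold(g, "LV", "RV", 4.0, "up") for g in names[40:44]]
    planted_modules = [
        PlantedModule(f"mod_{c}", tuple(names[100 + 12 * k: 112 + 12 * k]), c, 0.95)
        for k, c in enumerate(("LA", "RA", "LV", "RV"))
    ]
    planted_synchrony = [PlantedSynchrony(g, "LA", "RA", 0.995) for g in names[200:230]]
    return SimulationConfig(
        n_genes=2000,
        planted_de=planted_de,
        planted_modules=planted_modules,
        planted_synchrony=planted_synchrony,
        seed=seed,
    )


def write_gene_sets(config: SimulationConfig, path: Path, seed: int) -> None:
    """Synthetic pathway stand-ins over the simulated gene universe."""
    import numpy as np

    rng = np.random.default_rng(seed + 1)
    names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    lines = []
    for name, size in PATHWAY_SIZES.items():
        if name == "CMC":  # enriched for the planted atrial fold changes
            members = names[:40] + list(
                rng.choice(names[300:], size - 40, replace=False)
            )
        elif name == "ICT":  # contains the four coordination modules
            modules = names[100:148]
            members = modules + list(
                rng.choice(names[300:], size - len(modules), replace=False)
            )
        else:
            members = list(rng.choice(names[300:], size, replace=False))
        lines.append(f"{name}\tsynthetic pathway stand-in ({size} genes)\t" + "\t".join(members))
    path.write_text("\n".join(lines) + "\n")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2026)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    config = build_config(args.seed)
    paths = generate(config, args.out)
    write_gene_sets(config, args.out / "synthetic_pathways.gmt", args.seed)
    print(f"simulated {config.n_genes} genes x 4 chambers x 4 replicas (seed {config.seed})")
    print(f"planted: {len(config.planted_de)} DE genes, "
          f"{len(config.planted_modules)} modules, "
          f"{len(config.planted_synchrony)} synchronous genes")
    print(f"expression table: {paths['expression']}")
    print(f"gene sets:        {args.out / 'synthetic_pathways.gmt'}")


if __name__ == "__main__":
    main()
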