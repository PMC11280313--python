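#!/usr/bin/env python
"""Simulate the two knockout cohorts and their NP source databases.

Generates an Oat1-style cohort (4 KO vs 4 WT) and an Oat3-style cohort
(6 KO vs 6 WT), each a ~1000-metabolite serum panel with log-normal noise
(sigma 0.3) and the four reported vitamin fold changes planted on the
Oat3 cohort (biotin 4.55, thiamine 2.06, pyridoxal 1.86, pyridoxamine
2.32).  Writes panels, the three NP databases and ground truth under
results/data/.
"""

import sys
from pathlib import Path

from oatnp import synthdata

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohorts = {
        "oat1": synthdata.SynthConfig(
            seed=SEED, n_ko=4, n_wt=4,
            planted_effects=tuple(
                (f"metabolite_{i:04d}", fc) for i, fc in enumerate([2.5, 0.4, 3.0, 0.5, 2.0])
            ),
        ),
        "oat3": synthdata.SynthConfig(seed=SEED + 1, n_ko=6, n_wt=6),
    }
    for name, cfg in cohorts.items():
        panel, truth = synthdata.generate_metabolome(cfg)
        dbs = synthdata.generate_np_databases(cfg, truth)
        panel.to_tsv(OUT / f"{name}_panel.tsv")
        truth.to_json(OUT / f"{name}_ground_truth.json")
        for src, db in dbs.items():
            db.to_tsv(OUT / f"{name}_db_{src.lower()}.tsv")
        ko = panel.abundance[panel.ko_samples].mean(axis=1)
        wt = panel.abundance[panel.wt_samples].mean(axis=1)
        print(
            f"{name}: {panel.abundance.shape[0]} metabolites, "
            f"{cfg.n_ko} KO vs {cfg.n_wt} WT; "
            f"planted effects {len(truth.true_differential)}; "
            f"max empirical FC {float((ko / wt).max()):.2f}"
        )


if __name__ == "__main__":
    main()
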