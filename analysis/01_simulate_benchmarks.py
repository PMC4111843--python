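"""Generate example synthetic benchmark releases and write them as TSVs.

Produces a historic (cv, blind) pair and a preselected-blind pair, plus
the planted scoring matrices, under results/data/.  These files show the
benchmark dialect end to end; every later analysis regenerates its own
data in memory with fresh seeds.
"""

from pathlib import Path

import pandas as pd

from mhcbench.io import write_binding_tsv
from mhcbench.synthetic import GeneratorConfig, generate_bd_pair

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def dump_pair(config: GeneratorConfig, prefix: str) -> None:
    cv, blind, truth = generate_bd_pair(config)
    write_binding_tsv(cv, OUT / f"{prefix}_cv.tsv")
    write_binding_tsv(blind, OUT / f"{prefix}_blind.tsv")
    rows = []
    for allele, weights in truth.weights.items():
        for pos in range(weights.shape[0]):
            rows.append({"allele": allele, "position": pos + 1,
                         **{aa: w for aa, w in zip("ACDEFGHIKLMNPQRSTVWY", weights[pos])}})
    pd.DataFrame(rows).to_csv(OUT / f"{prefix}_planted_pssm.tsv", sep="\t", index=False)
    print(f"{prefix}: cv={cv.n_measurements} measurements over {len(cv)} datasets, "
          f"blind={blind.n_measurements} over {len(blind)} (mode={config.blind_mode})")


def main() -> None:
    base = GeneratorConfig(seed=2014, dataset_size=300, blind_size=150)
    dump_pair(base, "historic")
    from dataclasses import replace

    dump_pair(replace(base, blind_mode="preselected", seed=2015), "preselected")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
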