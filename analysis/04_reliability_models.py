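"""Fit and evaluate the reliability models on the deviation table.

Reads results/deviation_table.tsv (produced by 03_deviation_experiment.py),
searches all two-feature logistic models by LOOCV AROC — overall and
restricted to training-set-only / blind-set-only features — then evaluates
the two named presets and their max-combination, and splits datasets into
'good'/'bad' reporting groups at the 0.2 probability cutoff.

Outputs: feature_pair_search*.tsv (the ranked pair tables),
reliability_report.tsv (per-dataset LOOCV probabilities and groups) and a
printed summary of the preset/combined LOOCV AROCs.
"""

from pathlib import Path

import pandas as pd

from mhcbench.features import BLIND_FEATURES, CV_FEATURES
from mhcbench.reliability import (
    BLIND_PAIR,
    TRAIN_PAIR,
    combine_max,
    loocv_evaluate,
    pairwise_feature_search,
    reporting_split,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(OUT / "deviation_table.tsv", sep="\t")
    labels = table["label"]

    for name, restrict in (
        ("all", None), ("cv_only", CV_FEATURES), ("blind_only", BLIND_FEATURES)
    ):
        ranked = pairwise_feature_search(table, labels, restrict_to=restrict)
        ranked.to_csv(OUT / f"feature_pair_search_{name}.tsv", sep="\t", index=False)
        top = ranked.iloc[0]
        print(f"best {name} pair: ({top['feature_a']}, {top['feature_b']}) "
              f"LOOCV AROC {top['loocv_aroc']:.3f}")

    probs_train, auc_train = loocv_evaluate(table, labels, TRAIN_PAIR)
    probs_blind, auc_blind = loocv_evaluate(table, labels, BLIND_PAIR)
    probs_combined = combine_max(probs_train, probs_blind)
    from mhcbench.reliability import probability_aroc

    auc_combined = probability_aroc(probs_combined, labels)
    print(f"training-set model {TRAIN_PAIR}: LOOCV AROC {auc_train:.3f}")
    print(f"blind-set model {BLIND_PAIR}: LOOCV AROC {auc_blind:.3f}")
    print(f"max-combined model: LOOCV AROC {auc_combined:.3f}")

    report = table[["config", "replicate", "allele", "length",
                    "cv_aroc", "blind_aroc", "signed", "absolute", "label"]].copy()
    report["p_large_train"] = probs_train
    report["p_large_blind"] = probs_blind
    report["p_large_combined"] = probs_combined
    report["group"] = reporting_split(probs_combined, cutoff=0.2)
    report.to_csv(OUT / "reliability_report.tsv", sep="\t", index=False)

    by_group = report.groupby("group")["absolute"].agg(["size", "mean"])
    print("observed |cv - blind| by predicted reporting group:")
    print(by_group.round(4).to_string())
    print(f"written {OUT / 'reliability_report.tsv'}")


if __name__ == "__main__":
    main()
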