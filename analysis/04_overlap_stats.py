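"""Cross-trait overlap and pleiotropy statistics at the index variants.

Counts secondary-trait associations at the discovery index variants at
the 0.05/N and 1/N thresholds with direction-of-effect partitions,
tests low-frequency vs common coding-tag enrichment (Fisher exact),
checks disjointness of the >= 99%-confidence shared sets, and
correlates the two sharing-probability vectors (Spearman).  Writes
results/overlap_summary.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, STUDY_DIR

from pleioscan.overlap import (
    contingency_enrichment,
    disjointness_check,
    format_sig,
    membership_correlation,
    overlap_counts,
)
from pleioscan.sumstats import read_sumstats


def main() -> None:
    sig_path = RESULTS / "signals.tsv"
    if not sig_path.exists() or not (RESULTS / "classification_summary.json").exists():
        sys.exit("run 02_select_signals.py and 03_classify_effects.py first")
    signals = pd.read_csv(sig_path, sep="\t", keep_default_na=False)
    index_ids = signals["variant_id"].tolist()
    ss1 = read_sumstats(STUDY_DIR / "trait1.tsv", "trait1")

    summary = {"n_index": len(index_ids)}
    for trait in ("trait2", "trait3"):
        q = read_sumstats(STUDY_DIR / f"{trait}.tsv", trait)
        rep = overlap_counts(index_ids, ss1, q)
        print(f"[trait1 vs {trait}] {rep.summary()}")
        summary[trait] = {
            "strict_threshold": format_sig(rep.strict_threshold),
            "lenient_threshold": format_sig(rep.lenient_threshold),
            "n_strict": rep.n_strict, "n_lenient": rep.n_lenient,
            "n_same_direction": rep.n_same_direction,
            "n_opposite_direction": rep.n_opposite_direction,
        }

    # enrichment of coding tags among low-frequency leads (MAF < 5%)
    af = ss1.df.set_index("variant_id").loc[index_ids, "af"]
    maf = af.where(af <= 0.5, 1 - af)
    low = maf < 0.05
    coded = (signals.set_index("variant_id")["coding_variant"] != "NA")
    a, b = int((coded & low).sum()), int(low.sum())
    c, d = int((coded & ~low).sum()), int((~low).sum())
    if b and d:
        enr = contingency_enrichment(a, b, c, d)
        print(f"[coding enrichment] {a}/{b} low-frequency vs {c}/{d} common "
              f"leads coding-tagged: ratio "
              f"{'inf' if enr.ratio_infinite else round(enr.ratio, 2)}, "
              f"Fisher p = {enr.fisher_p:.2g}")
        summary["coding_enrichment"] = {
            "low_freq": [a, b], "common": [c, d],
            "fisher_p": enr.fisher_p,
            "ratio": None if enr.ratio_infinite else enr.ratio}

    # membership-probability structure across the two secondary traits
    p2 = pd.read_csv(RESULTS / "shared_posterior_trait2.csv")["post"]
    p3 = pd.read_csv(RESULTS / "shared_posterior_trait3.csv")["post"]
    corr = membership_correlation(p2.to_numpy(), p3.to_numpy())
    set2 = {v for v, p in zip(index_ids, p2) if p >= 0.99}
    set3 = {v for v, p in zip(index_ids, p3) if p >= 0.99}
    n_shared_sets = disjointness_check(set2, set3)
    print(f"[membership] Spearman rho = {corr['spearman_rho']:.2f} "
          f"(p = {corr['p']:.2g}) between the two sharing-probability vectors")
    print(f"[membership] 99%-confidence sets: {len(set2)} vs {len(set3)} "
          f"variants, intersection {n_shared_sets}")
    summary["membership_spearman"] = corr
    summary["n99_sets"] = {"trait2": len(set2), "trait3": len(set3),
                           "intersection": n_shared_sets}

    (RESULTS / "overlap_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"-> {RESULTS / 'overlap_summary.json'}")


if __name__ == "__main__":
    main()
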