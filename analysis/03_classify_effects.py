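"""Classify index-variant effect pairs with the two-group line models.

For each secondary trait (trait2, trait3), takes the discovery index
variants from 02, transforms (beta, se) of both traits to the
sqrt-heritability scale, compares one- vs two-group models, fits the
two-group mixture (one slope fixed at 0 for trait2, both free for
trait3 as for a population-wide hormone trait), samples Gibbs
memberships and estimates sharing proportions among the top half of
discovery associations.  Writes results/classification_<pair>.tsv and a
summary JSON.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, RHO, SEED, STUDY_DIR

from pleioscan.linemodels import (
    EMConfig,
    LineGroup,
    compare_one_vs_two,
    fit_em,
    gibbs_membership,
    scale_init,
    sharing_proportion,
)
from pleioscan.sumstats import heritability_scale, read_sumstats


def effect_pairs(index_ids, ss_a, ss_b):
    a = ss_a.df.set_index("variant_id").loc[index_ids]
    b = ss_b.df.set_index("variant_id").loc[index_ids]
    b1, s1 = heritability_scale(a["beta"].to_numpy(), a["se"].to_numpy(),
                                a["af"].to_numpy())
    b2, s2 = heritability_scale(b["beta"].to_numpy(), b["se"].to_numpy(),
                                b["af"].to_numpy())
    return (np.column_stack([b1, b2]), np.column_stack([s1, s2]),
            a["ln_pval"].to_numpy())


def classify(pair_name, B, S, lnp1, fixed_slope):
    tau = scale_init(B)
    cmp_ = compare_one_vs_two(B, S, scale=tau, correlation=RHO,
                              fixed_slope=fixed_slope)
    fit = cmp_["fit_two"]
    gibbs = gibbs_membership(B, S, fit, n_iter=10_000, burn_in=1_000, seed=SEED)
    shared_idx = int(np.argmax([abs(g.slope) for g in fit.groups]))
    post_shared = fit.posteriors[:, shared_idx]
    # top half of discovery associations; ln scale avoids p underflow
    share = sharing_proportion(post_shared, lnp1,
                               p_cutoff=float(np.median(lnp1)), prob_cutoff=0.8)
    print(f"[{pair_name}] one- vs two-group 2*dLL = {cmp_['stat']:.1f} "
          f"({'strong' if cmp_['strong_evidence'] else 'weak'} evidence for 2 groups)")
    print(f"[{pair_name}] fitted slopes {[round(g.slope, 3) for g in fit.groups]}, "
          f"pi {np.round(fit.pi, 3)}, scale init {tau:.4f}")
    print(f"[{pair_name}] sharing among top half: "
          f"{100 * share['fraction_shared']:.1f}% at posterior > 0.8; "
          f"{share['n_99']} variants at >= 99% confidence shared")
    return fit, gibbs, post_shared, share, cmp_["stat"]


def main() -> None:
    sig_path = RESULTS / "signals.tsv"
    if not sig_path.exists():
        sys.exit("run 02_select_signals.py first")
    index_ids = pd.read_csv(sig_path, sep="\t")["variant_id"].tolist()
    ss = {t: read_sumstats(STUDY_DIR / f"{t}.tsv", t)
          for t in ("trait1", "trait2", "trait3")}

    summary = {"n_index": len(index_ids)}
    shared_posteriors = {}
    for pair, fixed in (("trait2", 0.0), ("trait3", None)):
        B, S, lnp1 = effect_pairs(index_ids, ss["trait1"], ss[pair])
        fit, gibbs, post, share, stat = classify(f"trait1-{pair}", B, S, lnp1, fixed)
        shared_posteriors[pair] = post
        out = pd.DataFrame({"variant_id": index_ids})
        for gi, g in enumerate(fit.groups):
            out[f"post_{g.label or gi}"] = fit.posteriors[:, gi]
            out[f"gibbs_{g.label or gi}"] = gibbs.membership[:, gi]
        out.to_csv(RESULTS / f"classification_trait1_{pair}.tsv",
                   sep="\t", index=False)
        summary[f"{pair}_slopes"] = [round(g.slope, 4) for g in fit.groups]
        summary[f"{pair}_pi"] = [round(float(x), 4) for x in fit.pi]
        summary[f"{pair}_two_group_stat"] = round(stat, 2)
        summary[f"{pair}_sharing_pct_top_half"] = round(
            100 * share["fraction_shared"], 1)
        summary[f"{pair}_n99_shared"] = share["n_99"]

    pd.Series(shared_posteriors["trait2"]).to_csv(
        RESULTS / "shared_posterior_trait2.csv", index=False, header=["post"])
    pd.Series(shared_posteriors["trait3"]).to_csv(
        RESULTS / "shared_posterior_trait3.csv", index=False, header=["post"])
    (RESULTS / "classification_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"-> {RESULTS}/classification_*.tsv, classification_summary.json")


if __name__ == "__main__":
    main()
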