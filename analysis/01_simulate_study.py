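"""Simulate the three-trait synthetic study.

Generates 120 LD blocks with one causal variant each and bivariate true
effects for the discovery/autoimmune pair from the line-group mixture.
The discovery trait is produced as an inverse-variance-weighted
meta-analysis of two cohorts (two thirds / one third of the effective
sample); ~10% of variants are present only in the larger cohort and
pass through the meta single-sided, like population-specific
low-frequency alleles.  Hormone-trait (trait3) effects are drawn
conditionally on the discovery effects.  Writes the trait TSVs, dense
LD files and the ground-truth table under results/synthetic_study/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import (
    ARCH_12,
    BLOCK,
    GROUPS_13,
    N_BLOCKS,
    N_EFF_1,
    N_EFF_2,
    N_EFF_3,
    PI_13,
    SEED,
    STUDY_DIR,
)

from pleioscan.simulate import (
    LDBlockSpec,
    simulate_conditional_trait,
    simulate_effect_pairs,
    simulate_ld_block,
    simulate_marginal_sumstats,
)
from pleioscan.sumstats import SumStats, ivw_meta, write_ld_dense, write_sumstats


def meta_two_cohorts(b1, ld, af, rng):
    """Trait-1 summary stats as an IVW meta of two unequal cohorts."""
    ss_a = simulate_marginal_sumstats(b1, ld, af, 2 * N_EFF_1 / 3, rng, "cohortA")
    ss_b = simulate_marginal_sumstats(b1, ld, af, N_EFF_1 / 3, rng, "cohortB")
    only_a = rng.random(len(ld)) < 0.10  # absent from the smaller cohort
    recs = []
    for i, vid in enumerate(ld.variants):
        ra = ss_a.record(vid)
        recs.append(ivw_meta([ra] if only_a[i] else [ra, ss_b.record(vid)]))
    return SumStats.from_records("trait1", recs), int(only_a.sum())


def main() -> None:
    rng = np.random.default_rng(SEED)
    blocks, parts1, parts2, parts3 = [], [], [], []
    eff12_all, lab12_all, b3_all, lab13_all = [], [], [], []
    n_single = 0

    for bi in range(N_BLOCKS):
        spec = LDBlockSpec(**{**BLOCK.__dict__, "chrom": (bi % 22) + 1,
                              "base_pos": BLOCK.base_pos + (bi // 22) * 20_000_000})
        ld, af = simulate_ld_block(spec, rng)
        eff, lab = simulate_effect_pairs(1, ARCH_12, rng)
        b3c, lab3 = simulate_conditional_trait(eff[:, 0], GROUPS_13, PI_13, rng)

        m = len(ld)
        b1, b2, b3 = np.zeros(m), np.zeros(m), np.zeros(m)
        lab12, lab13 = np.full(m, -1), np.full(m, -1)
        pos = rng.integers(0, m)
        b1[pos], b2[pos], b3[pos] = eff[0, 0], eff[0, 1], b3c[0]
        lab12[pos], lab13[pos] = lab[0], lab3[0]

        ss1, ns = meta_two_cohorts(b1, ld, af, rng)
        n_single += ns
        parts1.append(ss1.df)
        parts2.append(simulate_marginal_sumstats(b2, ld, af, N_EFF_2, rng,
                                                 "trait2").df)
        parts3.append(simulate_marginal_sumstats(b3, ld, af, N_EFF_3, rng,
                                                 "trait3").df)
        blocks.append(ld)
        eff12_all.append(np.column_stack([b1, b2]))
        lab12_all.append(lab12)
        b3_all.append(b3)
        lab13_all.append(lab13)

    ss = {name: SumStats(name, pd.concat(p, ignore_index=True))
          for name, p in (("trait1", parts1), ("trait2", parts2),
                          ("trait3", parts3))}
    STUDY_DIR.mkdir(parents=True, exist_ok=True)
    for name, s in ss.items():
        write_sumstats(s, STUDY_DIR / f"{name}.tsv")
    ld_dir = STUDY_DIR / "ld"
    ld_dir.mkdir(exist_ok=True)
    for i, ld in enumerate(blocks):
        write_ld_dense(ld, ld_dir / f"block_{i:04d}.txt",
                       ld_dir / f"block_{i:04d}.variants.txt")

    eff12 = np.vstack(eff12_all)
    lab12 = np.concatenate(lab12_all)
    lab13 = np.concatenate(lab13_all)
    truth = pd.DataFrame({
        "variant_id": [v for ld in blocks for v in ld.variants],
        "beta1_true": eff12[:, 0],
        "beta2_true": eff12[:, 1],
        "beta3_true": np.concatenate(b3_all),
        "group_12": lab12,
        "group_13": lab13,
    })
    truth.to_csv(STUDY_DIR / "truth.tsv", sep="\t", index=False)

    n_causal = int((lab12 >= 0).sum())
    print(f"simulated {N_BLOCKS} blocks, {len(truth)} variants, "
          f"{n_causal} causal")
    print(f"  trait1 = IVW meta of two cohorts "
          f"(n_eff {2 * N_EFF_1 // 3:,} + {N_EFF_1 // 3:,}); "
          f"{n_single} variants single-cohort only")
    print(f"  shared with trait2 (slope 0.43): "
          f"{int((lab12 == 1).sum())}/{n_causal}")
    print(f"  shared with trait3 (slope 0.99): "
          f"{int((lab13 == 1).sum())}/{n_causal}")
    print(f"  outputs in {STUDY_DIR}")


if __name__ == "__main__":
    main()
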