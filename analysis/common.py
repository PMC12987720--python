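"""Shared study design for the numbered analysis scripts.

One synthetic "study": a discovery case-control scan (trait1, an
autoimmune-hypothyroidism-like phenotype), a second autoimmune-like
scan (trait2) whose shared variants sit on a slope-0.43 line, and a
quantitative hormone-level trait (trait3) where sharing follows slopes
0.13 / 0.99.  Sizes are desk-scale stand-ins for a biobank analysis:
120 LD blocks of 30 variants, one causal variant each, effective sample
sizes around 3e5.
"""

from pathlib import Path

from pleioscan.linemodels import LineGroup
from pleioscan.simulate import LDBlockSpec, TraitArchitecture

SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "synthetic_study"

N_BLOCKS = 120
TAU = 0.15          # prior scale of true effects (sqrt-heritability units)
RHO = 0.99
N_EFF_1 = 300_000   # discovery-scan effective sample size
N_EFF_2 = 300_000
N_EFF_3 = 226_947   # hormone-level scan (disjoint controls)

BLOCK = LDBlockSpec(n_variants=30, ar1_lambda=0.9, spacing_bp=20_000)

ARCH_12 = TraitArchitecture(
    n1=N_EFF_1, n2=N_EFF_2,
    groups=[LineGroup(0.0, TAU, RHO, label="trait1_only"),
            LineGroup(0.43, TAU, RHO, label="shared")],
    proportions=(0.62, 0.38),
    trait_labels=("trait1", "trait2"),
)

# trait3 sharing structure: a residual population-wide slope and a strong
# thyroid-like component on slope 0.99 for 20% of causal variants
GROUPS_13 = [LineGroup(0.13, TAU, RHO, label="residual"),
             LineGroup(0.99, TAU, RHO, label="shared")]
PI_13 = (0.80, 0.20)
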