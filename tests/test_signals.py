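import math

import numpy as np
import pandas as pd
import pytest

from pleioscan.signals import (
    IndexSignal,
    SelectionConfig,
    conditional_association,
    dynamic_threshold,
    group_loci,
    select_independent_signals,
    signals_to_frame,
    tag_coding,
)
from pleioscan.simulate import LDBlockSpec, simulate_ld_block, simulate_marginal_sumstats
from pleioscan.sumstats import LDMatrix, SumStats, Variant, z_to_ln_p


def make_sumstats(positions, zs, chrom=1, trait="t"):
    """Summary stats with given positions and (signed) z-scores."""
    rows = []
    for pos, z in zip(positions, zs):
        v = Variant(chrom, pos, "A", "G")
        se = 0.01
        rows.append({"variant_id": v.id, "chrom": chrom, "pos": pos,
                     "ref": "A", "alt": "G", "beta": z * se, "se": se,
                     "pval": math.exp(z_to_ln_p(z)), "af": 0.3,
                     "n_cases": np.nan, "n_controls": np.nan,
                     "ln_pval": float(z_to_ln_p(z))})
    return SumStats(trait, pd.DataFrame(rows))


def make_ld(ids, r):
    return LDMatrix(ids, np.asarray(r, float))


def psd_corr(n, rng):
    """Random correlation matrix via a Gram construction (PSD by design)."""
    A = rng.standard_normal((n, n + 3))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestDynamicThreshold:
    def test_cap_binds_at_moderate_chisq(self):
        assert dynamic_threshold(20.0) == pytest.approx(0.1)  # 5/20 > 0.1

    def test_strong_peak_in_hard_zone(self):
        t = dynamic_threshold(500.0)
        assert t == pytest.approx(0.01)
        assert t < SelectionConfig().hard_zone_t

    def test_boundary_tie(self):
        assert dynamic_threshold(50.0) == pytest.approx(0.1)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dynamic_threshold(0.0)


class TestSelection:
    def test_dependent_pair_collapses_to_one(self):
        ss = make_sumstats([1_000_000, 1_500_000], [math.sqrt(40), 6.0])
        ids = ss.variant_ids
        ld = make_ld(ids, [[1, math.sqrt(0.5)], [math.sqrt(0.5), 1]])
        sel = select_independent_signals(ss, ld)
        assert len(sel) == 1
        assert sel[0].chisq == pytest.approx(40, rel=1e-6)

    def test_weak_ld_pair_kept(self):
        ss = make_sumstats([1_000_000, 1_500_000], [math.sqrt(40), 6.0])
        ids = ss.variant_ids
        r = math.sqrt(0.005)
        sel = select_independent_signals(ss, make_ld(ids, [[1, r], [r, 1]]))
        assert len(sel) == 2

    def test_hard_zone_suppresses_nearby_secondary(self):
        # leader chi-square 1000 -> T = 0.005 < 0.02: nothing within 1 Mb,
        # even at r^2 well below T
        ss = make_sumstats([1_000_000, 1_500_000], [math.sqrt(1000), 6.0])
        ids = ss.variant_ids
        r = math.sqrt(0.001)
        sel = select_independent_signals(ss, make_ld(ids, [[1, r], [r, 1]]))
        assert len(sel) == 1
        # but beyond 1 Mb (still inside the +-2 Mb screen) the pair survives
        ss2 = make_sumstats([1_000_000, 2_500_000], [math.sqrt(1000), 6.0])
        sel2 = select_independent_signals(ss2, make_ld(ss2.variant_ids,
                                                       [[1, r], [r, 1]]))
        assert len(sel2) == 2

    def test_equality_rejects_strict_inequality(self):
        # r^2 exactly T must reject (rule is strictly less-than)
        ss = make_sumstats([1_000_000, 1_500_000], [math.sqrt(40), 6.0])
        r = math.sqrt(0.1)
        sel = select_independent_signals(ss, make_ld(ss.variant_ids,
                                                     [[1, r], [r, 1]]))
        assert len(sel) == 1

    def test_per_mb_cap_two_signals(self):
        zs = [math.sqrt(60), math.sqrt(50), math.sqrt(40)]
        ss = make_sumstats([1_000_000, 1_400_000, 1_800_000], zs)
        ld = make_ld(ss.variant_ids, np.eye(3))
        sel = select_independent_signals(ss, ld)
        assert len(sel) == 2  # third within 1 Mb of both, cap = 2

    def test_conditional_third_confirmed(self):
        zs = [math.sqrt(60), math.sqrt(50), math.sqrt(40)]
        ss = make_sumstats([1_000_000, 1_400_000, 1_800_000], zs)
        ld = make_ld(ss.variant_ids, np.eye(3))
        cfg = SelectionConfig(allow_conditional_third=True)
        sel = select_independent_signals(ss, ld, cfg)
        assert len(sel) == 3
        assert sel[2].conditional_flag == "confirmed_third"

    def test_conditional_third_rejected_when_shadow(self):
        # third variant is pure LD shadow of the first: conditional z ~ 0
        z1 = math.sqrt(60)
        r13 = 0.9
        zs = [z1, math.sqrt(50), r13 * z1]
        ss = make_sumstats([1_000_000, 1_400_000, 1_800_000], zs)
        r = np.eye(3)
        r[0, 2] = r[2, 0] = r13
        # r13^2 = 0.81 > T of signal 1 anyway; use moderate LD below T instead
        r[0, 2] = r[2, 0] = 0.28  # r^2 = 0.078 < T = 0.0833? T=min(.1,5/60)=0.0833
        # keep marginal z consistent with the shadow structure
        zs = [z1, math.sqrt(50), 0.28 * z1]
        ss = make_sumstats([1_000_000, 1_400_000, 1_800_000], zs)
        cfg = SelectionConfig(allow_conditional_third=True)
        sel = select_independent_signals(ss, make_ld(ss.variant_ids, r), cfg)
        # shadow z = 0.28*sqrt(60) = 2.17, not even GWS -> only 2 signals
        assert len(sel) == 2

    def test_missing_ld_policies(self):
        ss = make_sumstats([1_000_000, 1_500_000], [math.sqrt(40), 6.0])
        ld = make_ld([ss.variant_ids[0]], [[1.0]])  # second variant unknown
        assert len(select_independent_signals(ss, ld)) == 1
        cfg = SelectionConfig(missing_ld="allow")
        assert len(select_independent_signals(ss, ld, cfg)) == 2

    def test_mhc_exclusion(self):
        ss = make_sumstats([28_600_000, 40_000_000], [7.0, 6.5], chrom=6)
        ld = make_ld(ss.variant_ids, np.eye(2))
        assert len(select_independent_signals(ss, ld)) == 2
        cfg = SelectionConfig(mhc_exclusion=True)
        sel = select_independent_signals(ss, ld, cfg)
        assert [s.pos for s in sel] == [40_000_000]

    def test_determinism_and_tie_break(self):
        ss = make_sumstats([1_000_000, 9_000_000], [6.0, 6.0])
        ld = make_ld(ss.variant_ids, np.eye(2))
        sel1 = select_independent_signals(ss, ld)
        sel2 = select_independent_signals(ss, ld)
        assert [s.variant_id for s in sel1] == [s.variant_id for s in sel2]
        assert sel1[0].pos == 1_000_000  # tie broken by position

    def test_pairwise_certificate_on_synthetic_block(self):
        spec = LDBlockSpec(n_variants=40, ar1_lambda=0.95, chrom=5,
                           base_pos=2_000_000, spacing_bp=100_000)
        ld, af = simulate_ld_block(spec, 21)
        b = np.zeros(40); b[5] = 0.08; b[30] = 0.05
        ss = simulate_marginal_sumstats(b, ld, af, 300_000, 22)
        sel = select_independent_signals(ss, ld)
        for i, si in enumerate(sel):
            for sj in sel[:i]:
                if abs(si.pos - sj.pos) <= 2_000_000:
                    assert ld.pair_r(si.variant_id, sj.variant_id) ** 2 < sj.t_threshold


class TestConditional:
    def _block(self):
        ids = [f"1:{p}:A:G" for p in (100, 200, 300)]
        return ids

    def test_unlinked_conditioning_is_identity(self):
        ids = self._block()
        ss = make_sumstats([100, 200, 300], [6.0, 5.0, 4.0])
        ld = make_ld(ss.variant_ids, np.eye(3))
        z, _ = conditional_association(ss.variant_ids[0], [ss.variant_ids[1]], ss, ld)
        assert z == pytest.approx(6.0, rel=1e-9)

    def test_pure_shadow_conditions_to_zero(self):
        # z_t = r * z_c exactly: conditional z must vanish
        r = 0.8
        zc = 8.0
        ss = make_sumstats([100, 200], [zc, r * zc])
        R = [[1, r], [r, 1]]
        z, _ = conditional_association(ss.variant_ids[1], [ss.variant_ids[0]],
                                       ss, make_ld(ss.variant_ids, R))
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_matches_explicit_regression_on_genotypes(self):
        """Summary conditional z tracks the z from a joint OLS refit."""
        rng = np.random.default_rng(17)
        n = 20_000
        r = 0.6
        L = np.linalg.cholesky([[1, r], [r, 1]])
        G = rng.standard_normal((n, 2)) @ L.T
        y = 0.05 * G[:, 0] + 0.03 * G[:, 1] + rng.standard_normal(n)
        # marginal summaries
        zs, betas = [], []
        for j in range(2):
            x = (G[:, j] - G[:, j].mean()) / G[:, j].std()
            b = float(x @ y / n)
            se = float(y.std() / math.sqrt(n))
            zs.append(b / se)
        ss = make_sumstats([100, 200], zs)
        Remp = np.corrcoef(G.T)
        z_cond, _ = conditional_association(ss.variant_ids[0], [ss.variant_ids[1]],
                                            ss, make_ld(ss.variant_ids, Remp))
        # oracle: multiple regression t-statistic of predictor 0
        import statsmodels.api as sm
        X = sm.add_constant(G)
        tval = sm.OLS(y, X).fit().tvalues[1]
        assert z_cond == pytest.approx(tval, rel=0.05)

    def test_singular_conditioning_set(self):
        ss = make_sumstats([100, 200, 300], [8.0, 7.0, 6.9])
        rr = 1 - 1e-9  # conditioning pair essentially collinear
        R = np.array([[1, 0.2, 0.2], [0.2, 1, rr], [0.2, rr, 1]])
        with pytest.raises(np.linalg.LinAlgError):
            conditional_association(ss.variant_ids[0], ss.variant_ids[1:],
                                    ss, make_ld(ss.variant_ids, R))
        with pytest.raises(ValueError):
            conditional_association(ss.variant_ids[0], [], ss,
                                    make_ld(ss.variant_ids, R))


class TestLoci:
    def _sig(self, pos, chrom=1):
        return IndexSignal(variant_id=f"{chrom}:{pos}:A:G", chrom=chrom, pos=pos,
                           ln_pvalue=-50.0, chisq=50.0, t_threshold=0.1, rank=0)

    def test_chaining(self):
        sigs = [self._sig(1_000_000), self._sig(1_500_000), self._sig(3_000_000)]
        n = group_loci(sigs)
        assert n == 2
        assert [s.locus_id for s in sigs] == [1, 1, 2]

    def test_chain_extends_transitively(self):
        sigs = [self._sig(p) for p in (1_000_000, 1_900_000, 2_800_000)]
        assert group_loci(sigs) == 1

    def test_chromosome_break(self):
        sigs = [self._sig(1_000_000, 1), self._sig(1_200_000, 2)]
        assert group_loci(sigs) == 2

    def test_edge_cases(self):
        assert group_loci([]) == 0
        one = [self._sig(5)]
        assert group_loci(one) == 1 and one[0].locus_id == 1


class TestCodingTag:
    def test_lead_itself_coding(self):
        s = IndexSignal("1:100:A:G", 1, 100, -50, 50, 0.1, 1)
        ld = make_ld(["1:100:A:G"], [[1.0]])
        tag_coding([s], ld, ["1:100:A:G"])
        assert s.coding_variant == "1:100:A:G" and s.coding_r2 == 1.0

    def test_below_threshold_not_tagged(self):
        ids = ["1:100:A:G", "1:200:A:G"]
        r = math.sqrt(0.80)
        s = IndexSignal(ids[0], 1, 100, -50, 50, 0.1, 1)
        tag_coding([s], make_ld(ids, [[1, r], [r, 1]]), [ids[1]])
        assert s.coding_variant is None

    def test_best_of_several(self):
        ids = ["1:100:A:G", "1:200:A:G", "1:300:A:G"]
        R = np.array([[1.0, 0.985, 0.99], [0.985, 1.0, 0.9702], [0.99, 0.9702, 1.0]])
        s = IndexSignal(ids[0], 1, 100, -50, 50, 0.1, 1)
        tag_coding([s], make_ld(ids, R), ids[1:])
        assert s.coding_variant == ids[2]
        assert s.coding_r2 == pytest.approx(0.99 ** 2)

    def test_no_coding_in_window(self):
        s = IndexSignal("1:100:A:G", 1, 100, -50, 50, 0.1, 1)
        tag_coding([s], make_ld(["1:100:A:G"], [[1.0]]), [])
        assert s.coding_variant is None


# ---------------------------------------------------------------------------
# brute-force oracle (deliberately naive re-implementation of the rules)
# ---------------------------------------------------------------------------

def brute_force_select(positions, chisqs, R, cfg: SelectionConfig):
    """Reference greedy selection over one chromosome by plain loops."""
    gws_chisq = float(np.square(-__import__("scipy").special.ndtri(cfg.gws_threshold / 2)))
    order = sorted(range(len(positions)),
                   key=lambda i: (-chisqs[i], positions[i]))
    picked = []
    for i in order:
        if chisqs[i] < gws_chisq:
            continue
        ok = True
        n_near = 0
        for j in picked:
            d = abs(positions[i] - positions[j])
            Tj = min(cfg.t_cap, cfg.residual_chisq / chisqs[j])
            if d <= cfg.window_bp and R[i, j] ** 2 >= Tj:
                ok = False
            if d <= cfg.hard_zone_bp and Tj < cfg.hard_zone_t:
                ok = False
            if d <= cfg.per_mb_span:
                n_near += 1
        if ok and n_near >= cfg.per_mb_cap:
            ok = False
        if ok:
            picked.append(i)
    return picked


def test_selection_matches_brute_force_on_random_blocks():
    """200 random blocks: exact agreement with the naive oracle plus the
    post-hoc pairwise r^2 < T certificate on every output."""
    rng = np.random.default_rng(2026)
    cfg = SelectionConfig()
    for rep in range(200):
        m = int(rng.integers(5, 51))
        positions = np.sort(rng.choice(np.arange(1, 6_000_00) * 10, size=m,
                                       replace=False))
        R = psd_corr(m, rng)
        # chi-squares spanning sub-GWS to extreme
        chisqs = np.exp(rng.uniform(math.log(10), math.log(2000), size=m))
        zs = np.sqrt(chisqs) * rng.choice([-1, 1], size=m)
        ss = make_sumstats(positions.tolist(), zs.tolist(), chrom=int(rng.integers(1, 23)))
        ids = ss.variant_ids
        # make_sumstats sorts by position; build LD in that order
        ld = LDMatrix(ids, R)
        sel = select_independent_signals(ss, ld, cfg)
        got = sorted(s.variant_id for s in sel)
        want_idx = brute_force_select(positions, chisqs, R, cfg)
        want = sorted(ids[i] for i in want_idx)
        assert got == want, f"rep {rep}: {got} != {want}"
        # pairwise certificate
        for a, sa in enumerate(sel):
            for sb in sel[:a]:
                if abs(sa.pos - sb.pos) <= cfg.window_bp:
                    assert ld.pair_r(sa.variant_id, sb.variant_id) ** 2 < sb.t_threshold


def test_lowering_t_cap_never_increases_signal_count():
    rng = np.random.default_rng(7)
    m = 30
    positions = np.sort(rng.choice(np.arange(1, 500_000) * 10, m, replace=False))
    R = psd_corr(m, rng)
    chisqs = np.exp(rng.uniform(math.log(20), math.log(500), m))
    ss = make_sumstats(positions.tolist(), np.sqrt(chisqs).tolist())
    ld = LDMatrix(ss.variant_ids, R)
    counts = [len(select_independent_signals(ss, ld, SelectionConfig(t_cap=t)))
              for t in (0.1, 0.05, 0.03, 0.02)]
    assert counts == sorted(counts, reverse=True)


def test_frame_output_columns():
    ss = make_sumstats([1_000_000], [7.0])
    sel = select_independent_signals(ss, make_ld(ss.variant_ids, [[1.0]]))
    df = signals_to_frame(sel)
    assert list(df.columns) == ["rank", "variant_id", "chrom", "pos", "pval",
                                "chisq", "T", "locus_id", "conditional_flag",
                                "coding_variant", "coding_r2"]
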