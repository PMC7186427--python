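import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fstgc.inference import (
    DesignSpec,
    bh_fdr,
    build_design,
    correlation_table,
    effect_table,
    fit_connection_glm,
    mann_whitney_u,
    simple_effects,
    spearman_correlate,
    volume_group_test,
)


def make_design(n_per_cell=10, seed=0):
    rng = np.random.default_rng(seed)
    cells = [(0, 0), (0, 1), (1, 0), (1, 1)]
    snp1 = np.repeat([c[0] for c in cells], n_per_cell).astype(float)
    snp2 = np.repeat([c[1] for c in cells], n_per_cell).astype(float)
    n = 4 * n_per_cell
    cov = np.column_stack(
        [
            rng.integers(0, 2, size=n).astype(float),
            rng.normal(25, 5, size=n),
            rng.normal(12, 3, size=n),
        ]
    )
    ids = [f"s{i:03d}" for i in range(n)]
    return DesignSpec(
        snp1=snp1, snp2=snp2, covariates=cov, subject_ids=ids,
        snp1_levels=("GG", "CG"), snp2_levels=("TT", "GT"),
    )


# ---------------------------------------------------------------------------
# GLM F
# ---------------------------------------------------------------------------

class TestConnectionGLM:
    def test_f_matches_rss_ratio_oracle(self):
        rng = np.random.default_rng(1)
        design = make_design(8, seed=2)
        y = rng.normal(size=design.n)
        out = fit_connection_glm(y, design)
        X = design.full_matrix()
        n, k = X.shape
        rss = lambda M: float(
            np.sum((y - M @ np.linalg.lstsq(M, y, rcond=None)[0]) ** 2)
        )
        rss_full = rss(X)
        for family, col in [("snp1", 1), ("snp2", 2), ("interaction", 3)]:
            rss_red = rss(np.delete(X, col, axis=1))
            F_oracle = (rss_red - rss_full) / (rss_full / (n - k))
            assert out[family]["F"] == pytest.approx(F_oracle, abs=1e-8)
            assert out[family]["p"] == pytest.approx(
                stats.f.sf(F_oracle, 1, n - k), abs=1e-10
            )

    def test_exact_cell_shift_recovered_without_interaction(self):
        # hand-constructed ANOVA: pure snp1 shift, zero noise
        design = make_design(10, seed=3)
        delta = 0.7
        y = delta * design.snp1  # no noise, no interaction
        out = fit_connection_glm(y, design)
        assert out["snp1"]["p"] < 1e-12
        assert out["snp1"]["estimate"] == pytest.approx(delta, abs=1e-8)
        assert out["interaction"]["F"] == pytest.approx(0.0, abs=1e-6)

    def test_type_one_error_calibrated(self):
        """Null strengths give uniform p: rejection rate near 5%."""
        rng = np.random.default_rng(4)
        design = make_design(8, seed=5)
        hits = 0
        reps = 2000
        for _ in range(reps):
            y = rng.normal(size=design.n)
            hits += fit_connection_glm(y, design)["snp1"]["p"] < 0.05
        # binomial 99% interval around 0.05 with 2000 reps
        assert abs(hits / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_confounded_covariate_dropped_with_valid_result(self):
        # rank policy: a covariate identical to a factor is degenerate and
        # is dropped; the factor tests remain well defined
        design = make_design(6, seed=6)
        design.covariates[:, 0] = design.snp1  # gender equals the factor
        y = np.random.default_rng(0).normal(size=design.n)
        out = fit_connection_glm(y, design)
        assert all(np.isfinite(out[f]["F"]) for f in out)
        assert all(0 <= out[f]["p"] <= 1 for f in out)

    def test_empty_joint_cell_interaction_untestable(self):
        design = make_design(8, seed=19)
        keep = ~((design.snp1 == 1) & (design.snp2 == 1))
        sub = DesignSpec(
            snp1=design.snp1[keep], snp2=design.snp2[keep],
            covariates=design.covariates[keep],
            subject_ids=[s for s, k in zip(design.subject_ids, keep) if k],
            snp1_levels=design.snp1_levels, snp2_levels=design.snp2_levels,
        )
        y = np.random.default_rng(1).normal(size=sub.n)
        out = fit_connection_glm(y, sub)
        assert out["interaction"]["p"] == 1.0
        assert np.isfinite(out["snp1"]["F"]) and np.isfinite(out["snp2"]["F"])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mw_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all group labelings."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = stats.rankdata(pooled)
    def u_of(idx):
        return ranks[list(idx)].sum() - na * (na + 1) / 2
    u_obs = u_of(range(na))
    mu = na * len(b) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_of(comb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_all_ties_p_one(self):
        _, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=5)
        ua, pa = mann_whitney_u(a, b)
        ub, pb = mann_whitney_u(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))
        assert pa == pytest.approx(pb)

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 3), (4, 4), (3, 5), (4, 6), (2, 8)])
    def test_exact_p_equals_full_enumeration(self, na, nb, rng):
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mw_enumeration_oracle(a, b), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def bh_stepup_oracle(pvals, q):
    """Classical step-up: largest i with p_(i) <= i*q/m; flag those."""
    m = len(pvals)
    order = np.argsort(pvals)
    flags = np.zeros(m, dtype=bool)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            k = rank
    flags[order[:k]] = True
    return flags


class TestBHFDR:
    def test_all_p_one_no_flags(self):
        _, flags = bh_fdr([1.0] * 5, 0.05)
        assert not flags.any()

    def test_stepup_example_all_flagged(self):
        q, flags = bh_fdr([0.001, 0.008, 0.039, 0.041], 0.05)
        assert flags.all()
        assert (q <= 0.05).all()

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=200, deadline=None)
    def test_flags_match_stepup_enumeration(self, pvals, q):
        pvals = np.asarray(pvals)
        _, flags = bh_fdr(pvals, q)
        np.testing.assert_array_equal(flags, bh_stepup_oracle(pvals, q))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_threshold(self, pvals):
        _, strict = bh_fdr(pvals, 0.01)
        _, loose = bh_fdr(pvals, 0.05)
        assert strict.sum() <= loose.sum()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)

    def test_q_never_below_p(self, rng):
        p = rng.uniform(size=30)
        q, _ = bh_fdr(p, 0.05)
        assert (q >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_strictly_increasing_rho_one(self):
        rho, _ = spearman_correlate([1, 2, 5, 9], [0.1, 0.4, 0.5, 2.0])
        assert rho == pytest.approx(1.0)

    def test_strictly_decreasing_rho_minus_one(self):
        rho, _ = spearman_correlate([1, 2, 3], [5, 4, 0])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 6.0, 6.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_correlate(x, y)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho1, p1 = spearman_correlate(x, y)
        rho2, p2 = spearman_correlate(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_missing_pairs_deleted(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.5, 2.5, 3.0, np.nan, 5.5]
        rho, _ = spearman_correlate(x, y)
        assert rho == pytest.approx(1.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlate([1.0, 1.0, 1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_correlate([1.0, np.nan], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Effect table / simple effects / volumes / correlations
# ---------------------------------------------------------------------------

def strengths_frame(design, rng, effect=None):
    """90-connection strengths table with an optional planted effect."""
    from fstgc import PathwayDefinition, connection_name

    conns = [connection_name(s, t) for s, t in PathwayDefinition().connections()]
    data = rng.normal(0, 0.1, size=(design.n, len(conns)))
    df = pd.DataFrame(data, index=design.subject_ids, columns=conns)
    if effect:
        conn, family, delta = effect
        carrier = {
            "snp1": design.snp1, "snp2": design.snp2,
            "interaction": design.interaction,
        }[family]
        df[conn] += delta * carrier
    return df


class TestEffectTable:
    def test_three_families_per_connection_with_family_fdr(self, rng):
        design = make_design(8, seed=7)
        table = effect_table(strengths_frame(design, rng), design, 0.01)
        assert len(table) == 270
        assert set(table["family"]) == {"snp1", "snp2", "interaction"}
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert (table.loc[table["significant"], "q"] <= 0.01).all()

    def test_planted_effect_flagged_in_its_family(self, rng):
        design = make_design(12, seed=8)
        df = strengths_frame(design, rng, effect=("L.dLPFC->R.dLPFC", "snp1", 0.4))
        table = effect_table(df, design, 0.01)
        hit = table[
            (table["connection"] == "L.dLPFC->R.dLPFC") & (table["family"] == "snp1")
        ].iloc[0]
        assert hit["significant"]
        assert hit["estimate"] == pytest.approx(0.4, abs=0.1)

    def test_cell_summaries_present(self, rng):
        design = make_design(5, seed=9)
        table = effect_table(
            strengths_frame(design, rng).iloc[:, :3], design, 0.01
        )
        for cell in ["GG/TT", "GG/GT", "CG/TT", "CG/GT"]:
            assert f"mean_{cell}" in table.columns
            assert (table[f"n_{cell}"] == 5).all()


class TestSimpleEffects:
    def test_no_flagged_connections_empty_table(self, rng):
        design = make_design(6, seed=10)
        out = simple_effects(strengths_frame(design, rng), design, [])
        assert len(out) == 0

    def test_contrast_labels_are_within_level_comparisons(self, rng):
        design = make_design(6, seed=11)
        df = strengths_frame(design, rng)
        out = simple_effects(df, design, ["L.dLPFC->R.dLPFC"])
        labels = set(out["contrast"])
        assert "CG/GT vs. GG/GT" in labels  # vary snp1 within snp2=GT
        assert "GG/GT vs. GG/TT" in labels  # vary snp2 within snp1=GG
        assert len(out) == 4

    def test_cell_specific_effect_detected_with_power(self):
        """Effect planted in one joint cell: its contrasts are the ones
        that fire (delta = 1 sd, 30 per cell)."""
        hits_target = 0
        hits_unrelated = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(20_000 + seed)
            design = make_design(30, seed=12)
            df = strengths_frame(design, rng).iloc[:, :5]
            cell_mask = (design.snp1 == 1) & (design.snp2 == 1)
            df.loc[cell_mask, df.columns[0]] += 0.1  # 1 sd of the 0.1-noise
            out = simple_effects(df, design, [df.columns[0]], q_threshold=0.05)
            tgt = out[out["contrast"] == "CG/GT vs. GG/GT"]
            unrel = out[out["contrast"] == "GG/GT vs. GG/TT"]
            hits_target += bool(tgt["significant"].any())
            hits_unrelated += bool(unrel["significant"].any())
        assert hits_target / reps >= 0.8
        assert hits_unrelated / reps <= 0.2


class TestVolumeGroupTest:
    def volumes(self, design, rng, shift_region=None, shift=0.0, confound=None):
        regions = ["L.Caudate", "R.Caudate", "L.Thalamus", "R.Thalamus"]
        data = rng.normal(5.0, 0.3, size=(design.n, len(regions)))
        df = pd.DataFrame(data, index=design.subject_ids, columns=regions)
        if shift_region:
            df[shift_region] += shift * design.snp1
        if confound is not None:
            df["L.Caudate"] += confound
        return df

    def covariates(self, design):
        return pd.DataFrame(
            {
                "subject_id": design.subject_ids,
                "gender": design.covariates[:, 0],
                "age": design.covariates[:, 1],
                "edu": design.covariates[:, 2],
            }
        )

    def groups(self, design):
        return pd.Series(
            np.where(design.snp1 == 0, "GG", "CG"),
            index=design.subject_ids, name="group",
        )

    def test_identical_groups_null(self, rng):
        design = make_design(8, seed=13)
        vol = self.volumes(design, rng) * 0 + 5.0
        out = volume_group_test(vol, self.groups(design), self.covariates(design))
        assert (out["t"] == 0).all()
        assert (out["p"] == 1).all()

    def test_planted_shift_detected_with_power(self):
        hits_target = 0
        hits_other = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(30_000 + seed)
            design = make_design(12, seed=14)  # 24 per marginal snp1 group
            vol = self.volumes(design, rng, "R.Thalamus", shift=1.5 * 0.3)
            out = volume_group_test(
                vol, self.groups(design), self.covariates(design), q_threshold=0.01
            )
            out = out.set_index("region")
            hits_target += bool(out.loc["R.Thalamus", "significant"])
            hits_other += bool(out.drop("R.Thalamus")["significant"].any())
        assert hits_target / reps >= 0.8
        assert hits_other / reps <= 0.1

    def test_covariate_explained_difference_not_flagged(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(40_000 + seed)
            design = make_design(8, seed=15)
            # group difference fully carried by age
            age_centred = design.covariates[:, 1] - design.covariates[:, 1].mean()
            vol = self.volumes(design, rng, confound=0.05 * age_centred)
            out = volume_group_test(
                vol, self.groups(design), self.covariates(design), q_threshold=0.01
            )
            hits += bool(out["significant"].any())
        assert hits / reps <= 0.1


class TestCorrelationTable:
    def test_rows_only_for_flagged_connections_and_subsets(self, rng):
        design = make_design(10, seed=16)
        df = strengths_frame(design, rng, effect=("L.dLPFC->R.dLPFC", "snp1", 0.5))
        effects = effect_table(df, design, 0.01)
        behavior = pd.DataFrame(
            rng.normal(size=(design.n, 2)),
            index=design.subject_ids, columns=["DUP", "VF"],
        )
        out = correlation_table(df, behavior, effects, design, 0.01)
        assert set(out["connection"]) <= set(
            effects.loc[effects["significant"], "connection"]
        )
        snp1_rows = out[out["family"] == "snp1"]
        assert set(snp1_rows["subset"]) <= {"GG", "CG"}
        assert (out["n"] >= 3).all()
        assert out["rho"].between(-1, 1).all()

    def test_planted_coupling_recovered(self, rng):
        design = make_design(12, seed=17)
        df = strengths_frame(design, rng, effect=("L.dLPFC->R.dLPFC", "snp1", 0.5))
        effects = effect_table(df, design, 0.01)
        strength = df["L.dLPFC->R.dLPFC"]
        behavior = pd.DataFrame(
            {"DUP": 100 * strength + rng.normal(0, 1.0, size=design.n)},
            index=design.subject_ids,
        )
        out = correlation_table(df, behavior, effects, design, 0.01)
        rows = out[
            (out["connection"] == "L.dLPFC->R.dLPFC") & (out["scale"] == "DUP")
        ]
        assert len(rows) and (rows["rho"] > 0.5).all()


class TestEmpiricalFDR:
    def test_pipeline_fdr_within_bound(self):
        """Mixed null/non-null strengths: realised FDR stays near nominal."""
        q_nom = 0.05
        fdps = []
        design = make_design(10, seed=18)
        from fstgc import PathwayDefinition, connection_name

        conns = [connection_name(s, t) for s, t in PathwayDefinition().connections()]
        true = set(conns[:10])
        for seed in range(200):
            rng = np.random.default_rng(50_000 + seed)
            data = rng.normal(0, 0.1, size=(design.n, 90))
            df = pd.DataFrame(data, index=design.subject_ids, columns=conns)
            for c in true:
                df[c] += 0.25 * design.snp1
            table = effect_table(df, design, q_nom)
            snp1 = table[table["family"] == "snp1"]
            flagged = set(snp1.loc[snp1["significant"], "connection"])
            if flagged:
                fdps.append(len(flagged - true) / len(flagged))
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= 1.5 * q_nom


def test_build_design_from_subgroups():
    from fstgc.synthetic import paper_cell_genotypes
    from fstgc import assign_subgroups

    geno = paper_cell_genotypes()
    labels, _ = assign_subgroups(geno, "rs11146020", "rs3813296")
    rng = np.random.default_rng(0)
    pheno = pd.DataFrame(
        {
            "subject_id": sorted(geno["subject_id"].unique()),
            "gender": rng.choice(["M", "F"], size=55),
            "age": rng.normal(25, 5, size=55),
            "edu": rng.normal(12, 3, size=55),
        }
    )
    design = build_design(labels, pheno)
    assert design.n == 53
    assert design.snp1_levels == ("GG", "CG")
    assert design.snp2_levels == ("TT", "GT")
    # reference cell GG/TT carries code (0, 0)
    cells = design.cell_labels()
    assert ((design.snp1 == 0) & (design.snp2 == 0)).sum() == (cells == "GG/TT").sum()
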