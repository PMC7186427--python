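"""Genotype main/interaction inference on directed connections.

For every directed connection the per-subject signed path coefficient is
modelled by a general linear model with two two-level genotype factors
(reference genotype coded 0), their product, and gender, age and
education as covariates.  Each of the three effect families (SNP1 main,
SNP2 main, interaction) is tested by a full-versus-reduced residual
sum-of-squares F with one numerator degree of freedom and corrected by
Benjamini-Hochberg FDR within its own 90-connection family.  Connections
with a significant interaction receive simple-effect contrasts; flagged
connections are carried into Spearman brain-behavior correlation within
the genotype subsets that define the flag.  A rank-based Mann-Whitney U
on covariate-adjusted strengths accompanies every parametric test as a
robustness column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathway import EFFECT_FAMILIES, connection_name, parse_connection

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("gender", "age", "edu")


@dataclass
class DesignSpec:
    """Group-level design for the two-SNP GLM.

    ``snp1`` / ``snp2`` are 0/1 codings (reference genotype 0), the
    interaction is their product, and the covariates are gender (0/1),
    age and education in years.
    """

    snp1: np.ndarray
    snp2: np.ndarray
    covariates: np.ndarray  # n x 3: gender, age, edu
    subject_ids: list[str]
    snp1_levels: tuple[str, str]  # (reference, variant) genotype labels
    snp2_levels: tuple[str, str]

    @property
    def interaction(self) -> np.ndarray:
        return self.snp1 * self.snp2

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def full_matrix(self) -> np.ndarray:
        """Type-III style design: the factors enter effect-coded
        (centered at -1/2, +1/2) so that with the interaction in the
        model, dropping a main-effect column tests the factor's effect
        averaged over the other factor's levels rather than its simple
        effect at the reference level."""
        c1 = self.snp1 - 0.5
        c2 = self.snp2 - 0.5
        return np.column_stack(
            [np.ones(self.n), c1, c2, c1 * c2, self.covariates]
        )

    def cell_labels(self) -> pd.Series:
        g1 = np.where(self.snp1 == 0, self.snp1_levels[0], self.snp1_levels[1])
        g2 = np.where(self.snp2 == 0, self.snp2_levels[0], self.snp2_levels[1])
        return pd.Series(
            [f"{a}/{b}" for a, b in zip(g1, g2)], index=self.subject_ids
        )


def build_design(
    subgroups: pd.Series,
    phenotypes: pd.DataFrame,
    reference_genotypes: tuple[str, str] = ("GG", "TT"),
) -> DesignSpec:
    """Assemble the design from joint-cell labels and a phenotype table.

    ``subgroups`` maps subject_id to a "snp1geno/snp2geno" label (the
    output of subgroup assignment); ``phenotypes`` must carry gender,
    age and edu columns indexed or keyed by subject_id.
    """
    pheno = phenotypes.set_index("subject_id") if "subject_id" in phenotypes else phenotypes
    ids = [s for s in subgroups.index if s in pheno.index]
    if len(ids) < len(subgroups):
        missing = sorted(set(subgroups.index) - set(ids))
        raise ValueError(f"phenotypes missing for subjects: {missing}")
    sub = subgroups.loc[ids]
    split = sub.str.split("/", expand=True)
    g1, g2 = split[0], split[1]
    ref1, ref2 = reference_genotypes
    lv1 = sorted(g1.unique(), key=lambda g: (g != ref1, g))
    lv2 = sorted(g2.unique(), key=lambda g: (g != ref2, g))
    if len(lv1) != 2 or len(lv2) != 2:
        raise ValueError(
            f"factors must be two-level after subgrouping, got {lv1} and {lv2}"
        )
    gender = (
        pheno.loc[ids, "gender"].map({"M": 0.0, "F": 1.0}).astype(float)
        if pheno["gender"].dtype == object
        else pheno.loc[ids, "gender"].astype(float)
    )
    cov = np.column_stack(
        [
            gender.to_numpy(),
            pheno.loc[ids, "age"].to_numpy(dtype=float),
            pheno.loc[ids, "edu"].to_numpy(dtype=float),
        ]
    )
    return DesignSpec(
        snp1=(g1 != lv1[0]).to_numpy(dtype=float),
        snp2=(g2 != lv2[0]).to_numpy(dtype=float),
        covariates=cov,
        subject_ids=list(ids),
        snp1_levels=(lv1[0], lv1[1]),
        snp2_levels=(lv2[0], lv2[1]),
    )


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def fit_connection_glm(
    strengths: np.ndarray, design: DesignSpec
) -> dict[str, dict[str, float]]:
    """Full-versus-reduced F tests for the three effect families.

    For each family the reduced model drops that single column, so the
    numerator has one degree of freedom:
    F = (RSS_reduced - RSS_full) / (RSS_full / (n - k)).
    Also returns the family's coefficient in the full model as the
    effect estimate.
    """
    y = np.asarray(strengths, dtype=float).ravel()
    X = design.full_matrix()
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"too few subjects ({n}) for {k} design columns")

    interaction_testable = True
    if np.linalg.matrix_rank(X) < k:
        # degenerate covariate columns (e.g. constant gender) are dropped;
        # an interaction made collinear by an empty joint cell is reported
        # as untestable; collinear factor columns are unrecoverable
        base = X[:, :3]  # intercept + both factor codings
        if np.linalg.matrix_rank(base) < 3:
            raise ValueError("rank-deficient design (confounded factor columns)")
        cols = [0, 1, 2]
        if np.linalg.matrix_rank(X[:, :4]) == 4:
            cols.append(3)
        else:
            interaction_testable = False
            logger.warning(
                "interaction not estimable (empty joint cell); reporting p=1"
            )
        for j in range(4, k):
            if np.linalg.matrix_rank(X[:, cols + [j]]) == len(cols) + 1:
                cols.append(j)
            else:
                logger.warning("dropping degenerate covariate column %d", j - 4)
        X = X[:, cols]
        k = X.shape[1]

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss_full = float(resid @ resid)
    dof = n - k

    out: dict[str, dict[str, float]] = {}
    family_col = {"snp1": 1, "snp2": 2}
    if interaction_testable:
        family_col["interaction"] = 3
    for family, col in family_col.items():
        X_red = np.delete(X, col, axis=1)
        rss_red = _ols_rss(X_red, y)
        F = max(0.0, (rss_red - rss_full)) / (rss_full / dof) if rss_full > 0 else np.inf
        p = float(stats.f.sf(F, 1, dof)) if np.isfinite(F) else 0.0
        out[family] = dict(estimate=float(coef[col]), F=float(F), p=p, dof_denom=dof)
    if not interaction_testable:
        out["interaction"] = dict(estimate=float("nan"), F=0.0, p=1.0, dof_denom=dof)
    return out


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    Exact p by enumeration of the rank distribution when the combined
    sample is small (n_a + n_b <= 12) and tie-free; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties and np.unique(pooled).size == 1:
        # all values identical: U at its null mean, no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_fdr(
    pvals: Sequence[float], q_threshold: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    flags = q <= q_threshold
    return q, flags


def spearman_correlate(
    strengths: Sequence[float], scores: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing pairs.

    rho is the Pearson correlation of midranks; the p-value uses the
    t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(strengths, dtype=float).ravel()
    y = np.asarray(scores, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired vectors required")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, have {x.size}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero rank variance in one variable")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Table-level stages
# ---------------------------------------------------------------------------

def _adjusted_strengths(y: np.ndarray, design: DesignSpec) -> np.ndarray:
    """Covariate-adjusted strengths for rank-based group comparisons.

    The covariate coefficients are estimated in the full model (factors
    included) and only the centred covariate contribution is subtracted;
    a pooled residualization would let covariate components that happen
    to correlate with the factors absorb part of the group effect.
    """
    X = design.full_matrix()
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    cov = design.covariates
    cov_centred = cov - cov.mean(axis=0)
    return y - cov_centred @ coef[4:]


def effect_table(
    strengths: pd.DataFrame,
    design: DesignSpec,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-connection statistics for all three effect families.

    ``strengths``: subjects x connections table of signed path
    coefficients (index must match the design's subject ids).  FDR is
    applied within each effect family across its connections.  Each row
    also carries the Mann-Whitney robustness test on covariate-adjusted
    strengths (marginal groups for main effects; the family's defining
    contrast) and the four joint-cell means and SDs.
    """
    data = strengths.loc[design.subject_ids]
    cells = design.cell_labels()
    cell_names = sorted(cells.unique())
    rows = []
    for conn in data.columns:
        y = data[conn].to_numpy(dtype=float)
        fam = fit_connection_glm(y, design)
        adj = _adjusted_strengths(y, design)
        groups = {
            "snp1": (adj[design.snp1 == 0], adj[design.snp1 == 1]),
            "snp2": (adj[design.snp2 == 0], adj[design.snp2 == 1]),
            "interaction": (
                adj[design.interaction == 0],
                adj[design.interaction == 1],
            ),
        }
        for family in EFFECT_FAMILIES:
            ga, gb = groups[family]
            if ga.size and gb.size:
                u, p_u = mann_whitney_u(ga, gb)
            else:  # empty contrast group (e.g. empty joint cell)
                u, p_u = float("nan"), float("nan")
            row = dict(
                connection=conn,
                family=family,
                estimate=fam[family]["estimate"],
                F=fam[family]["F"],
                p=fam[family]["p"],
                U=u,
                p_mannwhitney=p_u,
            )
            for cell in cell_names:
                vals = y[(cells == cell).to_numpy()]
                row[f"mean_{cell}"] = float(vals.mean()) if vals.size else np.nan
                row[f"sd_{cell}"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
                row[f"n_{cell}"] = int(vals.size)
            rows.append(row)
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    table["significant"] = False
    for family in EFFECT_FAMILIES:
        mask = table["family"] == family
        q, flags = bh_fdr(table.loc[mask, "p"].to_numpy(), q_threshold)
        table.loc[mask, "q"] = q
        table.loc[mask, "significant"] = flags
    return table


def simple_effects(
    strengths: pd.DataFrame,
    design: DesignSpec,
    flagged_connections: Sequence[str],
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Within-level contrasts for connections with a flagged interaction.

    For each flagged connection, within each level of one SNP the other
    SNP's genotypes are contrasted (covariate-adjusted mean difference
    plus Mann-Whitney on adjusted values), producing rows labelled like
    ``"CG/GT vs. GG/GT"``.
    """
    rows = []
    if not flagged_connections:
        return pd.DataFrame(
            columns=[
                "connection", "contrast", "n_a", "n_b",
                "mean_diff_adjusted", "U", "p", "q", "significant",
            ]
        )
    data = strengths.loc[design.subject_ids]
    cells = design.cell_labels().to_numpy()
    lv1, lv2 = design.snp1_levels, design.snp2_levels
    contrasts = []
    # vary SNP1 within each SNP2 level, then vary SNP2 within each SNP1 level
    for g2 in lv2:
        contrasts.append(((lv1[1], g2), (lv1[0], g2)))
    for g1 in lv1:
        contrasts.append(((g1, lv2[1]), (g1, lv2[0])))
    for conn in flagged_connections:
        y = data[conn].to_numpy(dtype=float)
        adj = _adjusted_strengths(y, design)
        for (a1, a2), (b1, b2) in contrasts:
            cell_a, cell_b = f"{a1}/{a2}", f"{b1}/{b2}"
            va = adj[cells == cell_a]
            vb = adj[cells == cell_b]
            if va.size == 0 or vb.size == 0:
                logger.warning(
                    "skipping contrast %s vs. %s for %s: empty cell",
                    cell_a, cell_b, conn,
                )
                continue
            u, p = mann_whitney_u(va, vb)
            rows.append(
                dict(
                    connection=conn,
                    contrast=f"{cell_a} vs. {cell_b}",
                    n_a=int(va.size),
                    n_b=int(vb.size),
                    mean_diff_adjusted=float(va.mean() - vb.mean()),
                    U=u,
                    p=p,
                )
            )
    table = pd.DataFrame(rows)
    if len(table):
        q, flags = bh_fdr(table["p"].to_numpy(), q_threshold)
        table["q"] = q
        table["significant"] = flags
    return table


def volume_group_test(
    volumes: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Covariate-adjusted two-group t-tests on per-region volumes.

    Each region is modelled as volume ~ intercept + group + gender +
    age + edu; the reported t is the group coefficient's t statistic
    (the two-sample t with covariates as regressors), with BH-FDR
    across regions.
    """
    vol = volumes.set_index("subject_id") if "subject_id" in volumes else volumes
    ids = [s for s in groups.index if s in vol.index]
    g = groups.loc[ids]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group labels, got {levels}")
    n_a = int((g == levels[0]).sum())
    n_b = int((g == levels[1]).sum())
    if min(n_a, n_b) < 3:
        raise ValueError(f"degenerate group sizes: {n_a} vs {n_b}")
    cov = covariates.set_index("subject_id") if "subject_id" in covariates else covariates
    gender = cov.loc[ids, "gender"]
    if gender.dtype == object:
        gender = gender.map({"M": 0.0, "F": 1.0})
    Z = np.column_stack(
        [
            np.ones(len(ids)),
            gender.to_numpy(dtype=float),
            cov.loc[ids, "age"].to_numpy(dtype=float),
            cov.loc[ids, "edu"].to_numpy(dtype=float),
        ]
    )
    mask_a = (g == levels[0]).to_numpy()
    X = np.column_stack([Z[:, :1], mask_a.astype(float), Z[:, 1:]])
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient volume design (confounded covariates)")
    dof = len(ids) - k
    xtx_inv = np.linalg.inv(X.T @ X)
    rows = []
    for region in vol.columns:
        y = vol.loc[ids, region].to_numpy(dtype=float)
        coefs = xtx_inv @ (X.T @ y)
        resid = y - X @ coefs
        s2 = float(resid @ resid) / dof
        se = np.sqrt(s2 * xtx_inv[1, 1])
        scale = max(float(np.abs(y).max()), 1.0)
        if se <= 1e-10 * scale:  # perfect fit: no residual variance
            t, p = 0.0, 1.0
        else:
            t = float(coefs[1] / se)
            p = float(2 * stats.t.sf(abs(t), dof))
        rows.append(
            dict(region=region, group_a=levels[0], group_b=levels[1],
                 n_a=n_a, n_b=n_b, t=t, p=p)
        )
    table = pd.DataFrame(rows)
    q, flags = bh_fdr(table["p"].to_numpy(), q_threshold)
    table["q"] = q
    table["significant"] = flags
    return table


def correlation_table(
    strengths: pd.DataFrame,
    behavior: pd.DataFrame,
    effect_flags: pd.DataFrame,
    design: DesignSpec,
    q_threshold: float = 0.01,
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman brain-behavior correlation for flagged connections.

    Runs within the genotype subsets defining each flag: the two
    genotype levels of the flagged SNP for main effects, the four joint
    cells for interaction flags.  Missing behavior values are dropped
    pairwise; rows with fewer than ``min_n`` complete pairs are
    suppressed.  BH-FDR across all reported rows.
    """
    flagged = effect_flags[effect_flags["significant"]]
    if not len(flagged):
        return pd.DataFrame(
            columns=["connection", "family", "subset", "scale",
                     "rho", "p", "n", "q", "significant"]
        )
    cells = design.cell_labels()
    split = cells.str.split("/", expand=True)
    subsets_by_family = {
        "snp1": {lev: split[0] == lev for lev in design.snp1_levels},
        "snp2": {lev: split[1] == lev for lev in design.snp2_levels},
        "interaction": {cell: cells == cell for cell in sorted(cells.unique())},
    }
    data = strengths.loc[design.subject_ids]
    beh = behavior.set_index("subject_id") if "subject_id" in behavior else behavior
    beh = beh.loc[design.subject_ids]
    rows = []
    for _, frow in flagged.iterrows():
        conn, family = frow["connection"], frow["family"]
        for subset_name, mask in subsets_by_family[family].items():
            idx = mask[mask].index
            for scale in beh.columns:
                x = data.loc[idx, conn].to_numpy(dtype=float)
                y = beh.loc[idx, scale].to_numpy(dtype=float)
                keep = np.isfinite(x) & np.isfinite(y)
                if keep.sum() < min_n:
                    logger.info(
                        "suppressing %s/%s/%s: only %d complete pairs",
                        conn, subset_name, scale, int(keep.sum()),
                    )
                    continue
                try:
                    rho, p = spearman_correlate(x[keep], y[keep])
                except ValueError:
                    continue
                rows.append(
                    dict(connection=conn, family=family, subset=subset_name,
                         scale=scale, rho=rho, p=p, n=int(keep.sum()))
                )
    table = pd.DataFrame(rows)
    if len(table):
        q, flags = bh_fdr(table["p"].to_numpy(), q_threshold)
        table["q"] = q
        table["significant"] = flags
    return table


@dataclass
class InferenceResults:
    """Bundle of all group-level output tables."""

    effects: pd.DataFrame
    simple_effects: pd.DataFrame
    correlations: pd.DataFrame
    volume_tests: pd.DataFrame


def run_full_inference(
    strengths: pd.DataFrame,
    subgroups: pd.Series,
    phenotypes: pd.DataFrame,
    volumes: pd.DataFrame | None = None,
    behavior_scales: Sequence[str] | None = None,
    q_threshold: float = 0.01,
    reference_genotypes: tuple[str, str] = ("GG", "TT"),
) -> InferenceResults:
    """Run the complete group-level analysis.

    Three effect families x all connections with per-family FDR, simple
    effects on flagged interactions, per-region volume contrasts between
    the extreme joint cells of every flagged family, and Spearman
    correlation of flagged connections against the behavioral scales.
    """
    design = build_design(subgroups, phenotypes, reference_genotypes)
    effects = effect_table(strengths, design, q_threshold)
    flagged_inter = effects[
        (effects["family"] == "interaction") & effects["significant"]
    ]["connection"].tolist()
    simples = simple_effects(strengths, design, flagged_inter, q_threshold)

    pheno = (
        phenotypes.set_index("subject_id")
        if "subject_id" in phenotypes
        else phenotypes
    )
    if behavior_scales is None:
        reserved = {
            "gender", "age", "edu", "motion_summary",
            "max_translation_mm", "max_rotation_deg",
        }
        behavior_scales = [c for c in pheno.columns if c not in reserved]
    behavior = pheno[list(behavior_scales)]
    correlations = correlation_table(
        strengths, behavior, effects, design, q_threshold
    )

    if volumes is not None:
        cells = design.cell_labels()
        # contrast the two marginal SNP1 groups (covariate-adjusted)
        split = cells.str.split("/", expand=True)
        groups = split[0]
        groups.name = "group"
        volume_tests = volume_group_test(
            volumes, groups, phenotypes, q_threshold
        )
    else:
        volume_tests = pd.DataFrame()
    return InferenceResults(effects, simples, correlations, volume_tests)
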