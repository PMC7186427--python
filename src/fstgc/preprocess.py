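"""Time-series conditioning, subject exclusion and genotype QC.

Tabular analogues of resting-state fMRI preprocessing applied to
region-averaged time courses: initial-volume discard, linear detrending,
ideal (frequency-domain) band-pass filtering and nuisance regression,
followed by head-motion exclusion and two-SNP subgroup assignment with
Hardy-Weinberg / minor-allele-frequency checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's time x region signal matrix.

    Parameters
    ----------
    subject_id : str
        Subject token, e.g. ``"sub-001"``.
    data : ndarray, shape (T, R)
        Region-averaged signal, one row per repetition time (TR).
    region_labels : tuple of str
        Column labels, unique, length R.
    tr_seconds : float
        Sampling interval in seconds.
    """

    subject_id: str
    data: np.ndarray
    region_labels: tuple[str, ...]
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if data.ndim != 2:
            raise ValueError("time series data must be 2-D (time x region)")
        if data.shape[0] < 2:
            raise ValueError("need at least two time points")
        if data.shape[1] != len(self.region_labels):
            raise ValueError(
                f"{data.shape[1]} columns but {len(self.region_labels)} labels"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if not np.isfinite(data).all():
            raise ValueError("time series contains non-finite values")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=list(self.region_labels))


# ---------------------------------------------------------------------------
# Time-series conditioning
# ---------------------------------------------------------------------------

def discard_initial(ts: ROITimeSeries, k: int) -> ROITimeSeries:
    """Drop the first ``k`` volumes (magnetisation-equilibration discard)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {k} of {ts.n_timepoints} time points"
        )
    if k == 0:
        return ts
    return replace(ts, data=ts.data[k:])


def detrend_linear(ts: ROITimeSeries) -> ROITimeSeries:
    """Subtract the per-region least-squares line (intercept + slope * t)."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least three time points to detrend")
    t = np.arange(ts.n_timepoints, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return replace(ts, data=ts.data - design @ coef)


def bandpass(ts: ROITimeSeries, low_hz: float, high_hz: float) -> ROITimeSeries:
    """Ideal band-pass: rectangular mask in the frequency domain.

    Frequencies in ``[low_hz, high_hz]`` are retained exactly; everything
    else (including the zero-frequency/DC component when ``low_hz > 0``)
    is zeroed.  This mirrors the ideal filtering applied by resting-state
    toolboxes rather than an IIR design.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(
            f"high_hz={high_hz:g} exceeds Nyquist {nyquist:g} Hz at "
            f"TR={ts.tr_seconds:g} s"
        )
    spectrum = np.fft.rfft(ts.data, axis=0)
    freqs = np.fft.rfftfreq(ts.n_timepoints, d=ts.tr_seconds)
    mask = (freqs >= low_hz - 1e-15) & (freqs <= high_hz + 1e-15)
    if low_hz > 0:
        mask[0] = False
    filtered = np.fft.irfft(spectrum * mask[:, None], n=ts.n_timepoints, axis=0)
    return replace(ts, data=filtered)


def bandpass_butterworth(
    ts: ROITimeSeries, low_hz: float, high_hz: float, order: int = 4
) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass, offered as an alternative filter."""
    from scipy.signal import butter, filtfilt

    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz > nyquist:
        raise ValueError(f"high_hz exceeds Nyquist {nyquist:g} Hz")
    b, a = butter(order, [low_hz / nyquist, high_hz / nyquist], btype="band")
    return replace(ts, data=filtfilt(b, a, ts.data, axis=0))


def regress_nuisance(ts: ROITimeSeries, covariates: np.ndarray) -> ROITimeSeries:
    """Remove the least-squares projection onto [intercept | covariates].

    Rank-deficient designs (e.g. duplicated covariate columns) are handled
    by the minimum-norm solution, which leaves residuals identical to
    those from the de-duplicated design; a warning is logged.
    """
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"covariate rows ({cov.shape[0]}) do not match T ({ts.n_timepoints})"
        )
    design = np.column_stack([np.ones(ts.n_timepoints), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "nuisance design rank %d < %d columns; degenerate columns ignored",
            rank,
            design.shape[1],
        )
    coef, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return replace(ts, data=ts.data - design @ coef)


def condition_timeseries(
    ts: ROITimeSeries,
    discard_k: int = 10,
    band: tuple[float, float] = (0.01, 0.1),
    nuisance: np.ndarray | None = None,
) -> ROITimeSeries:
    """Apply the full conditioning chain: discard, detrend, band-pass,
    nuisance regression.

    ``nuisance`` rows must align with the series either before or after
    the discard; the same rows are dropped.  The nuisance regressors are
    passed through the *same* detrend and band-pass as the data before
    regression — regressing unfiltered confounds on filtered data would
    reintroduce out-of-band mismatch and leave in-band confound signal
    behind.
    """
    out = discard_initial(ts, discard_k)
    out = detrend_linear(out)
    out = bandpass(out, *band)
    if nuisance is not None:
        cov = np.asarray(nuisance, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] == ts.n_timepoints:
            cov = cov[discard_k:]
        elif cov.shape[0] != out.n_timepoints:
            raise ValueError("nuisance rows match neither raw nor trimmed T")
        cov_ts = ROITimeSeries(
            subject_id=ts.subject_id,
            data=cov,
            region_labels=tuple(f"cov_{j}" for j in range(cov.shape[1])),
            tr_seconds=ts.tr_seconds,
        )
        cov_ts = bandpass(detrend_linear(cov_ts), *band)
        filt = cov_ts.data
        # drift-like regressors are annihilated by the detrend; drop them
        keep_cols = filt.std(axis=0) > 1e-10 * max(out.data.std(), 1e-30)
        if keep_cols.any():
            out = regress_nuisance(out, filt[:, keep_cols])
    return out


# ---------------------------------------------------------------------------
# Subject exclusion
# ---------------------------------------------------------------------------

def motion_exclude(
    records: pd.DataFrame | Iterable,
    trans_mm: float = 1.5,
    rot_deg: float = 1.5,
) -> tuple[list[str], list[str]]:
    """Split subjects into (kept, excluded) by head motion.

    A subject is excluded when max translation *exceeds* ``trans_mm`` or
    max rotation *exceeds* ``rot_deg`` — strictly greater, so a subject
    at exactly the threshold is kept.

    ``records`` is either a DataFrame with columns ``subject_id``,
    ``max_translation_mm`` and ``max_rotation_deg``, or an iterable of
    objects with those attributes.
    """
    if trans_mm <= 0 or rot_deg <= 0:
        raise ValueError("motion thresholds must be positive")
    if isinstance(records, pd.DataFrame):
        rows = records.to_dict("records")
        getter = lambda r, f: r.get(f)  # noqa: E731
        sid = lambda r: r.get("subject_id")  # noqa: E731
    else:
        rows = list(records)
        getter = getattr
        sid = lambda r: getattr(r, "subject_id")  # noqa: E731

    missing = [
        str(sid(r))
        for r in rows
        if getter(r, "max_translation_mm") is None
        or getter(r, "max_rotation_deg") is None
        or not np.isfinite(getter(r, "max_translation_mm"))
        or not np.isfinite(getter(r, "max_rotation_deg"))
    ]
    if missing:
        raise ValueError(f"missing motion fields for subjects: {missing}")

    kept, excluded = [], []
    for r in rows:
        s = str(sid(r))
        if getter(r, "max_translation_mm") > trans_mm or getter(r, "max_rotation_deg") > rot_deg:
            excluded.append(s)
            logger.info(
                "excluding %s: translation %.3f mm / rotation %.3f deg "
                "(thresholds %.2f / %.2f)",
                s,
                getter(r, "max_translation_mm"),
                getter(r, "max_rotation_deg"),
                trans_mm,
                rot_deg,
            )
        else:
            kept.append(s)
    return kept, excluded


# ---------------------------------------------------------------------------
# Genotype QC and subgrouping
# ---------------------------------------------------------------------------

def _wide_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Long (subject_id, snp_id, genotype) -> wide subject x SNP table."""
    required = {"subject_id", "snp_id", "genotype"}
    if required.issubset(genotypes.columns):
        return genotypes.pivot(
            index="subject_id", columns="snp_id", values="genotype"
        )
    return genotypes  # already wide: subjects x SNPs


def assign_subgroups(
    genotypes: pd.DataFrame,
    snp1: str,
    snp2: str,
    min_group_size: int = 3,
) -> tuple[pd.Series, list[str]]:
    """Cross-classify subjects by two SNPs, dropping rare genotype classes.

    Any *marginal* genotype class of either SNP with fewer than
    ``min_group_size`` carriers is removed together with its carriers
    (mirroring the exclusion of a two-subject homozygote class).  The
    downstream design treats each SNP as a two-level factor, so if more
    than two marginal classes survive, the smallest surplus classes are
    likewise excluded.  The remaining subjects are labelled by their
    joint cell, e.g. ``"GG/GT"`` (snp1 genotype / snp2 genotype).

    Returns
    -------
    labels : Series
        Joint-cell label indexed by subject_id, for kept subjects.
    excluded : list of str
        Subject ids removed with a rare genotype class.
    """
    wide = _wide_genotypes(genotypes)
    for snp in (snp1, snp2):
        if snp not in wide.columns:
            raise ValueError(f"SNP {snp!r} absent from genotype table")
        if wide[snp].isna().any():
            bad = wide.index[wide[snp].isna()].tolist()
            raise ValueError(f"missing {snp} genotype for subjects: {bad}")

    keep = pd.Series(True, index=wide.index)
    excluded: list[str] = []
    for snp in (snp1, snp2):
        counts = wide.loc[keep, snp].value_counts()
        drop = [g for g, n in counts.items() if n < min_group_size]
        # two-level factor: shed the smallest surplus classes as well
        surviving = counts.drop(drop).sort_values(ascending=False)
        drop += list(surviving.index[2:])
        for geno in drop:
            carriers = wide.index[keep & (wide[snp] == geno)].tolist()
            excluded.extend(str(c) for c in carriers)
            keep &= wide[snp] != geno
            logger.info(
                "dropping %s genotype %s (n=%d): subjects %s",
                snp, geno, int(counts[geno]), carriers,
            )

    kept = wide.loc[keep]
    labels = kept[snp1].str.cat(kept[snp2], sep="/")
    if labels.nunique() < 2:
        raise ValueError(
            "fewer than two surviving genotype cells; no contrast possible"
        )
    labels.name = "subgroup"
    return labels, excluded


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic SNP."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int
    major_allele: str = "A"
    minor_allele: str = "a"

    def __post_init__(self) -> None:
        if min(self.n_hom_major, self.n_het, self.n_hom_minor) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @classmethod
    def from_genotypes(
        cls, genotypes: Sequence[str], alleles: tuple[str, str] | None = None
    ) -> "GenotypeCounts":
        """Tally genotype strings like ``"CG"`` (allele order ignored)."""
        allele_counts: dict[str, int] = {}
        for g in genotypes:
            if len(g) != 2:
                raise ValueError(f"malformed genotype {g!r}")
            for a in g:
                allele_counts[a] = allele_counts.get(a, 0) + 1
        if alleles is None:
            if len(allele_counts) > 2:
                raise ValueError(f"more than two alleles seen: {allele_counts}")
            ordered = sorted(allele_counts, key=lambda a: (-allele_counts[a], a))
            if len(ordered) == 1:
                ordered.append(ordered[0])
            major, minor = ordered[0], ordered[-1]
        else:
            major, minor = alleles
        unknown = set(allele_counts) - {major, minor}
        if unknown:
            raise ValueError(f"alleles outside declared set: {sorted(unknown)}")
        n_maj = sum(1 for g in genotypes if set(g) == {major})
        n_min = sum(1 for g in genotypes if set(g) == {minor})
        n_het = len(genotypes) - n_maj - n_min
        return cls(n_maj, n_het, n_min, major, minor)


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the rarer allele, in [0, 0.5]."""
    if counts.total == 0:
        raise ValueError("no genotypes counted")
    freq = (2 * counts.n_hom_minor + counts.n_het) / (2 * counts.total)
    return min(freq, 1.0 - freq)


def hwe_test(
    counts: GenotypeCounts, method: Literal["chi2", "exact"] = "chi2"
) -> tuple[float, float]:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``chi2``: Pearson statistic sum((obs - exp)^2 / exp) against
    expectations p^2, 2pq, q^2 from the sample allele frequency, with one
    degree of freedom.

    ``exact``: conditional exact test enumerating all heterozygote counts
    compatible with the observed allele counts; the p-value sums the
    probabilities of outcomes no more likely than the observed one.
    """
    n = counts.total
    if n == 0:
        raise ValueError("no genotypes counted")
    n_minor_alleles = 2 * counts.n_hom_minor + counts.n_het

    if method == "chi2":
        q = n_minor_alleles / (2 * n)
        p = 1.0 - q
        expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
        observed = np.array(
            [counts.n_hom_major, counts.n_het, counts.n_hom_minor], dtype=float
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (observed - expected) ** 2 / expected
        chi2 = float(np.nansum(terms[expected > 0]))
        return chi2, float(stats.chi2.sf(chi2, df=1))

    if method == "exact":
        return _hwe_exact(n, n_minor_alleles, counts.n_het)

    raise ValueError(f"unknown method {method!r}")


def _hwe_exact(n: int, n_minor: int, obs_het: int) -> tuple[float, float]:
    """Levene-Haldane conditional distribution of the heterozygote count."""
    n_major = 2 * n - n_minor
    rare = min(n_minor, n_major)
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logprobs = []
    for h in hets:
        n_min_hom = (rare - h) // 2
        n_maj_hom = n - h - n_min_hom
        if n_maj_hom < 0:
            logprobs.append(-np.inf)
            continue
        lp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(n_maj_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_min_hom + 1)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logprobs.append(lp)
    logprobs = np.asarray(logprobs)
    probs = np.exp(logprobs - logprobs.max())
    probs /= probs.sum()
    idx = np.nonzero(hets == obs_het)[0]
    if idx.size == 0:
        raise ValueError(
            f"heterozygote count {obs_het} incompatible with allele counts"
        )
    p_obs = probs[idx[0]]
    pval = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return float(p_obs), min(pval, 1.0)
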