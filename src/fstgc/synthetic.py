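"""Synthetic imaging-genetics cohort generator.

Generates genotype-stratified cohorts whose directed-connectivity,
volumetric and behavioral structure matches the assumptions of the
downstream analysis: each subject's resting signal is a stationary
lag-1 vector autoregression over the ten pathway regions, with selected
cross-coefficients shifted by genotype; genotypes for two biallelic
SNPs are drawn under Hardy-Weinberg equilibrium; behavioral scores are
linearly coupled to selected true path strengths; and per-region
volumes carry genotype-cell mean shifts.

All randomness derives from a single master seed via per-subject
independent substreams, so changing the subject count never reshuffles
earlier subjects and the same seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pathway import DEFAULT_REGIONS, PathwayDefinition, connection_name
from .preprocess import ROITimeSeries

logger = logging.getLogger(__name__)

SNP1 = "rs11146020"  # GRIN1; ancestral allele G, variant C
SNP2 = "rs3813296"  # GRIA2; alleles G/T, minor G

#: major (reference) and minor allele per SNP
DEFAULT_ALLELES: dict[str, tuple[str, str]] = {SNP1: ("G", "C"), SNP2: ("T", "G")}
#: minor-allele frequencies of the simulated population
DEFAULT_MAF: dict[str, float] = {SNP1: 0.195, SNP2: 0.246}
#: reference genotype (coded 0 in the group design)
REFERENCE_GENOTYPES: dict[str, str] = {SNP1: "GG", SNP2: "TT"}

BEHAVIOR_SCALES: tuple[str, ...] = (
    "DUP", "SANS", "TMT", "BACS-SC", "HVLT-R", "WMS-III SS",
    "NAB-M", "BVMT-R", "VF", "MSCEIT-ME", "CPT-IP",
)

# population mean / sd used for uncoupled behavioral scores
_BEHAVIOR_BASE: dict[str, tuple[float, float]] = {
    "DUP": (31.0, 30.0),
    "SANS": (16.0, 12.0),
    "TMT": (42.0, 20.0),
    "BACS-SC": (50.0, 12.0),
    "HVLT-R": (22.5, 6.0),
    "WMS-III SS": (14.0, 3.5),
    "NAB-M": (13.5, 7.5),
    "BVMT-R": (23.0, 8.5),
    "VF": (20.0, 6.5),
    "MSCEIT-ME": (87.0, 16.0),
    "CPT-IP": (2.2, 1.0),
}

# nominal region volumes (cm^3, one hemisphere) for the volume table
_BASE_VOLUMES: dict[str, float] = {
    "L.dLPFC": 14.0, "R.dLPFC": 14.0,
    "L.Caudate": 3.6, "R.Caudate": 3.6,
    "L.Putamen": 4.5, "R.Putamen": 4.5,
    "L.Pallidum": 1.6, "R.Pallidum": 1.6,
    "L.Thalamus": 6.8, "R.Thalamus": 6.8,
}


@dataclass(frozen=True)
class EffectSpec:
    """A genotype-dependent shift of one directed VAR coefficient.

    ``delta`` is added to the (target, source) entry of the subject's
    transition matrix when the subject carries the non-reference level
    of ``factor`` (for ``interaction``, when the subject sits in the
    joint genotype ``cell``, e.g. ``"CG/GT"``).
    """

    source: str
    target: str
    factor: str  # "snp1" | "snp2" | "interaction"
    delta: float
    cell: str | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("effect connection must join distinct regions")
        if self.factor not in ("snp1", "snp2", "interaction"):
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.factor == "interaction" and self.cell is None:
            raise ValueError("interaction effects need a joint genotype cell")

    @property
    def connection(self) -> str:
        return connection_name(self.source, self.target)


@dataclass(frozen=True)
class NuisanceSpec:
    """Drift and pseudo-motion nuisance structure of the simulated scan."""

    drift_amplitude: float = 0.5
    n_motion: int = 6
    motion_sd: float = 1.0
    loading: float = 0.3  # nuisance loading relative to signal sd
    smooth_window: int = 5


def default_base_var(n_regions: int = 10) -> np.ndarray:
    """Stable lag-1 transition matrix for the ten-region pathway.

    Diagonal autocorrelation 0.35 plus weak directed structure along
    the cortico-striato-pallido-thalamo-cortical loop.
    """
    A = np.eye(n_regions) * 0.35
    if n_regions == 10:
        idx = {lab: i for i, lab in enumerate(DEFAULT_REGIONS)}
        loop = [
            ("L.dLPFC", "L.Caudate", 0.10), ("R.dLPFC", "R.Caudate", 0.10),
            ("L.dLPFC", "L.Putamen", 0.08), ("R.dLPFC", "R.Putamen", 0.08),
            ("L.Caudate", "L.Pallidum", 0.10), ("R.Caudate", "R.Pallidum", 0.10),
            ("L.Putamen", "L.Pallidum", 0.08), ("R.Putamen", "R.Pallidum", 0.08),
            ("L.Pallidum", "L.Thalamus", 0.10), ("R.Pallidum", "R.Thalamus", 0.10),
            ("L.Thalamus", "L.dLPFC", 0.08), ("R.Thalamus", "R.dLPFC", 0.08),
        ]
        for src, tgt, w in loop:
            A[idx[tgt], idx[src]] = w
    return A


def default_effect_map() -> list[EffectSpec]:
    """Planted genotype effects mirroring the reported connection pattern:
    a SNP1 effect within bilateral dLPFC, a SNP2 effect on the descending
    prefrontal-striatal path, and an interaction on the ascending
    pallidum-to-prefrontal path."""
    return [
        EffectSpec("L.dLPFC", "R.dLPFC", "snp1", 0.2),
        EffectSpec("L.dLPFC", "R.Caudate", "snp2", 0.2),
        EffectSpec("R.Pallidum", "R.dLPFC", "interaction", 0.2, cell="CG/GT"),
    ]


def default_behavior_couplings() -> list[tuple[str, str, float, float]]:
    """(connection, scale, coupling, noise sd) tuples coupling scores to
    true path strengths, echoing the reported brain-behavior pattern."""
    return [
        (connection_name("L.dLPFC", "R.dLPFC"), "DUP", 120.0, 20.0),
        (connection_name("L.dLPFC", "R.Caudate"), "BVMT-R", 35.0, 5.0),
        (connection_name("R.Pallidum", "R.dLPFC"), "MSCEIT-ME", -65.0, 10.0),
    ]


@dataclass
class CohortConfig:
    """Full simulation recipe; the defaults are the study conditions."""

    n_subjects: int = 55
    n_timepoints: int = 170  # acquired volumes, before the discard
    tr_seconds: float = 3.0
    maf: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MAF))
    alleles: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_ALLELES)
    )
    region_labels: tuple[str, ...] = DEFAULT_REGIONS
    base_var: np.ndarray | None = None
    effect_map: list[EffectSpec] = field(default_factory=default_effect_map)
    innovation_sd: float = 1.0
    nuisance_spec: NuisanceSpec = field(default_factory=NuisanceSpec)
    behavior_couplings: list[tuple[str, str, float, float]] = field(
        default_factory=default_behavior_couplings
    )
    volume_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    volume_noise_frac: float = 0.05
    coefficient_jitter_sd: float = 0.05
    burn_in: int = 50
    min_group_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for snp, m in self.maf.items():
            if not 0 <= m <= 0.5:
                raise ValueError(f"MAF for {snp} outside [0, 0.5]: {m}")
        if self.base_var is None:
            self.base_var = default_base_var(len(self.region_labels))
        self.base_var = np.asarray(self.base_var, dtype=float)
        R = len(self.region_labels)
        if self.base_var.shape != (R, R):
            raise ValueError("base_var shape must match region count")
        if spectral_radius(self.base_var) >= 1:
            raise ValueError("base_var is not stable (spectral radius >= 1)")
        discard_and_order = 10 + 1
        if self.n_timepoints <= discard_and_order + self.nuisance_spec.n_motion:
            raise ValueError("n_timepoints too small for discard + model order")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.maf)

    def reference_genotype(self, snp: str) -> str:
        major, _ = self.alleles[snp]
        return major + major


@dataclass
class CohortBundle:
    """Everything the downstream pipeline consumes, in memory."""

    config: CohortConfig
    timeseries: list[ROITimeSeries]
    nuisance: dict[str, pd.DataFrame]  # subject_id -> T x q regressors
    genotypes: pd.DataFrame  # long: subject_id, snp_id, genotype
    phenotypes: pd.DataFrame  # one row per subject
    volumes: pd.DataFrame  # subject_id x region
    truth: dict


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------

def sample_genotypes(
    n: int,
    maf: Mapping[str, float],
    seed: int | np.random.Generator,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Draw genotypes under Hardy-Weinberg equilibrium.

    For minor-allele frequency m the genotype probabilities are
    (1-m)^2 homozygous major, 2m(1-m) heterozygous, m^2 homozygous
    minor.  Returns a long table (subject_id, snp_id, genotype) with
    alleles in sorted order within each genotype string.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alleles = dict(alleles or DEFAULT_ALLELES)
    rows = []
    for snp, m in maf.items():
        if not 0 <= m <= 0.5:
            raise ValueError(f"MAF for {snp} outside [0, 0.5]: {m}")
        major, minor = alleles.get(snp, ("A", "a"))
        genos = [
            "".join(sorted(major + major)),
            "".join(sorted(major + minor)),
            "".join(sorted(minor + minor)),
        ]
        probs = [(1 - m) ** 2, 2 * m * (1 - m), m**2]
        draws = rng.choice(3, size=n, p=probs)
        for i, d in enumerate(draws):
            rows.append((f"sub-{i + 1:03d}", snp, genos[d]))
    return pd.DataFrame(rows, columns=["subject_id", "snp_id", "genotype"])


def _factor_active(
    spec: EffectSpec,
    genotypes: Mapping[str, str],
    config: CohortConfig,
) -> bool:
    snp_ids = config.snp_ids
    snp1, snp2 = snp_ids[0], snp_ids[1] if len(snp_ids) > 1 else snp_ids[0]
    if spec.factor == "snp1":
        return genotypes[snp1] != config.reference_genotype(snp1)
    if spec.factor == "snp2":
        return genotypes[snp2] != config.reference_genotype(snp2)
    cell = f"{genotypes[snp1]}/{genotypes[snp2]}"
    return cell == spec.cell


def build_subject_var(
    base_var: np.ndarray,
    genotypes: Mapping[str, str],
    effect_map: Sequence[EffectSpec],
    config: CohortConfig | None = None,
    region_labels: Sequence[str] | None = None,
    jitter: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Apply genotype-conditional coefficient shifts to the base VAR.

    Each :class:`EffectSpec` delta is added to the (target, source)
    entry when the subject's genotypes activate the spec's factor
    level.  Optional per-subject ``jitter`` (connection -> shift) adds
    continuous variation.  The result must remain stationary.
    """
    config = config or CohortConfig()
    labels = list(region_labels or config.region_labels)
    A = np.array(base_var, dtype=float, copy=True)
    idx = {lab: i for i, lab in enumerate(labels)}
    for spec in effect_map:
        if spec.source not in idx or spec.target not in idx:
            raise ValueError(f"effect references unknown region: {spec}")
        if _factor_active(spec, genotypes, config):
            A[idx[spec.target], idx[spec.source]] += spec.delta
    if jitter:
        for conn, shift in jitter.items():
            src, tgt = conn.split("->")
            A[idx[tgt], idx[src]] += shift
    rho = spectral_radius(A)
    if rho >= 1:
        cell = "/".join(genotypes[s] for s in (config.snp_ids))
        raise ValueError(
            f"VAR for genotype cell {cell} unstable (spectral radius {rho:.3f})"
        )
    return A


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.apply_along_axis(
        lambda c: np.convolve(c, kernel, mode="same"), 0, x
    )


def simulate_timeseries(
    var: np.ndarray,
    T: int,
    innovation_sd: float,
    nuisance_spec: NuisanceSpec | None = None,
    burn_in: int = 50,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 3.0,
    region_labels: Sequence[str] | None = None,
    subject_id: str = "sub-000",
) -> tuple[ROITimeSeries, pd.DataFrame]:
    """Simulate x(t) = A x(t-1) + drift + loading * nuisance(t) + e(t).

    The innovations are iid Gaussian; ``burn_in`` initial samples are
    discarded so the retained series is (approximately) stationary.
    The nuisance regressors (slow drift plus smoothed pseudo-motion
    noise) are returned alongside for downstream regression.
    """
    A = np.asarray(var, dtype=float)
    R = A.shape[0]
    if A.shape != (R, R):
        raise ValueError("var must be square")
    if spectral_radius(A) >= 1:
        raise ValueError("unstable VAR (spectral radius >= 1)")
    if T <= 0:
        raise ValueError("T must be positive")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = nuisance_spec or NuisanceSpec()

    total = T + burn_in
    eps = rng.normal(0.0, innovation_sd, size=(total, R))
    x = np.zeros((total, R))
    for t in range(1, total):
        x[t] = A @ x[t - 1] + eps[t]
    x = x[burn_in:]

    # nuisance structure added on top of the autoregressive signal
    nuis_cols = {}
    signal_sd = x.std(axis=0).mean()
    drift = np.linspace(-1.0, 1.0, T)
    if spec.drift_amplitude > 0:
        drift_load = rng.normal(0.0, 1.0, size=R)
        x = x + spec.drift_amplitude * signal_sd * np.outer(drift, drift_load)
        nuis_cols["drift"] = drift
    if spec.n_motion > 0:
        motion = rng.normal(0.0, spec.motion_sd, size=(T, spec.n_motion))
        motion = _smooth(motion, spec.smooth_window)
        loadings = rng.normal(0.0, 1.0, size=(spec.n_motion, R))
        x = x + spec.loading * signal_sd * (motion @ loadings)
        for j in range(spec.n_motion):
            nuis_cols[f"motion_{j + 1}"] = motion[:, j]

    labels = tuple(region_labels or [f"R{i + 1}" for i in range(R)])
    ts = ROITimeSeries(
        subject_id=subject_id, data=x, region_labels=labels, tr_seconds=tr_seconds
    )
    return ts, pd.DataFrame(nuis_cols, dtype=float)


def simulate_behavior(
    path_strengths: pd.DataFrame,
    couplings: Sequence[tuple[str, str, float, float]],
    seed: int | np.random.Generator = 0,
    scales: Sequence[str] = BEHAVIOR_SCALES,
) -> pd.DataFrame:
    """Behavioral scores linearly coupled to true path strengths.

    ``path_strengths`` is a subjects x connections table of true VAR
    coefficients; each coupling (connection, scale, coefficient,
    noise sd) sets  scale = base_mean + coefficient * strength + noise.
    Uncoupled scales are pure population noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(path_strengths)
    out = {}
    coupled = {scale: (conn, coef, noise) for conn, scale, coef, noise in couplings}
    for conn, scale, *_ in couplings:
        if conn not in path_strengths.columns:
            raise ValueError(f"unknown connection in coupling: {conn!r}")
        if scale not in scales:
            raise ValueError(f"unknown behavioral scale: {scale!r}")
    # one substream per scale, so adding subjects or scales never
    # reshuffles the draws of the others
    streams = rng.spawn(len(scales))
    for scale, srng in zip(scales, streams):
        mean, sd = _BEHAVIOR_BASE.get(scale, (0.0, 1.0))
        if scale in coupled:
            conn, coef, noise_sd = coupled[scale]
            strength = path_strengths[conn].to_numpy(dtype=float)
            vals = mean + coef * (strength - strength.mean()) + srng.normal(
                0.0, noise_sd, size=n
            )
        else:
            vals = srng.normal(mean, sd, size=n)
        out[scale] = vals
    return pd.DataFrame(out, index=path_strengths.index)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def _subject_rng(master_seed: int, stream: int, subject: int = 0) -> np.random.Generator:
    """Independent substream; subject count changes never reshuffle
    earlier subjects because each stream is keyed, not sequential."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream, subject))
    return np.random.default_rng(ss)


def simulate_cohort(
    config: CohortConfig,
    genotype_override: pd.DataFrame | None = None,
) -> CohortBundle:
    """Generate the complete dataset bundle for one cohort.

    ``genotype_override`` replaces the Hardy-Weinberg draw with a fixed
    long-format genotype table (for reproducing specific cell counts).
    """
    n = config.n_subjects
    if genotype_override is not None:
        genotypes = genotype_override.copy()
        ids = sorted(genotypes["subject_id"].unique())
        if len(ids) != n:
            raise ValueError(
                f"override has {len(ids)} subjects, config expects {n}"
            )
    else:
        # per-subject genotype substreams keep earlier subjects fixed
        # when the cohort grows
        rows = []
        for k in range(n):
            grng = _subject_rng(config.seed, 0, k)
            sid = f"sub-{k + 1:03d}"
            for snp, m in config.maf.items():
                major, minor = config.alleles.get(snp, ("A", "a"))
                genos = [
                    "".join(sorted(major + major)),
                    "".join(sorted(major + minor)),
                    "".join(sorted(minor + minor)),
                ]
                probs = [(1 - m) ** 2, 2 * m * (1 - m), m**2]
                rows.append((sid, snp, genos[grng.choice(3, p=probs)]))
        genotypes = pd.DataFrame(
            rows, columns=["subject_id", "snp_id", "genotype"]
        )
        ids = sorted(genotypes["subject_id"].unique())

    wide = genotypes.pivot(index="subject_id", columns="snp_id", values="genotype")
    conn_names = [connection_name(s.source, s.target) for s in config.effect_map]
    conn_names += [c for c, *_ in config.behavior_couplings]

    timeseries: list[ROITimeSeries] = []
    nuisance: dict[str, pd.DataFrame] = {}
    strengths = pd.DataFrame(index=ids, columns=sorted(set(conn_names)), dtype=float)
    pheno_rows = []
    vol_rows = []
    region_list = list(config.region_labels)

    # jitter gives behavioral couplings a continuous substrate: only the
    # connections a scale is coupled to receive per-subject variation,
    # genotype effects elsewhere stay deterministic per cell
    jitter_conns = sorted({c for c, *_ in config.behavior_couplings})
    for k, sid in enumerate(ids):
        geno = wide.loc[sid].to_dict()
        rng = _subject_rng(config.seed, 1, k)
        jitter = {
            conn: rng.normal(0.0, config.coefficient_jitter_sd)
            for conn in jitter_conns
        }
        A = build_subject_var(
            config.base_var, geno, config.effect_map, config, jitter=jitter
        )
        idx = {lab: i for i, lab in enumerate(region_list)}
        for conn in strengths.columns:
            src, tgt = conn.split("->")
            strengths.loc[sid, conn] = A[idx[tgt], idx[src]]

        ts, nuis = simulate_timeseries(
            A,
            config.n_timepoints,
            config.innovation_sd,
            config.nuisance_spec,
            burn_in=config.burn_in,
            seed=rng,
            tr_seconds=config.tr_seconds,
            region_labels=config.region_labels,
            subject_id=sid,
        )
        timeseries.append(ts)
        nuisance[sid] = nuis

        # demographics and motion
        prng = _subject_rng(config.seed, 2, k)
        gender = "M" if prng.random() < 0.5 else "F"
        age = float(np.clip(prng.normal(25.0, 6.0), 18, 45))
        edu = float(np.clip(prng.normal(12.7, 3.0), 6, 22))
        motion_summary = float(abs(prng.normal(0.36, 0.21)))
        max_trans = float(prng.gamma(2.0, 0.25))
        max_rot = float(prng.gamma(2.0, 0.25))
        pheno_rows.append(
            dict(
                subject_id=sid,
                gender=gender,
                age=round(age, 1),
                edu=round(edu, 1),
                motion_summary=motion_summary,
                max_translation_mm=max_trans,
                max_rotation_deg=max_rot,
            )
        )

        # volumes with genotype-cell shifts
        vrng = _subject_rng(config.seed, 3, k)
        snp_ids = config.snp_ids
        cell = "/".join(geno[s] for s in snp_ids)
        vols = {"subject_id": sid}
        for region in region_list:
            base = _BASE_VOLUMES.get(region, 5.0)
            shift = config.volume_effects.get((region, cell), 0.0)
            vols[region] = float(
                base + shift + vrng.normal(0.0, config.volume_noise_frac * base)
            )
        vol_rows.append(vols)

    behavior = simulate_behavior(
        strengths,
        config.behavior_couplings,
        _subject_rng(config.seed, 4),
    )
    phenotypes = pd.DataFrame(pheno_rows).set_index("subject_id")
    phenotypes = phenotypes.join(behavior)
    phenotypes = phenotypes.reset_index()
    volumes = pd.DataFrame(vol_rows)

    truth = {
        "seed": config.seed,
        "effects": [
            dict(
                connection=s.connection,
                factor=s.factor,
                delta=s.delta,
                cell=s.cell,
            )
            for s in config.effect_map
        ],
        "behavior_couplings": [
            dict(connection=c, scale=s, coupling=co, noise_sd=nsd)
            for c, s, co, nsd in config.behavior_couplings
        ],
        "volume_effects": {
            f"{region}|{cell}": shift
            for (region, cell), shift in config.volume_effects.items()
        },
        "true_strengths": {
            str(sid): {c: float(strengths.loc[sid, c]) for c in strengths.columns}
            for sid in ids
        },
    }
    return CohortBundle(
        config=config,
        timeseries=timeseries,
        nuisance=nuisance,
        genotypes=genotypes,
        phenotypes=phenotypes,
        volumes=volumes,
        truth=truth,
    )


def paper_cell_genotypes(
    cells: Mapping[tuple[str, str], int] | None = None,
    n_rare: int = 2,
    rare_genotype: str = "GG",
) -> pd.DataFrame:
    """Fixed genotype assignment reproducing the reported joint cells.

    Default cells: 14 GG/GT, 17 GG/TT, 10 CG/GT, 12 CG/TT, plus
    ``n_rare`` carriers of the rare rs3813296 GG class (excluded by
    subgroup assignment downstream).
    """
    if cells is None:
        cells = {
            ("GG", "GT"): 14,
            ("GG", "TT"): 17,
            ("CG", "GT"): 10,
            ("CG", "TT"): 12,
        }
    rows = []
    i = 0
    for (g1, g2), count in cells.items():
        for _ in range(count):
            i += 1
            sid = f"sub-{i:03d}"
            rows.append((sid, SNP1, g1))
            rows.append((sid, SNP2, g2))
    for _ in range(n_rare):
        i += 1
        sid = f"sub-{i:03d}"
        rows.append((sid, SNP1, "GG"))
        rows.append((sid, SNP2, rare_genotype))
    return pd.DataFrame(rows, columns=["subject_id", "snp_id", "genotype"])
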