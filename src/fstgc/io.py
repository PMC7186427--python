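"""File formats and run configuration.

All tables are tab-separated UTF-8 with a header row; floats are
serialised at 12 significant digits so every table round-trips through
its reader without loss at that precision.  Subject-level files are
discovered through a manifest rather than directory scanning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .preprocess import ROITimeSeries

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


@dataclass
class RunConfig:
    """Pipeline parameters plus either input paths or a simulate block."""

    out_dir: str = "fstgc_out"
    seed: int = 0
    discard_k: int = 10
    band: tuple[float, float] = (0.01, 0.1)
    trans_mm: float = 1.5
    rot_deg: float = 1.5
    order_p: int = 1
    q_threshold: float = 0.01
    min_group_size: int = 3
    tr_seconds: float = 3.0
    standardize: bool = True
    snp1: str = "rs11146020"
    snp2: str = "rs3813296"
    reference_genotypes: tuple[str, str] = ("GG", "TT")
    # either simulate... or point at existing tables
    simulate: dict | None = None
    timeseries_manifest: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    volumes_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.band = tuple(self.band)  # type: ignore[assignment]
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not 0 <= self.band[0] < self.band[1] <= nyquist + 1e-12:
            raise ValueError(
                f"band {self.band} invalid for TR={self.tr_seconds} "
                f"(Nyquist {nyquist:.4f} Hz)"
            )
        for name in ("trans_mm", "rot_deg", "q_threshold", "tr_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reference_genotypes" in raw:
            raw["reference_genotypes"] = tuple(raw["reference_genotypes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["band"] = list(self.band)
        d["reference_genotypes"] = list(self.reference_genotypes)
        return d


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    ts.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_timeseries(
    path: str | Path,
    tr_seconds: float,
    subject_id: str | None = None,
) -> ROITimeSeries:
    """Read a rectangular region x time table (header = region labels)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        if any(_is_number(tok) for tok in labels):
            raise ValueError(f"{path}:1: missing header row of region labels")
        if len(set(labels)) != len(labels):
            raise ValueError(f"{path}:1: duplicate region labels")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: ragged row "
                    f"({len(parts)} fields, expected {len(labels)})"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell: {exc}") from None
    return ROITimeSeries(
        subject_id=subject_id or path.stem.replace("_timeseries", ""),
        data=np.asarray(rows, dtype=float),
        region_labels=tuple(labels),
        tr_seconds=tr_seconds,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Genotypes and other tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genotypes(
    path: str | Path,
    allele_sets: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Read a long genotype table and normalise allele order.

    Columns: subject_id, snp_id, genotype.  ``"GC"`` and ``"CG"`` are
    the same unordered pair and normalise to the sorted form.  If
    ``allele_sets`` declares the alleles of a SNP, anything outside the
    set is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "snp_id", "genotype"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: genotype table needs columns {sorted(required)}"
        )
    df["genotype"] = df["genotype"].map(lambda g: "".join(sorted(g.strip())))
    if (df["genotype"].str.len() != 2).any():
        bad = df.loc[df["genotype"].str.len() != 2]
        raise ValueError(f"{path}: malformed genotypes:\n{bad}")
    if allele_sets:
        for snp, alleles in allele_sets.items():
            sub = df[df["snp_id"] == snp]
            seen = set("".join(sub["genotype"]))
            extra = seen - set(alleles)
            if extra:
                raise ValueError(
                    f"{path}: alleles {sorted(extra)} outside declared set "
                    f"{alleles} for {snp}"
                )
    return df


# ---------------------------------------------------------------------------
# Bundles and manifests
# ---------------------------------------------------------------------------

def write_bundle(bundle, out_dir: str | Path) -> Path:
    """Write a simulated cohort to disk in the pipeline's formats.

    Emits per-subject time-series and nuisance tables, genotypes.tsv,
    phenotypes.tsv, volumes.tsv, truth.json (planted effects, for tests)
    and a manifest listing every file.
    """
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for ts in bundle.timeseries:
        ts_path = ts_dir / f"{ts.subject_id}_timeseries.tsv"
        write_timeseries(ts, ts_path)
        nuis_path = ts_dir / f"{ts.subject_id}_nuisance.tsv"
        bundle.nuisance[ts.subject_id].to_csv(
            nuis_path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        entries.append(
            dict(
                subject_id=ts.subject_id,
                timeseries=str(ts_path.relative_to(out)),
                nuisance=str(nuis_path.relative_to(out)),
            )
        )
    write_table(bundle.genotypes, out / "genotypes.tsv")
    write_table(bundle.phenotypes, out / "phenotypes.tsv")
    write_table(bundle.volumes, out / "volumes.tsv")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    manifest = dict(
        seed=bundle.config.seed,
        tr_seconds=bundle.config.tr_seconds,
        n_subjects=bundle.config.n_subjects,
        subjects=entries,
    )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out / "manifest.json"


def read_bundle_files(manifest_path: str | Path, tr_seconds: float):
    """Load the per-subject time series + nuisance tables via a manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    series, nuisance = [], {}
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        series.append(
            read_timeseries(base / entry["timeseries"], tr_seconds, subject_id=sid)
        )
        nuisance[sid] = pd.read_csv(base / entry["nuisance"], sep="\t")
    return series, nuisance


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(out_dir: str | Path, config: RunConfig, outputs: list[str]) -> None:
    """Record config hash, seed and versions for bit-identical re-runs."""
    import fstgc

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = dict(
        config=config.to_dict(),
        config_sha256=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seed=config.seed,
        versions=dict(
            fstgc=fstgc.__version__,
            numpy=np.__version__,
            pandas=pd.__version__,
        ),
        outputs=sorted(outputs),
    )
    with open(Path(out_dir) / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
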