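"""TSV readers/writers, run configuration and region reports.

All interchange formats are tab-separated UTF-8 text with ``NA`` for
missing values (marker ids in legacy microsatellite lists can contain
commas, so TSV over CSV). Physical positions are stored internally in base
pairs and written as Mbp with six decimals, which round-trips losslessly at
base-pair resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .markers import MarkerMap, MarkerMapError
from .simulate import (
    CODE_TO_LETTER,
    LETTER_TO_CODE,
    GenotypePanel,
)
from .scan import RegionCall, ThresholdSet
from .strain_stats import validate_phenotypes

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A data file violates the interchange format."""


class ConfigError(ValueError):
    pass


# --------------------------------------------------------------------------
# marker map
# --------------------------------------------------------------------------

def write_map(marker_map: MarkerMap, path) -> None:
    df = marker_map.table.copy()
    out = pd.DataFrame(
        {
            "marker": df["marker"],
            "chrom": df["chrom"],
            "pos_mbp": (df["pos_bp"] / 1e6).map(lambda v: f"{v:.6f}"),
            "pos_cm": df["pos_cm"].map(lambda v: f"{v:.6f}"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker", "chrom", "pos_mbp", "pos_cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: marker map missing columns {missing}")
    try:
        table = pd.DataFrame(
            {
                "marker": df["marker"],
                "chrom": df["chrom"],
                "pos_bp": (df["pos_mbp"].astype(float) * 1e6).round().astype(np.int64),
                "pos_cm": df["pos_cm"].astype(float),
            }
        )
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric position ({exc})") from exc
    try:
        mmap = MarkerMap(table)
    except MarkerMapError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    logger.info("read marker map: %d markers from %s", mmap.n_markers, path)
    return mmap


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def write_genotypes(panel: GenotypePanel, path) -> None:
    """Rows = strains; columns: strain, family, then one column per marker
    with values A/B/H/NA."""
    frame = panel.to_frame()
    frame.insert(0, "family", panel.families)
    frame.insert(0, "strain", panel.strain_ids)
    frame.to_csv(path, sep="\t", index=False)


def read_genotypes(path, marker_map: MarkerMap) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("strain", "family"):
        if col not in df.columns:
            raise ParseError(f"{path}: genotype table missing column {col!r}")
    marker_cols = [c for c in df.columns if c not in ("strain", "family")]
    expected = list(marker_map.marker_ids)
    if marker_cols != expected:
        extra = set(marker_cols) - set(expected)
        missing = set(expected) - set(marker_cols)
        raise ParseError(
            f"{path}: marker columns disagree with map "
            f"(missing {len(missing)}, unexpected {len(extra)}, "
            f"or out of order)"
        )
    if df["strain"].duplicated().any():
        dup = df.loc[df["strain"].duplicated(), "strain"].iloc[0]
        raise ParseError(f"{path}: duplicate strain id {dup!r}")

    values = df[marker_cols].to_numpy()
    matrix = np.empty(values.shape, dtype=np.int8)
    for letter, code in LETTER_TO_CODE.items():
        matrix[values == letter] = code
    known = np.isin(values, list(LETTER_TO_CODE))
    if not known.all():
        r, c = np.argwhere(~known)[0]
        raise ParseError(
            f"{path}: unknown allele symbol {values[r, c]!r} at line {r + 2}, "
            f"marker {marker_cols[c]!r} (expected A/B/H/NA)"
        )
    panel = GenotypePanel(
        matrix, df["strain"].tolist(), df["family"].tolist(), marker_map
    )
    logger.info(
        "read genotypes: %d strains x %d markers from %s",
        panel.n_strains, panel.n_markers, path,
    )
    return panel


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno[["animal_id", "strain", "condition", "ige_ng_ml"]].to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    try:
        validate_phenotypes(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    logger.info("read phenotypes: %d records from %s", len(df), path)
    return df[["animal_id", "strain", "condition", "ige_ng_ml"]]


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full simulate -> stats -> scan -> report run.

    ``seed`` is mandatory: every stochastic stage (breeding, phenotype
    generation, permutations) draws from it, making runs byte-reproducible.
    """

    seed: int
    out_dir: str = "rcscan_out"
    genotypes: str | None = None
    phenotypes: str | None = None
    marker_map: str | None = None
    conditions: list[str] = field(
        default_factory=lambda: ["baseline", "OVA-PBS", "OVA-OVA"]
    )
    alpha: float = 0.05
    n_perm: int = 10_000
    n_markers: int = 1215
    n_acb: int = 10
    n_bca: int = 21
    n_backcrosses: int = 2
    qtl_marker: str | None = None
    qtl_effect: float = 1.5
    strain_variance: float = 0.25
    residual_variance: float = 0.5
    n_per_strain: list[int] = field(default_factory=lambda: [5, 20])
    make_plots: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is required")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        if "seed" not in raw:
            raise ConfigError(f"{path}: seed is required")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def format_region_row(region: RegionCall) -> dict:
    return {
        "condition": region.condition,
        "chrom": region.chromosome,
        "region_mbp": f"{region.start_mbp:.2f}–{region.end_mbp:.2f}",
        "peak_marker": region.peak_marker,
        "peak_p": f"{region.peak_p:.2e}",
        "n_markers": region.n_markers,
    }


def report_regions(
    regions: list[RegionCall],
    thresholds: list[ThresholdSet],
    path,
) -> None:
    """Write the region table (one row per significant region, positions in
    Mbp at 2 decimals, peak p in scientific notation) with a footer recording
    alpha, permutation count and the thresholds on both scales."""
    rows = [format_region_row(r) for r in regions]
    header = ["condition", "chrom", "region_mbp", "peak_marker", "peak_p", "n_markers"]
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(row[h]) for h in header))
    for thr in thresholds:
        lines.append(
            f"# condition={thr.condition} alpha={thr.alpha} n_perm={thr.n_perm} "
            f"threshold_neg_log10={thr.threshold_neg_log10:.3f} "
            f"threshold_p={thr.threshold_p:.3g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_scan(scan: pd.DataFrame, path) -> None:
    out = scan.copy()
    out["pos_mbp"] = out["pos_mbp"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_thresholds(thresholds: list[ThresholdSet], path) -> None:
    rows = [
        {
            "condition": t.condition,
            "alpha": t.alpha,
            "n_perm": t.n_perm,
            "threshold_neg_log10": f"{t.threshold_neg_log10:.10g}",
            "threshold_p": f"{t.threshold_p:.10g}",
            "seed": t.seed,
        }
        for t in thresholds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
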