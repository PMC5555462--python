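"""Marker-by-marker genome scan with permutation genome-wide thresholds.

The model regresses the per-strain mean log2 phenotype on parental-origin
genotype (coded 0 = C57BL/6J allele, 1 = A/J allele) one marker at a time;
for a binary regressor the slope t-test is exactly the pooled two-sample
t-test between the two allele classes. Genome-wide significance is
calibrated by the standard permutation construction: strain labels of the
phenotype vector are shuffled, the full scan re-run, and the empirical
(1 - alpha) quantile of the per-permutation maximum -log10(p) taken as the
threshold. Significant regions are maximal runs of contiguous significant
markers on one chromosome.

Usage follows the fitted-model idiom::

    model = GenomeScan.from_panels(pheno, genotypes, condition="baseline")
    res = model.fit()
    thr = res.permutation_threshold(alpha=0.05, n_perm=10000, seed=1)
    regions = res.call_regions(thr)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MarkerMap
from .simulate import GenotypePanel
from .strain_stats import validate_phenotypes

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Strain sets of the phenotype vector and genotype panel disagree."""


# --------------------------------------------------------------------------
# small numeric utilities
# --------------------------------------------------------------------------

def quantile_rule(values: np.ndarray, q: float) -> float:
    """Empirical quantile by the order-statistic ceiling rule.

    Returns the k-th smallest value with k = max(1, ceil(q * n)); q = 1
    gives the maximum. This type-1 convention makes the permutation
    threshold an actually-observed permutation statistic.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quantile of empty set")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile level must be in [0, 1], got {q}")
    k = max(1, math.ceil(q * values.size))
    return float(np.partition(values, k - 1)[k - 1])


def strain_means(
    pheno: pd.DataFrame, condition: str, exclude: tuple[str, ...] = ()
) -> pd.Series:
    """Per-strain mean of log2(IgE) in one condition.

    Strains listed in ``exclude`` (typically the parental and consomic
    strains, whose genome-wide constant genotypes would confound
    single-marker effects) are dropped from the scan response.
    """
    pheno = validate_phenotypes(pheno)
    sub = pheno[pheno["condition"] == condition]
    if sub.empty:
        logger.warning("no records in condition %r", condition)
        return pd.Series(dtype=float, name=condition)
    sub = sub[~sub["strain"].isin(exclude)]
    means = sub.groupby("strain", sort=False)["log2_ige"].mean()
    means.name = condition
    return means


# --------------------------------------------------------------------------
# vectorised scan core
# --------------------------------------------------------------------------

def _scan_complete(Y: np.ndarray, G: np.ndarray):
    """OLS slope + t statistics of every column of G against every row of Y.

    Y : (r, n) response rows (row 0 is the observed phenotype; additional
        rows are permutations). G : (n, m) genotype dosages without NaN.
    Returns beta, se, t (each (r, m)); columns with zero genotype variance
    yield NaN and must be masked by the caller.
    """
    r, n = Y.shape
    Gc = G - G.mean(axis=0)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sgg = (Gc ** 2).sum(axis=0)  # (m,)
    syy = (Yc ** 2).sum(axis=1)  # (r,)
    sgy = Yc @ Gc  # (r, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sgy / sgg
        rss = syy[:, None] - beta * sgy
        rss = np.maximum(rss, 0.0)
        df = n - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sgg)
        t = beta / se
        t[np.isnan(t)] = 0.0  # constant response: no association signal
    return beta, se, t


def _class_counts(G: np.ndarray):
    """Per-marker counts of strains in the A (1) and B (0) classes."""
    typed = ~np.isnan(G)
    n_a = np.nansum(G, axis=0)
    n_used = typed.sum(axis=0)
    return n_a.astype(int), (n_used - n_a).astype(int), n_used


@dataclass(frozen=True)
class ThresholdSet:
    """Permutation-derived genome-wide significance threshold for one
    condition, reported on both the -log10 and the p scale
    (``threshold_p = 10 ** -threshold_neg_log10`` exactly)."""

    condition: str
    alpha: float
    n_perm: int
    threshold_neg_log10: float
    seed: int | None = None

    @property
    def threshold_p(self) -> float:
        return 10.0 ** (-self.threshold_neg_log10)


@dataclass(frozen=True)
class RegionCall:
    """Maximal run of contiguous significant markers on one chromosome.

    ``start_mbp``/``end_mbp`` are the physical positions of the outermost
    significant markers (closed interval; a single-marker region has
    start == end); ``peak_p`` is the smallest p in the run."""

    condition: str
    chromosome: str
    start_mbp: float
    end_mbp: float
    peak_marker: str
    peak_p: float
    n_markers: int


class GenomeScan:
    """Marker-by-marker linear-regression genome scan model.

    Parameters
    ----------
    y : pandas.Series
        Strain-level response (mean log2 phenotype), indexed by strain id.
    genotypes : GenotypePanel
        Parental-origin genotype matrix covering at least the strains in y.
    condition : str
        Label carried through to results and thresholds.
    min_class_size : int
        Markers with fewer strains than this in either allele class are
        skipped (slope test degenerate otherwise). Heterozygous and missing
        calls are dropped per marker.
    """

    def __init__(
        self,
        y: pd.Series,
        genotypes: GenotypePanel,
        condition: str = "",
        min_class_size: int = 3,
    ):
        strains = list(y.index.astype(str))
        missing = [s for s in strains if s not in genotypes.strain_ids]
        if missing:
            raise AlignmentError(
                f"strains in phenotype but not genotype panel: {missing}"
            )
        panel = genotypes.subset(strains)
        self.y = y.to_numpy(dtype=float)
        self.strain_ids = strains
        self.panel = panel
        self.marker_map: MarkerMap = panel.marker_map
        self.condition = condition
        self.min_class_size = int(min_class_size)

        G = panel.dosage()
        self._complete = ~np.isnan(G).any(axis=0)
        self._G = G
        n_a, n_b, n_used = _class_counts(G)
        self._n_a, self._n_b, self._n_used = n_a, n_b, n_used
        monomorphic = (n_a == 0) | (n_b == 0)
        small = (np.minimum(n_a, n_b) < self.min_class_size) & ~monomorphic
        self._skip_reason = np.where(
            monomorphic, "monomorphic",
            np.where(small, f"class_size<{self.min_class_size}", ""),
        )
        self._valid = ~(monomorphic | small)

    @classmethod
    def from_panels(
        cls,
        pheno: pd.DataFrame,
        genotypes: GenotypePanel,
        condition: str,
        include_parentals: bool = False,
        min_class_size: int = 3,
    ) -> "GenomeScan":
        """Build the scan from animal-level phenotypes and a genotype panel.

        The response is the per-strain mean log2 phenotype; parental and
        consomic strains are excluded by default (their constant genotypes
        confound marker effects with whole-genome background).
        """
        exclude: tuple[str, ...] = ()
        if not include_parentals:
            fam = genotypes.family
            exclude = tuple(fam.index[fam.isin(["parental", "CSS"])])
        y = strain_means(pheno, condition, exclude=exclude)
        y = y[[s for s in y.index if s in genotypes.strain_ids]]
        if len(y) < 2:
            raise AlignmentError(
                f"fewer than two scanable strains in condition {condition!r}"
            )
        return cls(y, genotypes, condition=condition, min_class_size=min_class_size)

    # -- fitting ------------------------------------------------------------

    def _scan_rows(self, Y: np.ndarray):
        """Scan every response row in Y (r, n) over all valid markers.

        Returns beta, se, t, p arrays of shape (r, m) with NaN at skipped
        markers, plus the per-row maximum -log10 p over valid markers.
        """
        r, n = Y.shape
        m = self.panel.n_markers
        beta = np.full((r, m), np.nan)
        se = np.full((r, m), np.nan)
        t = np.full((r, m), np.nan)
        p = np.full((r, m), np.nan)

        fast = self._valid & self._complete
        if fast.any():
            b_, s_, t_ = _scan_complete(Y, self._G[:, fast])
            beta[:, fast], se[:, fast], t[:, fast] = b_, s_, t_
            p[:, fast] = 2.0 * stats.t.sf(np.abs(t_), n - 2)

        slow = np.flatnonzero(self._valid & ~self._complete)
        for j in slow:
            g = self._G[:, j]
            mask = ~np.isnan(g)
            nj = int(mask.sum())
            b_, s_, t_ = _scan_complete(Y[:, mask], g[mask][:, None])
            beta[:, j], se[:, j], t[:, j] = b_[:, 0], s_[:, 0], t_[:, 0]
            p[:, j] = 2.0 * stats.t.sf(np.abs(t_[:, 0]), nj - 2)
        return beta, se, t, p

    def fit(self) -> "GenomeScanResults":
        """Run the scan on the observed phenotype vector."""
        Y = self.y[None, :]
        beta, se, t, p = self._scan_rows(Y)
        with np.errstate(divide="ignore"):
            neg_log10 = -np.log10(p[0])
        table = pd.DataFrame(
            {
                "marker": self.marker_map.marker_ids,
                "chrom": self.marker_map.chrom,
                "pos_mbp": self.marker_map.pos_mbp,
                "n_used": self._n_used,
                "beta": beta[0],
                "se": se[0],
                "t_stat": t[0],
                "p": p[0],
                "neg_log10_p": neg_log10,
                "skipped": ~self._valid,
                "skip_reason": self._skip_reason,
            }
        )
        return GenomeScanResults(self, table)


class GenomeScanResults:
    """Fitted genome scan: per-marker association statistics plus methods
    for permutation thresholds, region calling, plotting and summaries."""

    def __init__(self, model: GenomeScan, scan: pd.DataFrame):
        self.model = model
        self.scan = scan
        self.condition = model.condition

    # -- permutation thresholds ---------------------------------------------

    def permutation_maxima(
        self, n_perm: int, seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Genome-wide maximum -log10(p) of each phenotype permutation."""
        if n_perm < 1:
            raise ValueError("n_perm must be positive")
        if not self.model._valid.any():
            raise ValueError("no testable markers: every marker is skipped")
        if rng is None:
            rng = np.random.default_rng(seed)
        n = len(self.model.y)
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        # permute the sorted values so the maxima depend only on the multiset
        # of strain means: thresholds are exactly invariant to strain
        # relabeling for a given seed
        Y = np.sort(self.model.y)[perm_idx]
        _, _, _, p = self.model._scan_rows(Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            min_p = np.nanmin(p, axis=1)
        return -np.log10(min_p)

    def permutation_threshold(
        self,
        alpha: float = 0.05,
        n_perm: int = 10_000,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> ThresholdSet:
        """Genome-wide significance threshold at level ``alpha``.

        The threshold is the empirical (1 - alpha) quantile (ceiling-rule
        order statistic) of the per-permutation maximum -log10(p); a marker
        is significant when its p is at or below ``threshold_p``.
        """
        if not 0.0 < alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {alpha}")
        if n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        maxima = self.permutation_maxima(n_perm, seed=seed, rng=rng)
        thr = quantile_rule(maxima, 1.0 - alpha)
        return ThresholdSet(
            condition=self.condition,
            alpha=alpha,
            n_perm=n_perm,
            threshold_neg_log10=thr,
            seed=seed,
        )

    # -- regions -------------------------------------------------------------

    def call_regions(
        self, threshold: ThresholdSet, max_gap: int = 0
    ) -> list[RegionCall]:
        """Delimit significant regions from the fitted scan (see
        :func:`call_regions`)."""
        return call_regions(
            self.scan, threshold, condition=self.condition, max_gap=max_gap
        )

    # -- presentation ----------------------------------------------------------

    def plot_manhattan(self, threshold: ThresholdSet | None = None, **kwargs):
        from .plotting import manhattan_plot

        return manhattan_plot(self.scan, threshold, **kwargs)

    def summary(self, threshold: ThresholdSet | None = None) -> str:
        sc = self.scan
        tested = sc[~sc["skipped"]]
        lines = [
            "Genome scan: strain-mean log2 phenotype ~ parental-origin genotype",
            f"condition: {self.condition or '(unlabelled)'}",
            f"strains: {len(self.model.y)}   markers: {len(sc)} "
            f"(tested {len(tested)}, skipped {int(sc['skipped'].sum())})",
        ]
        if len(tested):
            top = tested.loc[tested["p"].idxmin()]
            lines.append(
                f"top marker: {top['marker']} (chr{top['chrom']} "
                f"{top['pos_mbp']:.2f} Mbp)  beta={top['beta']:+.3f}  "
                f"p={top['p']:.3g}"
            )
        if threshold is not None:
            lines.append(
                f"threshold (alpha={threshold.alpha}, n_perm={threshold.n_perm}): "
                f"-log10 p >= {threshold.threshold_neg_log10:.3f} "
                f"(p <= {threshold.threshold_p:.3g})"
            )
            regions = self.call_regions(threshold)
            if regions:
                lines.append("significant regions:")
                for r in regions:
                    lines.append(
                        f"  chr{r.chromosome} {r.start_mbp:.2f}-{r.end_mbp:.2f} Mbp  "
                        f"peak {r.peak_marker}  p={r.peak_p:.3g}"
                    )
            else:
                lines.append("significant regions: none")
        return "\n".join(lines)


def call_regions(
    scan: pd.DataFrame,
    threshold: ThresholdSet,
    condition: str = "",
    max_gap: int = 0,
) -> list[RegionCall]:
    """Maximal runs of contiguous significant markers, never spanning
    chromosomes.

    Significance is p <= threshold_p. Skipped markers are transparent (they
    neither extend nor break a run); up to ``max_gap`` consecutive
    non-significant tested markers are tolerated inside a run (default 0:
    any non-significant tested marker splits the region).
    """
    regions: list[RegionCall] = []
    thr_p = threshold.threshold_p
    for chrom, sub in scan.groupby("chrom", sort=False):
        tested = sub[~sub["skipped"]]
        if tested.empty:
            continue
        sig = (tested["p"] <= thr_p).to_numpy()
        pos = tested["pos_mbp"].to_numpy()
        pvals = tested["p"].to_numpy()
        names = tested["marker"].to_numpy()
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            gap = 0
            end = i
            while j + 1 < len(sig):
                if sig[j + 1]:
                    j += 1
                    end = j
                    gap = 0
                elif gap < max_gap:
                    j += 1
                    gap += 1
                else:
                    break
            run = slice(i, end + 1)
            run_p = pvals[run]
            run_names = names[run]
            run_sig = sig[run]
            peak_idx = int(np.lexsort((np.arange(run_p.size), run_p))[0])
            regions.append(
                RegionCall(
                    condition=condition or threshold.condition,
                    chromosome=str(chrom),
                    start_mbp=float(pos[i]),
                    end_mbp=float(pos[end]),
                    peak_marker=str(run_names[peak_idx]),
                    peak_p=float(run_p.min()),
                    n_markers=int(run_sig.sum()),
                )
            )
            i = end + 1
    return regions


def regions_to_frame(regions: list[RegionCall]) -> pd.DataFrame:
    cols = [
        "condition", "chromosome", "start_mbp", "end_mbp",
        "peak_marker", "peak_p", "n_markers",
    ]
    if not regions:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(r) for r in regions])[cols]
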