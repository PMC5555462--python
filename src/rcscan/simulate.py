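"""Breeding-scheme simulation of recombinant congenic strain (RCS) panels.

Simulates the construction of AcB/BcA-style panels from two inbred parental
strains, A/J (allele ``A``) and C57BL/6J (allele ``B``): an F1 cross, a fixed
number of backcrosses to the recurrent (major donor) parent, then
brother-sister mating to fixation. Meiosis follows a no-interference
(Poisson) crossover process, so the recombination fraction between two loci
obeys Haldane's map function c = (1 - exp(-2d)) / 2 for distance d Morgans.

With two backcrosses (N3 generation) the expected minor-donor genome
fraction of a fixed line is (1/2)^3 = 12.5%, the composition of the
classical AcB/BcA panel. QTL-driven phenotypes are generated on the log2
scale with strain and animal-level variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMap

# genotype codes used in the strains x markers matrix
CODE_B = 0  # C57BL/6J-derived allele
CODE_A = 1  # A/J-derived allele
CODE_H = 2  # residual heterozygous call
CODE_NA = -1  # missing

CODE_TO_LETTER = {CODE_A: "A", CODE_B: "B", CODE_H: "H", CODE_NA: "NA"}
LETTER_TO_CODE = {v: k for k, v in CODE_TO_LETTER.items()}

#: experimental conditions of the allergen-exposure design
CONDITIONS: tuple[str, ...] = ("baseline", "OVA-PBS", "OVA-OVA")


class BreedingConfigError(ValueError):
    pass


class QtlSpecError(ValueError):
    pass


@dataclass(frozen=True)
class BreedingConfig:
    """Parameters of the RCS breeding scheme.

    ``n_backcrosses=2`` (F1 -> N2 -> N3, then sib-mating) reproduces the
    ~12.5% minor-donor composition of the AcB/BcA panel; each additional
    backcross halves the expected minor-donor fraction.
    """

    n_acb: int = 10
    n_bca: int = 21
    n_backcrosses: int = 2
    max_inbreeding_generations: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_acb < 0 or self.n_bca < 0 or self.n_acb + self.n_bca < 1:
            raise BreedingConfigError("need at least one RCS strain")
        if self.n_backcrosses < 1:
            raise BreedingConfigError("n_backcrosses must be >= 1")
        if self.max_inbreeding_generations < 1:
            raise BreedingConfigError("max_inbreeding_generations must be >= 1")


class GenotypePanel:
    """Strains x markers matrix of parental-origin genotype calls.

    The matrix holds integer codes (1 = A/J allele, 0 = C57BL/6J allele,
    2 = heterozygous, -1 = missing); :meth:`to_frame` renders the letter
    form used in the TSV interchange format.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        strain_ids: list[str],
        families: list[str],
        marker_map: MarkerMap,
    ):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (strains x markers)")
        if matrix.shape != (len(strain_ids), marker_map.n_markers):
            raise ValueError(
                f"genotype matrix shape {matrix.shape} does not match "
                f"{len(strain_ids)} strains x {marker_map.n_markers} markers"
            )
        if len(families) != len(strain_ids):
            raise ValueError("one family label required per strain")
        valid = np.isin(matrix, list(CODE_TO_LETTER))
        if not valid.all():
            raise ValueError("genotype matrix contains invalid codes")
        self.matrix = matrix
        self.strain_ids = [str(s) for s in strain_ids]
        self.families = [str(f) for f in families]
        self.marker_map = marker_map

    @property
    def n_strains(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]

    @property
    def family(self) -> pd.Series:
        return pd.Series(self.families, index=self.strain_ids, name="family")

    def is_fixed(self) -> bool:
        """True when no strain carries a residual heterozygous call."""
        return not (self.matrix == CODE_H).any()

    def dosage(self) -> np.ndarray:
        """Float matrix coded 1 = A/J allele, 0 = B6 allele, NaN = H or
        missing (heterozygous and missing calls are dropped per marker in
        the scan)."""
        d = self.matrix.astype(float)
        d[(self.matrix == CODE_H) | (self.matrix == CODE_NA)] = np.nan
        return d

    def minor_donor_fraction(self) -> pd.Series:
        """Per-strain fraction of typed markers carrying the minor-donor
        allele (B for AcB strains, A for BcA strains; A-donor fraction for
        consomic strains; 0 for parentals)."""
        out = {}
        for i, (sid, fam) in enumerate(zip(self.strain_ids, self.families)):
            row = self.matrix[i]
            typed = row != CODE_NA
            het = row == CODE_H
            if fam == "AcB":
                donor = (row == CODE_B) + 0.5 * het
            elif fam in ("BcA", "CSS"):
                donor = (row == CODE_A) + 0.5 * het
            else:  # parental
                donor = np.zeros(row.shape)
            out[sid] = donor[typed].sum() / typed.sum()
        return pd.Series(out, name="minor_donor_fraction")

    def to_frame(self) -> pd.DataFrame:
        """Letter-coded DataFrame (index = strain ids, columns = marker ids)."""
        letters = np.vectorize(CODE_TO_LETTER.get)(self.matrix)
        return pd.DataFrame(
            letters, index=self.strain_ids, columns=self.marker_map.marker_ids
        )

    def subset(self, strain_ids: list[str]) -> "GenotypePanel":
        idx = [self.strain_ids.index(s) for s in strain_ids]
        return GenotypePanel(
            self.matrix[idx],
            [self.strain_ids[i] for i in idx],
            [self.families[i] for i in idx],
            self.marker_map,
        )

    def concat(self, other: "GenotypePanel") -> "GenotypePanel":
        if other.marker_map is not self.marker_map and not other.marker_map.table.equals(
            self.marker_map.table
        ):
            raise ValueError("panels use different marker maps")
        return GenotypePanel(
            np.vstack([self.matrix, other.matrix]),
            self.strain_ids + other.strain_ids,
            self.families + other.families,
            self.marker_map,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypePanel({self.n_strains} strains x {self.n_markers} markers)"


# --------------------------------------------------------------------------
# meiosis
# --------------------------------------------------------------------------

def simulate_meiosis(
    parent_hap1: np.ndarray,
    parent_hap2: np.ndarray,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a diploid parent under a no-interference crossover
    process.

    Crossover counts per chromosome are Poisson with mean equal to the
    chromosome genetic length in Morgans; crossover positions are uniform on
    the cM axis. Adjacent-marker recombination therefore follows Haldane's
    map function.
    """
    h1 = np.asarray(parent_hap1)
    h2 = np.asarray(parent_hap2)
    m = marker_map.n_markers
    if h1.shape != (m,) or h2.shape != (m,):
        raise ValueError(
            f"haplotype length mismatch: {h1.shape}, {h2.shape} vs {m} markers"
        )
    len_cm = marker_map.chrom_len_cm
    counts = rng.poisson(len_cm / 100.0)
    phase = rng.integers(0, 2, size=len_cm.size)
    chrom_idx = marker_map.chrom_index
    total = int(counts.sum())
    if total == 0:
        src = phase[chrom_idx]
    else:
        reps = np.repeat(np.arange(len_cm.size), counts)
        xpos = marker_map.chrom_offset_cm[reps] + rng.random(total) * len_cm[reps]
        xpos.sort()
        k = np.searchsorted(xpos, marker_map.global_cm, side="left")
        before = np.concatenate([[0], np.cumsum(counts)])[:-1]
        src = (phase[chrom_idx] + k - before[chrom_idx]) % 2
    return np.where(src == 0, h1, h2)


# --------------------------------------------------------------------------
# breeding
# --------------------------------------------------------------------------

def _breed_one_strain(
    recurrent_code: int,
    donor_code: int,
    marker_map: MarkerMap,
    n_backcrosses: int,
    max_gens: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Breed one fixed RCS line; returns the fixed genotype row (codes)."""
    m = marker_map.n_markers
    recurrent = np.full(m, recurrent_code, dtype=np.int8)
    donor = np.full(m, donor_code, dtype=np.int8)

    # F1 carries one haplotype from each parent; each backcross to the
    # recurrent parent halves the expected donor fraction. The final
    # backcross litter provides the two sibs that start the inbreeding.
    parents = (recurrent, donor)
    for _ in range(n_backcrosses - 1):
        gamete = simulate_meiosis(*parents, marker_map, rng)
        parents = (gamete, recurrent)
    sib1 = (simulate_meiosis(*parents, marker_map, rng), recurrent.copy())
    sib2 = (simulate_meiosis(*parents, marker_map, rng), recurrent.copy())

    def fixed_mask(p1, p2):
        a = p1[0]
        return (a == p1[1]) & (a == p2[0]) & (a == p2[1])

    for _ in range(max_gens):
        if fixed_mask(sib1, sib2).all():
            break
        o1 = (
            simulate_meiosis(*sib1, marker_map, rng),
            simulate_meiosis(*sib2, marker_map, rng),
        )
        o2 = (
            simulate_meiosis(*sib1, marker_map, rng),
            simulate_meiosis(*sib2, marker_map, rng),
        )
        sib1, sib2 = o1, o2

    fixed = fixed_mask(sib1, sib2)
    genotype = sib1[0].copy()
    if not fixed.all():
        # force fixation: per residual heterozygous segment, adopt one of the
        # four line haplotypes uniformly at random (preserves expected donor
        # fraction and block structure)
        haps = np.stack([sib1[0], sib1[1], sib2[0], sib2[1]])
        unfixed = ~fixed
        # contiguous runs of unfixed markers, never spanning chromosomes
        boundary = np.empty(len(unfixed), dtype=bool)
        boundary[0] = True
        boundary[1:] = (~unfixed[:-1]) | (
            np.diff(marker_map.chrom_index) != 0
        )
        seg_id = np.cumsum(boundary & unfixed) - 1
        n_seg = seg_id[unfixed].max() + 1 if unfixed.any() else 0
        choice = rng.integers(0, 4, size=n_seg)
        idx = np.flatnonzero(unfixed)
        genotype[idx] = haps[choice[seg_id[idx]], idx]
    return genotype


def breed_rcs_panel(
    config: BreedingConfig, marker_map: MarkerMap
) -> GenotypePanel:
    """Simulate a full AcB/BcA-style RCS panel.

    AcB strains use A/J as the recurrent (major donor) parent and carry
    C57BL/6J segments; BcA strains are the reciprocal. Identical configs
    (including seed) produce bit-identical panels.
    """
    rng = np.random.default_rng(config.seed)
    rows, strain_ids, families = [], [], []
    for i in range(config.n_acb):
        rows.append(
            _breed_one_strain(
                CODE_A, CODE_B, marker_map,
                config.n_backcrosses, config.max_inbreeding_generations, rng,
            )
        )
        strain_ids.append(f"AcB{i + 1:02d}")
        families.append("AcB")
    for i in range(config.n_bca):
        rows.append(
            _breed_one_strain(
                CODE_B, CODE_A, marker_map,
                config.n_backcrosses, config.max_inbreeding_generations, rng,
            )
        )
        strain_ids.append(f"BcA{i + 1:02d}")
        families.append("BcA")
    return GenotypePanel(np.stack(rows), strain_ids, families, marker_map)


def parental_panel(marker_map: MarkerMap) -> GenotypePanel:
    """The two parental strains as constant-genotype rows."""
    m = marker_map.n_markers
    matrix = np.stack(
        [np.full(m, CODE_A, np.int8), np.full(m, CODE_B, np.int8)]
    )
    return GenotypePanel(matrix, ["A/J", "C57BL/6J"], ["parental", "parental"], marker_map)


def make_css_strain(donor_chromosome: str, marker_map: MarkerMap) -> GenotypePanel:
    """Consomic (chromosome substitution) strain: A/J alleles along one donor
    chromosome on an otherwise C57BL/6J background (e.g. CSS4)."""
    mask = marker_map.markers_on(donor_chromosome)  # raises on unknown label
    row = np.where(mask, CODE_A, CODE_B).astype(np.int8)
    return GenotypePanel(
        row[None, :], [f"CSS{donor_chromosome}"], ["CSS"], marker_map
    )


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QtlEffect:
    """Additive effect (log2 units, added when the strain carries the A/J
    allele) at one marker, optionally restricted to a set of conditions."""

    marker: str
    effect: float
    conditions: tuple[str, ...] | None = None  # None = all conditions

    def applies(self, condition: str) -> bool:
        return self.conditions is None or condition in self.conditions


@dataclass(frozen=True)
class QtlSpec:
    """Generative architecture for log2-scale IgE phenotypes.

    Animal-level model:
    ``log2(IgE) = baseline_mean[condition] + sum(QTL effects) + strain effect
    + residual`` with the strain effect shared across conditions.
    """

    effects: tuple[QtlEffect, ...] = ()
    strain_variance: float = 0.25
    residual_variance: float = 0.5
    baseline_mean: dict = field(
        default_factory=lambda: {"baseline": 7.0, "OVA-PBS": 9.0, "OVA-OVA": 10.0}
    )

    def __post_init__(self):
        if self.strain_variance < 0 or self.residual_variance < 0:
            raise QtlSpecError("variances must be non-negative")

    def validate_markers(self, marker_map: MarkerMap) -> None:
        for q in self.effects:
            marker_map.marker_index(q.marker)  # KeyError on unknown


def simulate_phenotypes(
    panel: GenotypePanel,
    qtl: QtlSpec,
    n_per_strain: tuple[int, int] = (5, 20),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Animal-level IgE records for every strain in ``panel``.

    Returns a phenotype table with columns ``animal_id, strain, condition,
    ige_ng_ml``; IgE is 2**(log2 value), hence strictly positive. Group
    sizes are drawn uniformly from ``n_per_strain`` per strain/condition.
    """
    try:
        qtl.validate_markers(panel.marker_map)
    except KeyError as exc:
        raise QtlSpecError(f"QTL marker not in map: {exc}") from exc
    lo, hi = n_per_strain
    if not (1 <= lo <= hi):
        raise ValueError("n_per_strain must be an increasing positive range")
    if rng is None:
        rng = np.random.default_rng(seed)

    conditions = list(qtl.baseline_mean)
    qtl_cols = {
        q: panel.marker_map.marker_index(q.marker) for q in qtl.effects
    }
    strain_sd = np.sqrt(qtl.strain_variance)
    resid_sd = np.sqrt(qtl.residual_variance)

    records = []
    counter = 0
    for i, strain in enumerate(panel.strain_ids):
        u = rng.normal(0.0, strain_sd) if strain_sd > 0 else 0.0
        for cond in conditions:
            genetic = qtl.baseline_mean[cond]
            for q, col in qtl_cols.items():
                if not q.applies(cond):
                    continue
                code = panel.matrix[i, col]
                if code == CODE_A:
                    genetic += q.effect
                elif code == CODE_H:
                    genetic += 0.5 * q.effect
            n = int(rng.integers(lo, hi + 1))
            noise = rng.normal(0.0, resid_sd, size=n) if resid_sd > 0 else np.zeros(n)
            log2_vals = genetic + u + noise
            for v in log2_vals:
                counter += 1
                records.append(
                    {
                        "animal_id": f"a{counter:05d}",
                        "strain": strain,
                        "condition": cond,
                        "ige_ng_ml": float(2.0 ** v),
                    }
                )
    return pd.DataFrame.from_records(records)
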