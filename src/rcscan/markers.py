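"""Genome marker maps for inbred mouse strain panels.

A :class:`MarkerMap` is an ordered table of genotyping markers with a
chromosome label, a physical position (base pairs, exposed as Mbp) and a
genetic position (centimorgans). It is the coordinate system shared by the
breeding simulator, the genome scan and the plotting code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Mouse chromosome labels in canonical order (autosomes then X).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20)) + ("X",)

# Approximate physical chromosome lengths (Mbp) of the GRCm38/mm10 assembly,
# used to lay out the default synthetic marker map.
_MM10_LENGTHS_MBP: dict[str, float] = {
    "1": 195.5, "2": 182.1, "3": 160.0, "4": 156.5, "5": 151.8,
    "6": 149.7, "7": 145.4, "8": 129.4, "9": 124.6, "10": 130.7,
    "11": 122.1, "12": 120.1, "13": 120.4, "14": 124.9, "15": 104.0,
    "16": 98.2, "17": 94.9, "18": 90.7, "19": 61.4, "X": 171.0,
}


class MarkerMapError(ValueError):
    """Raised when a marker table violates the map invariants."""


class MarkerMap:
    """Ordered marker map (chromosome, physical bp, genetic cM).

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker`` (unique id), ``chrom`` (label in 1..19, X),
        ``pos_bp`` (physical position, base pairs, > 0) and ``pos_cm``
        (genetic position, centimorgans, non-decreasing within a
        chromosome). Rows must be sorted by (chromosome, pos_bp).
    """

    def __init__(self, table: pd.DataFrame):
        required = ["marker", "chrom", "pos_bp", "pos_cm"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise MarkerMapError(f"marker table missing columns: {missing}")
        df = table[required].copy().reset_index(drop=True)
        df["marker"] = df["marker"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        df["pos_cm"] = df["pos_cm"].astype(float)

        if df["marker"].duplicated().any():
            dups = df.loc[df["marker"].duplicated(), "marker"].tolist()
            raise MarkerMapError(f"duplicate marker ids: {dups[:5]}")
        bad_chrom = sorted(set(df["chrom"]) - set(CHROMOSOMES))
        if bad_chrom:
            raise MarkerMapError(f"unknown chromosome labels: {bad_chrom}")
        if (df["pos_bp"] <= 0).any():
            raise MarkerMapError("physical positions must be positive")

        order = {c: i for i, c in enumerate(CHROMOSOMES)}
        chrom_rank = df["chrom"].map(order).to_numpy()
        if not (np.diff(chrom_rank) >= 0).all():
            raise MarkerMapError("markers not grouped in chromosome order")
        for _, sub in df.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing:
                raise MarkerMapError("pos_bp not increasing within a chromosome")
            if not sub["pos_cm"].is_monotonic_increasing and not (
                np.diff(sub["pos_cm"].to_numpy()) >= 0
            ).all():
                raise MarkerMapError("pos_cm decreasing within a chromosome")

        self.table = df
        self._chrom_rank = chrom_rank
        self._build_meiosis_arrays()

    # -- construction helpers -------------------------------------------------

    def _build_meiosis_arrays(self) -> None:
        """Precompute per-chromosome arrays used by the meiosis simulator."""
        df = self.table
        self.chrom_labels = list(dict.fromkeys(df["chrom"]))
        idx = {c: i for i, c in enumerate(self.chrom_labels)}
        self.chrom_index = df["chrom"].map(idx).to_numpy(np.int64)
        # chromosome genetic length = position of the distal-most marker
        self.chrom_len_cm = np.array(
            [df.loc[df["chrom"] == c, "pos_cm"].max() for c in self.chrom_labels]
        )
        # offsets spread chromosomes along one global cM axis with gaps so
        # crossover positions from different chromosomes never interleave
        gap = self.chrom_len_cm.max() + 1.0 if len(self.chrom_len_cm) else 1.0
        self.chrom_offset_cm = np.concatenate(
            [[0.0], np.cumsum(self.chrom_len_cm + gap)[:-1]]
        )
        self.global_cm = (
            self.chrom_offset_cm[self.chrom_index] + df["pos_cm"].to_numpy()
        )

    # -- properties -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def pos_mbp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy() / 1e6

    @property
    def pos_cm(self) -> np.ndarray:
        return self.table["pos_cm"].to_numpy()

    def marker_index(self, marker_id: str) -> int:
        pos = np.flatnonzero(self.table["marker"].to_numpy() == str(marker_id))
        if pos.size == 0:
            raise KeyError(f"unknown marker id: {marker_id!r}")
        return int(pos[0])

    def markers_on(self, chrom: str) -> np.ndarray:
        """Boolean mask of markers on the given chromosome."""
        chrom = str(chrom)
        if chrom not in self.chrom_labels:
            raise KeyError(f"chromosome {chrom!r} not present in this map")
        return self.table["chrom"].to_numpy() == chrom

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MarkerMap({self.n_markers} markers, "
            f"{len(self.chrom_labels)} chromosomes)"
        )


def default_marker_map(n_markers: int = 1215, cm_per_mbp: float = 0.5) -> MarkerMap:
    """Synthetic genome-wide marker map at the density of classical mouse
    strain-panel marker lists.

    Markers are spread over chromosomes 1–19 and X proportionally to mm10
    physical length and evenly spaced within each chromosome. Genetic
    positions use a uniform ``cm_per_mbp`` rate (default 0.5 cM/Mbp, giving a
    ~13 Morgan genome, close to the mouse consensus map).
    """
    if n_markers < len(CHROMOSOMES):
        raise ValueError("need at least one marker per chromosome")
    lengths = np.array([_MM10_LENGTHS_MBP[c] for c in CHROMOSOMES])
    # largest-remainder apportionment, at least one marker per chromosome
    quota = n_markers * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), 1)
    remainder = n_markers - counts.sum()
    if remainder > 0:
        frac_order = np.argsort(quota - np.floor(quota))[::-1]
        counts[frac_order[:remainder]] += 1
    elif remainder < 0:
        big = np.argsort(counts)[::-1]
        counts[big[: -remainder]] -= 1

    rows = []
    for chrom, length, k in zip(CHROMOSOMES, lengths, counts):
        # even spacing with a half-step margin at both telomeres
        pos_mbp = (np.arange(k) + 0.5) * length / k
        for j, p in enumerate(pos_mbp):
            rows.append(
                {
                    "marker": f"m{chrom}_{j + 1}",
                    "chrom": chrom,
                    "pos_bp": int(round(p * 1e6)),
                    "pos_cm": p * cm_per_mbp,
                }
            )
    return MarkerMap(pd.DataFrame(rows))
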