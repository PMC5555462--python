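"""End-to-end pipeline: simulate -> strain stats -> genome scan -> report.

Each stage reads/writes the TSV interchange formats so stages can be run
separately (e.g. on real genotype/phenotype tables) or chained on a
simulated panel from a single :class:`~rcscan.io.RunConfig`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .markers import default_marker_map
from .scan import GenomeScan, regions_to_frame
from .simulate import (
    BreedingConfig,
    QtlEffect,
    QtlSpec,
    breed_rcs_panel,
    parental_panel,
    simulate_phenotypes,
)
from .strain_stats import dunnett_many_to_one, summarize_strains

logger = logging.getLogger(__name__)


def _out_dir(config: io.RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # run log: the effective settings (seed included) for reproducibility
    config.to_yaml(out / "run_config.yaml")
    return out


def run_simulate(config: io.RunConfig) -> dict[str, Path]:
    """Breed an RCS panel, generate phenotypes, write the three tables."""
    out = _out_dir(config)
    rng_master = np.random.SeedSequence(config.seed)
    breed_seed, pheno_seed = rng_master.spawn(2)

    mmap = default_marker_map(config.n_markers)
    breeding = BreedingConfig(
        n_acb=config.n_acb,
        n_bca=config.n_bca,
        n_backcrosses=config.n_backcrosses,
        seed=breed_seed.generate_state(1)[0] % (2 ** 31),
    )
    panel = breed_rcs_panel(breeding, mmap)
    panel = panel.concat(parental_panel(mmap))

    if config.qtl_marker is None:
        # default planted QTL: marker nearest the middle of chromosome 4
        chr4 = mmap.table[mmap.table["chrom"] == "4"]
        qtl_marker = chr4["marker"].iloc[len(chr4) // 2]
    else:
        qtl_marker = config.qtl_marker
    qtl = QtlSpec(
        effects=(QtlEffect(qtl_marker, config.qtl_effect),),
        strain_variance=config.strain_variance,
        residual_variance=config.residual_variance,
    )
    pheno = simulate_phenotypes(
        panel, qtl,
        n_per_strain=tuple(config.n_per_strain),
        rng=np.random.default_rng(pheno_seed),
    )

    paths = {
        "map": out / "marker_map.tsv",
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    io.write_map(mmap, paths["map"])
    io.write_genotypes(panel, paths["genotypes"])
    io.write_phenotypes(pheno, paths["phenotypes"])
    logger.info(
        "simulated %d strains x %d markers, %d animals (QTL at %s)",
        panel.n_strains, panel.n_markers, len(pheno), qtl_marker,
    )
    return paths


def _load_inputs(config: io.RunConfig):
    out = _out_dir(config)
    map_path = config.marker_map or out / "marker_map.tsv"
    geno_path = config.genotypes or out / "genotypes.tsv"
    pheno_path = config.phenotypes or out / "phenotypes.tsv"
    mmap = io.read_map(map_path)
    panel = io.read_genotypes(geno_path, mmap)
    pheno = io.read_phenotypes(pheno_path)
    return mmap, panel, pheno


def run_stats(config: io.RunConfig) -> dict[str, Path]:
    """Strain summaries and many-to-one informative-strain calls."""
    out = _out_dir(config)
    _, panel, pheno = _load_inputs(config)
    summaries = summarize_strains(pheno)
    io_paths = {"summaries": out / "strain_summaries.tsv"}
    summaries.to_csv(io_paths["summaries"], sep="\t", index=False)

    fam = panel.family
    calls = []
    for family, reference in (("AcB", "A/J"), ("BcA", "C57BL/6J")):
        members = [s for s in panel.strain_ids if fam.get(s) == family]
        if not members or reference not in panel.strain_ids:
            continue
        present = set(pheno["strain"])
        members = [s for s in members if s in present]
        if reference not in present or not members:
            continue
        for cond in config.conditions:
            calls.append(
                dunnett_many_to_one(pheno, reference, members, cond)
            )
    if calls:
        import pandas as pd

        informative = pd.concat(calls, ignore_index=True)
        io_paths["informative"] = out / "informative_strains.tsv"
        informative.to_csv(io_paths["informative"], sep="\t", index=False)
    if config.make_plots:
        from .plotting import strain_barplot

        for cond in config.conditions:
            if (summaries["condition"] == cond).any():
                p = out / f"strains_{cond.replace('/', '_')}.png"
                strain_barplot(summaries, cond, out_path=p)
                io_paths[f"plot_{cond}"] = p
    return io_paths


def run_scan(config: io.RunConfig) -> dict[str, Path]:
    """Per-condition genome scan, permutation thresholds and region calls."""
    out = _out_dir(config)
    _, panel, pheno = _load_inputs(config)
    rng_master = np.random.SeedSequence(config.seed)
    perm_seeds = rng_master.spawn(len(config.conditions))

    scans, thresholds, regions = {}, [], []
    for cond, seed_seq in zip(config.conditions, perm_seeds):
        if not (pheno["condition"] == cond).any():
            logger.warning("condition %r absent from phenotypes; skipped", cond)
            continue
        model = GenomeScan.from_panels(pheno, panel, condition=cond)
        res = model.fit()
        thr = res.permutation_threshold(
            alpha=config.alpha,
            n_perm=config.n_perm,
            rng=np.random.default_rng(seed_seq),
        )
        scans[cond] = res.scan
        thresholds.append(thr)
        regions.extend(res.call_regions(thr))

    paths: dict[str, Path] = {}
    for cond, scan in scans.items():
        p = out / f"scan_{cond.replace('/', '_')}.tsv"
        io.write_scan(scan, p)
        paths[f"scan_{cond}"] = p
    paths["thresholds"] = out / "thresholds.tsv"
    io.write_thresholds(thresholds, paths["thresholds"])
    paths["regions"] = out / "regions.tsv"
    io.report_regions(regions, thresholds, paths["regions"])
    regions_to_frame(regions).to_csv(out / "regions_raw.tsv", sep="\t", index=False)

    if config.make_plots and scans:
        from .plotting import manhattan_grid

        thr_by_cond = {t.condition: t for t in thresholds}
        paths["manhattan"] = out / "manhattan.png"
        manhattan_grid(scans, thr_by_cond, out_path=paths["manhattan"])
    return paths


def run_all(config: io.RunConfig) -> dict[str, Path]:
    paths = run_simulate(config)
    paths.update(run_stats(config))
    paths.update(run_scan(config))
    return paths
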