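"""Synthetic genomes, nascent-transcript libraries and bisulfite reports.

The generator plants three locus classes with known parameters so every
downstream stage can be validated against ground truth:

``feedback_rddm_only``
    Loci silenced exclusively by RdDM.  High Pol V transcription in
    the wild type, strongly reduced in every downstream-pathway mutant,
    and complete loss of methylation in *all* contexts in the mutant —
    the planted analogue of the "neither CG nor CHG present" group.
``multi_pathway``
    Loci additionally maintained by other methylation pathways.  Pol V
    transcription is unchanged in downstream mutants and symmetric
    (CG/CHG) methylation is retained — the "both present" control
    group.
``background``
    Everything else: a low genome-wide surveillance-transcription
    floor and no cytosines.

Bin-level read counts are negative-binomially dispersed around
``rate * depth / 1e6`` (Poisson when the dispersion is 0); per-cytosine
methylation is binomial around the planted level with an optional
bisulfite conversion error.  Every output stream is seeded per file, so
adding a genotype never perturbs the others, and a fixed seed gives
byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CytosineSite,
    GenomeLayout,
    Interval,
    ParameterError,
    TEAnnotation,
    te_end_partition,
)
from . import io as rio


class ConfigurationError(ValueError):
    pass


#: replicate structure of the simulated study: two biological replicates
#: per genotype except met1, which has a single one (exercising the
#: single-replicate generalized fold-change path).
GENOTYPE_REPLICATES = {
    "col0": 2,
    "nrpe1": 2,
    "drm2": 2,
    "spt5l": 2,
    "ago4": 2,
    "met1": 1,
    "cmt3": 2,
}

#: genotypes with simulated bisulfite methylomes (one library each)
WGBS_GENOTYPES = ("col0", "drm2", "met1")

#: expected reads per bin per million mapped reads, per locus class and
#: genotype.  Feedback loci lose transcription in downstream mutants;
#: multi-pathway loci do not; the Pol V null collapses both to the floor.
IPARE_RATES = {
    "feedback_rddm_only": {
        "col0": 50.0, "nrpe1": 0.5, "drm2": 5.0, "spt5l": 5.0,
        "ago4": 5.0, "met1": 5.0, "cmt3": 50.0,
    },
    "multi_pathway": {
        "col0": 50.0, "nrpe1": 0.5, "drm2": 50.0, "spt5l": 50.0,
        "ago4": 50.0, "met1": 50.0, "cmt3": 50.0,
    },
}

#: planted methylation fraction per locus class, genotype and context
METH_LEVELS = {
    "feedback_rddm_only": {
        "col0": {"CG": 0.6, "CHG": 0.4, "CHH": 0.6},
        "drm2": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
        "met1": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
    },
    "multi_pathway": {
        "col0": {"CG": 0.6, "CHG": 0.4, "CHH": 0.6},
        "drm2": {"CG": 0.5, "CHG": 0.3, "CHH": 0.05},
        "met1": {"CG": 0.0, "CHG": 0.3, "CHH": 0.3},
    },
}

#: cytosine sites per context within one locus
SITES_PER_LOCUS = {"CG": 12, "CHG": 12, "CHH": 24}

_TRINUCLEOTIDE = {"CG": "CGA", "CHG": "CAG", "CHH": "CAA"}


@dataclass(frozen=True)
class LocusTruth:
    """A planted locus with its known rates and methylation levels."""

    interval: Interval
    locus_class: str
    polv_rate: dict[str, float]  # genotype -> reads/bin/million
    meth_level: dict[str, dict[str, float]]  # genotype -> context -> level

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.polv_rate.values()):
            raise ParameterError("negative transcription rate")
        for ctx_levels in self.meth_level.values():
            if any(not (0 <= l <= 1) for l in ctx_levels.values()):
                raise ParameterError("methylation level outside [0, 1]")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate a ~1 Mb genome with two replicates per genotype,
    one million mapped reads per library, moderate count dispersion and
    ~30x bisulfite coverage.
    """

    seed: int
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    n_feedback_loci: int = 60
    n_multi_pathway_loci: int = 60
    locus_length: int = 200
    n_tes_per_chromosome: int = 150
    te_min_length: int = 300
    te_max_length: int = 3000
    n_genes_per_chromosome: int = 40
    gene_length: int = 2000
    te_end_placement_prob: float = 0.8
    depth: int = 1_000_000
    phi_sim: float = 0.1
    background_rate: float = 0.5  # surveillance floor, reads/bin/million
    coverage_mean: float = 30.0
    conversion_error: float = 0.005
    bin_size: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length,
            "locus_length": self.locus_length,
            "depth": self.depth,
            "coverage_mean": self.coverage_mean,
            "bin_size": self.bin_size,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.phi_sim < 0 or self.background_rate < 0:
            raise ConfigurationError("rates and dispersion must be non-negative")
        if not (0 <= self.conversion_error < 0.5):
            raise ConfigurationError("conversion_error must lie in [0, 0.5)")
        if not (0 <= self.te_end_placement_prob <= 1):
            raise ConfigurationError("te_end_placement_prob must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """Manifest of a written dataset: file paths plus in-memory truth."""

    layout: GenomeLayout
    tes: list[TEAnnotation]
    genes: list[Interval]
    truths: list[LocusTruth]
    outdir: str
    chrom_sizes_path: str
    te_bed_path: str
    genes_bed_path: str
    truth_path: str
    read_paths: dict[str, str]  # sample name -> BED path
    sample_genotypes: dict[str, str]
    cx_paths: dict[str, str]  # genotype -> cytosine report path
    depth: int


def _file_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible stream for one output file."""
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + list(name.encode())))


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    sizes: list[int],
    occupied: list[tuple[int, int]],
    margin: int,
    align: int = 1,
    max_tries: int = 200,
) -> list[int]:
    """Greedy random placement of intervals avoiding existing ones."""
    placed: list[int] = []
    occ = sorted(occupied)
    for size in sizes:
        hi = (length - size) // align
        if hi < 0:
            raise ConfigurationError("genome too small for requested features")
        for _ in range(max_tries):
            start = int(rng.integers(0, hi + 1)) * align
            lo, up = start - margin, start + size + margin
            if not any(s < up and lo < e for s, e in occ):
                occ.append((start, start + size))
                occ.sort()
                placed.append(start)
                break
        else:
            raise ConfigurationError("genome too small for requested features")
    return placed


def build_synthetic_genome(
    config: SyntheticConfig,
) -> tuple[GenomeLayout, list[TEAnnotation], list[Interval], list[LocusTruth]]:
    """Deterministically generate layout, TEs, genes and locus truths.

    Feedback loci are preferentially placed on the ends of long TEs
    (probability ``te_end_placement_prob``), emulating the enrichment
    of RdDM feedback on TE edges; multi-pathway loci avoid TE ends.
    """
    rng = _file_rng(config.seed, "genome")
    layout = GenomeLayout(
        tuple((f"Chr{i + 1}", config.chromosome_length) for i in range(config.n_chromosomes))
    )
    families = ("Gypsy", "Copia", "LINE", "MuDR", "Helitron")
    tes: list[TEAnnotation] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in layout.names}
    for name in layout.names:
        sizes = [
            int(
                round(
                    10
                    ** rng.uniform(np.log10(config.te_min_length), np.log10(config.te_max_length))
                    / 10
                )
                * 10
            )
            for _ in range(config.n_tes_per_chromosome)
        ]
        starts = _place_nonoverlapping(
            rng, config.chromosome_length, sizes, occupied[name], margin=200, align=10
        )
        for s, size in zip(starts, sizes):
            occupied[name].append((s, s + size))
            tes.append(
                TEAnnotation(
                    Interval(name, s, s + size, "+"),
                    str(rng.choice(families)),
                    "RdDM" if rng.random() < 0.5 else "non-RdDM",
                )
            )

    bs = config.bin_size
    loci: list[tuple[Interval, str]] = []
    locus_occ: dict[str, list[tuple[int, int]]] = {n: [] for n in layout.names}

    # feedback loci: mostly pinned to ends of long TEs
    long_tes = [t for t in tes if t.length >= 1000]
    long_tes = [long_tes[i] for i in rng.permutation(len(long_tes))]
    host_iter = iter(long_tes)
    n_on_ends = 0
    for i in range(config.n_feedback_loci):
        on_end = rng.random() < config.te_end_placement_prob
        placed = False
        if on_end:
            for te in host_iter:
                chrom = te.interval.chrom
                use_five = n_on_ends % 2 == 0
                anchor = te.interval.start if use_five else te.interval.end - config.locus_length
                start = max(0, (anchor // bs) * bs)
                if start + config.locus_length > config.chromosome_length:
                    continue
                span = (start - 2 * bs, start + config.locus_length + 2 * bs)
                if any(s < span[1] and span[0] < e for s, e in locus_occ[chrom]):
                    continue
                loci.append((Interval(chrom, start, start + config.locus_length), "feedback_rddm_only"))
                locus_occ[chrom].append((start, start + config.locus_length))
                n_on_ends += 1
                placed = True
                break
        if not placed:
            chrom = str(rng.choice(layout.names))
            avoid = locus_occ[chrom] + [
                (p.start, p.end)
                for t in tes
                if t.interval.chrom == chrom
                for p in te_end_partition(t)[:2]
                if p is not None
            ]
            start = _place_nonoverlapping(
                rng, config.chromosome_length, [config.locus_length], avoid,
                margin=2 * bs, align=bs,
            )[0]
            loci.append((Interval(chrom, start, start + config.locus_length), "feedback_rddm_only"))
            locus_occ[chrom].append((start, start + config.locus_length))

    # multi-pathway loci: anywhere except TE ends and other loci
    for _ in range(config.n_multi_pathway_loci):
        chrom = str(rng.choice(layout.names))
        avoid = locus_occ[chrom] + [
            (p.start, p.end)
            for t in tes
            if t.interval.chrom == chrom
            for p in te_end_partition(t)[:2]
            if p is not None
        ]
        start = _place_nonoverlapping(
            rng, config.chromosome_length, [config.locus_length], avoid,
            margin=2 * bs, align=bs,
        )[0]
        loci.append((Interval(chrom, start, start + config.locus_length), "multi_pathway"))
        locus_occ[chrom].append((start, start + config.locus_length))

    genes: list[Interval] = []
    for name in layout.names:
        avoid = occupied[name] + locus_occ[name]
        starts = _place_nonoverlapping(
            rng, config.chromosome_length,
            [config.gene_length] * config.n_genes_per_chromosome,
            avoid, margin=100, align=10,
        )
        genes.extend(Interval(name, s, s + config.gene_length, "+") for s in starts)

    truths = [
        LocusTruth(iv, cls, dict(IPARE_RATES[cls]),
                   {g: dict(v) for g, v in METH_LEVELS[cls].items()})
        for iv, cls in loci
    ]
    truths.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return layout, tes, genes, truths


def _locus_rate_track(
    layout: GenomeLayout, truths: list[LocusTruth], genotype: str,
    background_rate: float, bin_size: int,
) -> dict[str, np.ndarray]:
    """Expected rate per non-overlapping source bin, per chromosome."""
    tracks = {
        name: np.full(length // bin_size, background_rate)
        for name, length in layout.chromosomes
    }
    for t in truths:
        rate = t.polv_rate.get(genotype)
        if rate is None:
            continue
        track = tracks[t.interval.chrom]
        first = t.interval.start // bin_size
        last = (t.interval.end - 1) // bin_size
        track[first : last + 1] = rate
    return tracks


def simulate_ipare_library(
    truths: list[LocusTruth],
    genotype: str,
    layout: GenomeLayout,
    depth: int,
    phi_sim: float,
    seed: int,
    stream: str = "",
    background_rate: float = 0.5,
    bin_size: int = 100,
) -> list[Interval]:
    """Draw single-bp 5' read positions for one library.

    Counts per non-overlapping source bin are NB(rate * depth / 1e6,
    phi_sim) (Poisson at phi_sim = 0); positions are uniform within the
    bin.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    if phi_sim < 0:
        raise ConfigurationError("dispersion must be non-negative")
    rng = _file_rng(seed, f"ipare_{genotype}_{stream}")
    tracks = _locus_rate_track(layout, truths, genotype, background_rate, bin_size)
    reads: list[Interval] = []
    for name, _ in layout.chromosomes:
        means = tracks[name] * depth / 1e6
        if phi_sim == 0:
            counts = rng.poisson(means)
        else:
            r = 1.0 / phi_sim
            with np.errstate(invalid="ignore"):
                counts = np.where(
                    means > 0, rng.negative_binomial(r, r / (r + np.maximum(means, 1e-300))), 0
                )
        nz = np.flatnonzero(counts)
        for j in nz:
            base = int(j) * bin_size
            offs = rng.integers(0, bin_size, size=int(counts[j]))
            reads.extend(Interval(name, base + int(o), base + int(o) + 1, "+") for o in np.sort(offs))
    return reads


def simulate_wgbs(
    truths: list[LocusTruth],
    genotype: str,
    coverage_mean: float,
    conversion_error: float,
    seed: int,
    sites_per_locus: dict[str, int] | None = None,
) -> list[CytosineSite]:
    """Draw per-cytosine counts for one bisulfite methylome.

    Sites are evenly spaced within each planted locus at per-context
    densities; coverage is Poisson and the methylated count binomial
    with success probability ``level*(1-e) + (1-level)*e`` where ``e``
    is the bisulfite conversion error.
    """
    if coverage_mean <= 0:
        raise ConfigurationError("coverage_mean must be positive")
    if not (0 <= conversion_error < 0.5):
        raise ConfigurationError("conversion_error must lie in [0, 0.5)")
    density = dict(SITES_PER_LOCUS if sites_per_locus is None else sites_per_locus)
    rng = _file_rng(seed, f"wgbs_{genotype}")
    sites: list[CytosineSite] = []
    for t in truths:
        levels = t.meth_level.get(genotype)
        if levels is None:
            continue
        iv = t.interval
        for ctx in ("CG", "CHG", "CHH"):
            n_sites = density[ctx]
            positions = np.unique(
                np.linspace(iv.start, iv.end - 1, n_sites).astype(np.int64)
            )
            level = levels[ctx]
            p = level * (1 - conversion_error) + (1 - level) * conversion_error
            cov = rng.poisson(coverage_mean, size=positions.size)
            n_meth = rng.binomial(cov, p)
            for pos, c, m in zip(positions, cov, n_meth):
                sites.append(
                    CytosineSite(iv.chrom, int(pos), "+", ctx, int(m), int(c - m),
                                 _TRINUCLEOTIDE[ctx])
                )
    sites.sort(key=lambda s: (s.chrom, s.pos, s.context))
    return sites


def truth_table(truths: list[LocusTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "locus_class": t.locus_class,
        }
        for g, r in t.polv_rate.items():
            row[f"rate_{g}"] = r
        for g, ctx_levels in t.meth_level.items():
            for ctx, l in ctx_levels.items():
                row[f"meth_{ctx}_{g}"] = l
        rows.append(row)
    return pd.DataFrame(rows)


def export_dataset(config: SyntheticConfig, outdir: str | os.PathLike) -> SyntheticDataset:
    """Write a complete synthetic dataset and return its manifest.

    Two replicates per genotype (one for met1), one cytosine report per
    bisulfite genotype, TE/gene annotations, chromosome sizes and the
    ground-truth table.  Identical seeds give identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, tes, genes, truths = build_synthetic_genome(config)

    chrom_sizes = outdir / "genome.chrom.sizes"
    rio.write_chrom_sizes(layout, chrom_sizes)
    te_bed = outdir / "tes.bed"
    rio.write_te_bed(tes, te_bed)
    genes_bed = outdir / "genes.bed"
    rio.write_bed(genes, genes_bed)
    truth_path = outdir / "truth.tsv"
    rio.write_table(truth_table(truths), truth_path)

    read_paths: dict[str, str] = {}
    sample_genotypes: dict[str, str] = {}
    for genotype, n_rep in GENOTYPE_REPLICATES.items():
        for rep in range(1, n_rep + 1):
            sample = f"{genotype}_rep{rep}"
            reads = simulate_ipare_library(
                truths, genotype, layout, config.depth, config.phi_sim,
                config.seed, stream=f"rep{rep}",
                background_rate=config.background_rate, bin_size=config.bin_size,
            )
            path = outdir / f"ipare_{sample}.bed"
            rio.write_bed(reads, path)
            read_paths[sample] = str(path)
            sample_genotypes[sample] = genotype

    cx_paths: dict[str, str] = {}
    for genotype in WGBS_GENOTYPES:
        sites = simulate_wgbs(
            truths, genotype, config.coverage_mean, config.conversion_error, config.seed
        )
        path = outdir / f"cx_{genotype}.txt"
        rio.write_cx_report(sites, path)
        cx_paths[genotype] = str(path)

    manifest = {
        "config": asdict(config),
        "chrom_sizes": str(chrom_sizes),
        "te_bed": str(te_bed),
        "genes_bed": str(genes_bed),
        "truth": str(truth_path),
        "reads": read_paths,
        "sample_genotypes": sample_genotypes,
        "cx_reports": cx_paths,
        "depth": config.depth,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return SyntheticDataset(
        layout=layout, tes=tes, genes=genes, truths=truths, outdir=str(outdir),
        chrom_sizes_path=str(chrom_sizes), te_bed_path=str(te_bed),
        genes_bed_path=str(genes_bed), truth_path=str(truth_path),
        read_paths=read_paths, sample_genotypes=sample_genotypes,
        cx_paths=cx_paths, depth=config.depth,
    )
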