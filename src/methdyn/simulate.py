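"""Synthetic multi-condition methylomes with planted truth.

The generator emulates the architecture of a B-lineage methylome as a
hypermethylated background (level 0.85) carrying two planted layers:

* a **foundational** layer of hypomethylated regions (level 0.05) shared
  identically by every condition and lineage, a subset of which are long
  enough to be methylation canyons (> 3.5 kb);
* a **dynamic** layer of DNMT3A-maintained enhancer (DME) intervals
  whose methylation follows a condition-specific 3-vector over
  (proB, wild-type mature, knockout mature), drawn per lineage from a
  pattern catalog with configurable weights.

Reads are sampled at ~5x mean coverage (Poisson per CpG) with imperfect
bisulfite conversion (default 98.5%), matching typical WGBS noise.
Planted regulatory intervals get CpG-island-like densified CpG spacing,
as real HMRs and enhancers are CpG-rich relative to the genomic
background.  Fully unmethylated non-CpG (CHH/CHG) cytosines are planted
at configurable density so conversion-rate estimation can be exercised.

TAB-Seq tracks are generated from per-CpG (u, m, h) truth — the modified
fraction is split into 5mC and 5hmC by ``hmc_fraction`` — under the same
forward model the hydroxymeth module inverts, together with pure-5hmC,
pure-5mC and unmethylated spike-in control tracks.

Every output is a deterministic function of (config, seed): each
(lineage, condition, assay) stream gets an independent child generator
seeded from the config seed.

What this generator does NOT emulate: sequence content, read-level
errors, strand asymmetries, copy-number or mapping artifacts, or
CpG-density-linked methylation gradients.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methdyn.io import SITE_COLUMNS, MethylomeTrack, write_methcounts, write_bed
from methdyn.patterns import PatternVector, default_pattern_catalog

LINEAGES = ("B1a", "B2")
CONDITIONS = ("proB", "WT", "KO")


@dataclass
class TabSeqConfig:
    f_ox: float = 0.90  # TET oxidation efficiency
    g_protect: float = 0.97  # glucosylation protection efficiency of 5hmC
    hmc_fraction: float = 0.10  # fraction of the modified level that is 5hmC
    spike_sites: int = 50
    spike_coverage: int = 200  # per spike-in site, ~1e4 aggregate reads


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic methylome.

    Defaults encode the study conditions: ~5x mean coverage, 98.5%
    bisulfite conversion, three conditions (proB, WT mature, KO mature)
    in each of two lineages, a hypermethylated background at 0.85 over
    foundational HMRs at 0.05.
    """

    seed: int = 0
    coverage_mean: float = 5.0
    conversion_rate: float = 0.985
    background_level: float = 0.85
    foundational_level: float = 0.05
    lineages: tuple[str, ...] = LINEAGES
    conditions: tuple[str, ...] = CONDITIONS
    non_cpg_per_chrom: int = 1000
    tabseq: TabSeqConfig = field(default_factory=TabSeqConfig)

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "background_level", "foundational_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")


@dataclass
class MethylomeArchitecture:
    """Planted genome layout: CpG positions plus the two interval layers."""

    cpg_positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    background_level: float
    foundational_hmrs: pd.DataFrame  # chrom, start, end, is_canyon
    dme_intervals: pd.DataFrame  # chrom, start, end, pattern_<lineage> per lineage
    tss_positions: pd.DataFrame  # chrom, pos, strand, gene

    @property
    def canyon_intervals(self) -> pd.DataFrame:
        f = self.foundational_hmrs
        return f[f["is_canyon"]].reset_index(drop=True)


@dataclass
class TruthTable:
    """Ground truth for every planted interval and per-CpG state.

    ``intervals`` records each planted interval's layer, per-lineage
    pattern id, and true per-(lineage, condition) methylation level.
    Per-CpG truth is derived on demand: :meth:`modified_level` gives the
    true modified fraction at every CpG of a chromosome and
    :meth:`cytosine_simplex` splits it into (u, m, h).
    """

    intervals: pd.DataFrame
    config: SimulationConfig
    architecture: MethylomeArchitecture = field(repr=False)
    pattern_catalog: list[PatternVector] = field(repr=False)

    def modified_level(self, lineage: str, condition: str, chrom: str) -> np.ndarray:
        if condition not in self.config.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        if lineage not in self.config.lineages:
            raise ValueError(f"unknown lineage {lineage!r}")
        pos = self.architecture.cpg_positions[chrom]
        level = np.full(len(pos), self.config.background_level)
        cond_idx = self.config.conditions.index(condition)
        ivs = self.intervals[self.intervals["chrom"] == chrom]
        for _, rec in ivs.iterrows():
            sel = (pos >= rec["start"]) & (pos < rec["end"])
            if rec["layer"] == "foundational":
                level[sel] = self.config.foundational_level
            else:
                level[sel] = rec[f"levels_{lineage}"][cond_idx]
        return level

    def cytosine_simplex(self, lineage: str, condition: str, chrom: str):
        """Per-CpG (u, m, h) truth; u + m + h = 1 at every CpG."""
        L = self.modified_level(lineage, condition, chrom)
        h = self.config.tabseq.hmc_fraction * L
        m = L - h
        u = 1.0 - L
        return u, m, h


def _child_rng(seed: int, *tags: str) -> np.random.Generator:
    """Deterministic independent stream per (seed, tag...) combination.

    Tags are folded in with CRC32 (stable across processes, unlike
    Python's salted ``hash``)."""
    import zlib

    ints = [seed] + [zlib.crc32(f"methdyn:{t}".encode()) % (2**31) for t in tags]
    return np.random.default_rng(ints)


def generate_genome(
    n_chroms: int,
    chrom_length: int,
    cpg_spacing_mean: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """CpG positions with geometric inter-CpG gaps (mean spacing given).

    Returns {chrom: strictly increasing positions}; reproducible for a
    fixed seed.  ``n_chroms = 0`` yields an empty genome.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if cpg_spacing_mean <= 0:
        raise ValueError("cpg_spacing_mean must be positive")
    rng = np.random.default_rng(seed)
    genome = {}
    for i in range(n_chroms):
        n_draw = int(2 * chrom_length / cpg_spacing_mean) + 100
        gaps = rng.geometric(1.0 / cpg_spacing_mean, size=n_draw)
        pos = np.cumsum(gaps)
        genome[f"chr{i + 1}"] = pos[pos < chrom_length].astype(np.int64)
    return genome


def _place_intervals(rng, chrom_lengths, lengths, occupied, margin=2000):
    """Place intervals of the given lengths without overlap (with margin).

    ``occupied`` is a per-chrom list of (start, end) already taken.
    Raises if an interval cannot be placed after bounded retries.
    """
    placed = []
    chroms = list(chrom_lengths)
    for L in lengths:
        for _ in range(2000):
            chrom = chroms[rng.integers(len(chroms))]
            limit = chrom_lengths[chrom] - L - margin
            if limit <= margin:
                continue
            start = int(rng.integers(margin, limit))
            end = start + L
            if all(
                end + margin <= s or start >= e + margin
                for s, e in occupied.get(chrom, [])
            ):
                occupied.setdefault(chrom, []).append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise ValueError(
                f"genome too small to place an interval of length {L}"
            )
    return placed


def _densify(positions: np.ndarray, start: int, end: int, spacing: float, rng):
    """Add CpG-island-like extra CpGs inside [start, end)."""
    gaps = rng.geometric(1.0 / spacing, size=int(2 * (end - start) / spacing) + 10)
    extra = start + np.cumsum(gaps)
    extra = extra[extra < end]
    return np.union1d(positions, extra.astype(np.int64))


def plant_architecture(
    cpg_positions: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    n_foundational: int = 30,
    n_dme: int = 40,
    n_canyons: int = 3,
    pattern_catalog: list[PatternVector] | None = None,
    pattern_weights: dict[str, np.ndarray] | None = None,
    seed: int = 0,
    canyon_cutoff: int = 3500,
    dme_length: tuple[int, int] = (600, 1200),
    hmr_length: tuple[int, int] = (800, 2000),
    canyon_length: tuple[int, int] = (4000, 8000),
    island_spacing: float = 30.0,
    lineages: tuple[str, ...] = LINEAGES,
    conditions: tuple[str, ...] = CONDITIONS,
    config: SimulationConfig | None = None,
) -> tuple[MethylomeArchitecture, TruthTable]:
    """Plant the foundational + dynamic layers and record the truth.

    ``n_foundational`` counts ordinary foundational HMRs; ``n_canyons``
    additional foundational intervals are drawn longer than
    ``canyon_cutoff``.  Each DME receives, per lineage, a pattern id
    drawn from the catalog with ``pattern_weights[lineage]`` (uniform if
    omitted); its true per-condition levels are the pattern's levels.
    No two planted intervals overlap.
    """
    rng = np.random.default_rng(seed)
    catalog = pattern_catalog if pattern_catalog is not None else default_pattern_catalog()
    config = config if config is not None else SimulationConfig(seed=seed)

    occupied: dict[str, list] = {}
    hmr_lengths = list(rng.integers(hmr_length[0], hmr_length[1] + 1, n_foundational))
    canyon_lengths = [
        int(L)
        for L in rng.integers(
            max(canyon_length[0], canyon_cutoff + 1), canyon_length[1] + 1, n_canyons
        )
    ]
    found = _place_intervals(rng, chrom_lengths, hmr_lengths + canyon_lengths, occupied)
    is_canyon = [False] * n_foundational + [True] * n_canyons
    foundational = pd.DataFrame(found, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}, errors="ignore"
    )
    foundational["is_canyon"] = pd.Series(is_canyon, dtype=bool)

    dme_lengths = list(rng.integers(dme_length[0], dme_length[1] + 1, n_dme))
    dmes = pd.DataFrame(
        _place_intervals(rng, chrom_lengths, dme_lengths, occupied),
        columns=["chrom", "start", "end"],
    )
    ids = [p.id for p in catalog]
    for lineage in lineages:
        if pattern_weights and lineage in pattern_weights:
            w = np.asarray(pattern_weights[lineage], float)
            w = w / w.sum()
        else:
            w = np.full(len(catalog), 1.0 / len(catalog))
        dmes[f"pattern_{lineage}"] = rng.choice(ids, size=len(dmes), p=w)

    # densify CpGs inside planted regulatory intervals
    positions = {c: p.copy() for c, p in cpg_positions.items()}
    for frame in (foundational, dmes):
        for _, rec in frame.iterrows():
            positions[rec["chrom"]] = _densify(
                positions[rec["chrom"]], int(rec["start"]), int(rec["end"]),
                island_spacing, rng,
            )

    # one TSS near each DME (its "nearest gene") plus decoys
    tss_rows = []
    for i, (_, rec) in enumerate(dmes.iterrows()):
        strand = "+" if rng.random() < 0.5 else "-"
        offset = int(rng.integers(500, 5000))
        pos = int(rec["end"]) + offset if strand == "+" else int(rec["start"]) - offset
        tss_rows.append((rec["chrom"], max(pos, 0), strand, f"gene{i + 1}"))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene"])

    arch = MethylomeArchitecture(
        cpg_positions=positions,
        chrom_lengths=dict(chrom_lengths),
        background_level=config.background_level,
        foundational_hmrs=foundational,
        dme_intervals=dmes,
        tss_positions=tss,
    )

    level_map = {p.id: np.asarray(p.levels) for p in catalog}
    rows = []
    for _, rec in foundational.iterrows():
        row = {
            "chrom": rec["chrom"],
            "start": rec["start"],
            "end": rec["end"],
            "layer": "foundational",
        }
        for lineage in lineages:
            row[f"pattern_{lineage}"] = "foundational"
            row[f"levels_{lineage}"] = tuple(
                config.foundational_level for _ in conditions
            )
        rows.append(row)
    for _, rec in dmes.iterrows():
        row = {
            "chrom": rec["chrom"],
            "start": rec["start"],
            "end": rec["end"],
            "layer": "DME",
        }
        for lineage in lineages:
            pid = rec[f"pattern_{lineage}"]
            row[f"pattern_{lineage}"] = pid
            row[f"levels_{lineage}"] = tuple(level_map[pid])
        rows.append(row)
    base_cols = ["chrom", "start", "end", "layer"] + [
        c for lg in lineages for c in (f"pattern_{lg}", f"levels_{lg}")
    ]
    truth = TruthTable(
        intervals=pd.DataFrame(rows, columns=base_cols if not rows else None),
        config=config,
        architecture=arch,
        pattern_catalog=catalog,
    )
    return arch, truth


def _sample_counts(rng, n_sites: int, coverage_mean: float, p_protect: np.ndarray):
    total = rng.poisson(coverage_mean, size=n_sites)
    meth = rng.binomial(total, p_protect)
    return meth, total


def simulate_wgbs(
    architecture: MethylomeArchitecture,
    truth: TruthTable,
    lineage: str,
    condition: str,
    config: SimulationConfig | None = None,
    coverage_mean: float | None = None,
) -> MethylomeTrack:
    """Sample a WGBS track for one (lineage, condition).

    Per CpG: coverage ~ Poisson(coverage_mean) and protected reads ~
    Binomial(coverage, p) with p = level + (1 - level)(1 - conversion):
    modified cytosines always read protected, unmethylated ones read
    protected only on conversion failure.  Non-CpG cytosines are planted
    fully unmethylated.  Deterministic for a fixed config seed.
    """
    config = config if config is not None else truth.config
    cov = coverage_mean if coverage_mean is not None else config.coverage_mean
    rng = _child_rng(config.seed, "wgbs", lineage, condition)
    frames = []
    for chrom in sorted(architecture.cpg_positions):
        pos = architecture.cpg_positions[chrom]
        level = truth.modified_level(lineage, condition, chrom)
        p = level + (1.0 - level) * (1.0 - config.conversion_rate)
        meth, total = _sample_counts(rng, len(pos), cov, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": "+",
                    "context": "CpG",
                    "meth": meth,
                    "total": total,
                }
            )
        )
        # unmethylated non-CpG cytosines for conversion-rate estimation
        n_nc = config.non_cpg_per_chrom
        if n_nc:
            nc_pos = np.sort(
                rng.choice(architecture.chrom_lengths[chrom], size=n_nc, replace=False)
            )
            p_nc = np.full(n_nc, 1.0 - config.conversion_rate)
            meth_nc, total_nc = _sample_counts(rng, n_nc, cov, p_nc)
            ctx = rng.choice(["CHH", "CHG"], size=n_nc, p=[0.7, 0.3])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": nc_pos,
                        "strand": "+",
                        "context": ctx,
                        "meth": meth_nc,
                        "total": total_nc,
                    }
                )
            )
    sites = pd.concat(frames, ignore_index=True)[SITE_COLUMNS]
    # drop non-CpG positions colliding with CpGs (rare)
    sites = sites.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return MethylomeTrack(f"{lineage}_{condition}_wgbs", sites)


def _tab_protection(u, m, h, eff_f, eff_g, conv):
    return (
        h * (eff_g + (1 - eff_g) * (1 - conv))
        + m * ((1 - eff_f) + eff_f * (1 - conv))
        + u * (1 - conv)
    )


def simulate_tabseq(
    architecture: MethylomeArchitecture,
    truth: TruthTable,
    lineage: str,
    condition: str,
    config: SimulationConfig | None = None,
    coverage_mean: float | None = None,
) -> tuple[MethylomeTrack, dict[str, MethylomeTrack]]:
    """Sample a TAB-Seq track plus its spike-in control tracks.

    Protection probability per CpG follows the hydroxymeth forward
    model.  Spike-ins are synthetic chromosomes ("spike_hmc",
    "spike_mc", "spike_unmeth") of pure composition sampled with the
    same efficiencies and conversion rate.
    """
    config = config if config is not None else truth.config
    cov = coverage_mean if coverage_mean is not None else config.coverage_mean
    ts = config.tabseq
    for name, v in (("f_ox", ts.f_ox), ("g_protect", ts.g_protect)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    rng = _child_rng(config.seed, "tabseq", lineage, condition)
    frames = []
    for chrom in sorted(architecture.cpg_positions):
        pos = architecture.cpg_positions[chrom]
        u, m, h = truth.cytosine_simplex(lineage, condition, chrom)
        p = _tab_protection(u, m, h, ts.f_ox, ts.g_protect, config.conversion_rate)
        meth, total = _sample_counts(rng, len(pos), cov, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": "+",
                    "context": "CpG",
                    "meth": meth,
                    "total": total,
                }
            )
        )
    track = MethylomeTrack(
        f"{lineage}_{condition}_tabseq", pd.concat(frames, ignore_index=True)[SITE_COLUMNS]
    )

    spikes = {}
    compositions = {
        "spike_hmc": (0.0, 0.0, 1.0),
        "spike_mc": (0.0, 1.0, 0.0),
        "spike_unmeth": (1.0, 0.0, 0.0),
    }
    for name, (su, sm, sh) in compositions.items():
        p = _tab_protection(su, sm, sh, ts.f_ox, ts.g_protect, config.conversion_rate)
        pos = np.arange(ts.spike_sites) * 10 + 10
        total = rng.poisson(ts.spike_coverage, size=ts.spike_sites)
        meth = rng.binomial(total, p)
        spikes[name] = MethylomeTrack(
            name,
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "strand": "+",
                    "context": "CpG",
                    "meth": meth,
                    "total": total,
                }
            )[SITE_COLUMNS],
        )
    return track, spikes


def emit_fixture(
    architecture: MethylomeArchitecture,
    truth: TruthTable,
    out_dir,
    config: SimulationConfig | None = None,
    tabseq_for: tuple[tuple[str, str], ...] = (("B1a", "WT"), ("B2", "WT")),
) -> dict:
    """Write a complete on-disk fixture and return the file manifest.

    Emits per-(lineage, condition) methcounts-style WGBS tracks, TAB-Seq
    tracks with spike-ins for the requested pairs, BED files of the
    planted truth intervals and TSS annotations, a gene table linking
    each DME to its nearest gene, and the truth table (TSV).  Everything
    reloads through methdyn.io; a fixed seed gives a byte-identical
    fixture.
    """
    config = config if config is not None else truth.config
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, str] = {}

    def path(name):
        p = os.path.join(out_dir, name)
        manifest[name] = p
        return p

    for lineage in config.lineages:
        for condition in config.conditions:
            track = simulate_wgbs(architecture, truth, lineage, condition, config)
            write_methcounts(track, path(f"wgbs_{lineage}_{condition}.meth"))
    for lineage, condition in tabseq_for:
        track, spikes = simulate_tabseq(architecture, truth, lineage, condition, config)
        write_methcounts(track, path(f"tabseq_{lineage}_{condition}.meth"))
        for name, sp in spikes.items():
            write_methcounts(sp, path(f"tabseq_{lineage}_{condition}_{name}.meth"))

    write_bed(
        architecture.foundational_hmrs.assign(
            name=np.where(architecture.foundational_hmrs["is_canyon"], "canyon", "hmr")
        )[["chrom", "start", "end", "name"]],
        path("truth_foundational.bed"),
    )
    dme_cols = ["chrom", "start", "end"] + [
        f"pattern_{lg}" for lg in config.lineages
    ]
    write_bed(architecture.dme_intervals[dme_cols], path("truth_dme.bed"))
    tss = architecture.tss_positions
    write_bed(
        pd.DataFrame(
            {
                "chrom": tss["chrom"],
                "start": tss["pos"],
                "end": tss["pos"] + 1,
                "name": tss["gene"],
                "score": 0,
                "strand": tss["strand"],
            }
        ),
        path("tss.bed"),
    )
    # gene table: each DME linked to its nearest planted gene
    from methdyn.intervals import nearest_tss

    near = nearest_tss(architecture.dme_intervals, tss)
    gene_table = architecture.dme_intervals[["chrom", "start", "end"]].copy()
    gene_table["nearest_gene"] = near["nearest_gene"].to_numpy()
    gene_table["tss_distance"] = near["tss_distance"].to_numpy()
    gene_table.to_csv(path("dme_genes.tsv"), sep="\t", index=False)

    tt = truth.intervals.copy()
    for lineage in config.lineages:
        tt[f"levels_{lineage}"] = [
            ",".join(format(x, ".3g") for x in lv) for lv in tt[f"levels_{lineage}"]
        ]
    tt.to_csv(path("truth_table.tsv"), sep="\t", index=False)

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(sorted(manifest), fh, indent=1)
    return manifest


def default_fixture(seed: int = 0, scale: float = 1.0):
    """The standard two-lineage, three-condition synthetic study.

    Two chromosomes of 1 Mb, 100 bp mean CpG spacing, 30 foundational
    HMRs + 3 canyons, 40 DMEs per genome.  Pattern weights follow the
    study design qualitatively: in the B1a lineage ~75% of DMEs lose
    methylation during development (patterns P1 and P7), while the B2
    lineage is dominated by stably methylated, knockout-erased patterns.
    ``scale`` shrinks the genome and interval counts proportionally.

    Returns (architecture, truth, config).
    """
    config = SimulationConfig(seed=seed)
    genome = generate_genome(
        n_chroms=2,
        chrom_length=int(1_000_000 * scale),
        cpg_spacing_mean=100.0,
        seed=seed,
    )
    chrom_lengths = {c: int(1_000_000 * scale) for c in genome}
    catalog = default_pattern_catalog()
    ids = [p.id for p in catalog]
    w_b1a = {"P1": 0.45, "P7": 0.30, "P4": 0.08, "P9": 0.07, "P5": 0.05, "P6": 0.05}
    w_b2 = {"P6": 0.40, "P7": 0.20, "P1": 0.15, "P5": 0.10, "P10": 0.08, "P11": 0.07}
    weights = {
        "B1a": np.array([w_b1a.get(i, 0.0) for i in ids]),
        "B2": np.array([w_b2.get(i, 0.0) for i in ids]),
    }
    arch, truth = plant_architecture(
        genome,
        chrom_lengths,
        n_foundational=max(int(30 * scale), 4),
        n_dme=max(int(40 * scale), 6),
        n_canyons=max(int(3 * scale), 1),
        pattern_catalog=catalog,
        pattern_weights=weights,
        seed=seed,
        config=config,
    )
    return arch, truth, config
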