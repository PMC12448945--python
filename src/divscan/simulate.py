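"""Seeded synthetic multi-species cohort with planted ground truth.

The generator emulates the statistical structure the analysis assumes, not
sequence-level realism: per-bp heterozygous-site probabilities with
chromosome-class and hotspot multipliers, planted low-heterozygosity ROH
tracts, independent per-site missingness, interspecific variant densities
elevated in the same hotspot intervals, a repeat mask, and gene annotations
whose configured families cluster inside hotspots. Every planted feature is
recorded in a machine-readable :class:`TruthLedger`.

Site emission is sparse: only informative positions (HET, HOM_ALT and the
QC-failing records that will become missing) are materialised, and a
per-window sidecar carries the count of missing positions that were never
written, so window denominators stay exact while files stay small. A dense
mode materialises HOM_REF positions too, for brute-force oracle tests.

All sampling flows from one integer seed through a ``numpy`` SeedSequence
spawn tree, so identical (config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .divergence import PairwiseTrack
from .genome import GenomeIndex
from .intervals import IntervalSet
from .site_io import HET, HOM_ALT, MISSING, make_sites

__all__ = [
    "ChromPlan", "HotspotPlan", "ROHTract", "GenePlan", "SimConfig",
    "TruthLedger", "Cohort", "simulate_cohort", "scaled_default_config",
]


# ----------------------------------------------------------------- config
@dataclass(frozen=True)
class ChromPlan:
    name: str
    length: int
    micro: bool


@dataclass(frozen=True)
class HotspotPlan:
    chrom: str
    start: int
    end: int
    het_multiplier: float
    dist_multiplier: float
    shared: bool = True


@dataclass(frozen=True)
class ROHTract:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class GenePlan:
    family_sizes: dict[str, int]
    cluster_factors: dict[str, float]
    min_gene_len: int = 2_000
    max_gene_len: int = 15_000
    second_isoform_fraction: float = 0.2


@dataclass
class SimConfig:
    species: list[str]
    chroms: list[ChromPlan]
    macro_threshold: int
    baseline_het: float
    micro_het_multiplier: float
    hotspots: list[HotspotPlan]
    roh_plans: dict[str, list[ROHTract]]
    gene_plan: GenePlan
    roh_het_factor: float = 0.02
    missing_rate: float = 0.05
    hom_alt_rate: float = 5e-4
    lowmq_rate: float = 0.02
    multiallelic_rate: float = 0.005
    mean_depth: float = 30.0
    mask_fraction: float = 0.02
    mask_block: int = 1_000
    baseline_divergence: float = 0.02
    aligned_fraction: float = 0.8
    window_size: int = 50_000
    div_window_size: int = 10_000
    seed: int = 42

    def index(self) -> GenomeIndex:
        return GenomeIndex(tuple(c.name for c in self.chroms), tuple(c.length for c in self.chroms))

    def validate(self) -> "SimConfig":
        idx = self.index()
        rates = (self.baseline_het, self.missing_rate, self.hom_alt_rate, self.lowmq_rate,
                 self.multiallelic_rate, self.mask_fraction, self.baseline_divergence,
                 self.aligned_fraction)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.micro_het_multiplier, self.roh_het_factor) <= 0:
            raise ValueError("multipliers must be > 0")
        for h in self.hotspots:
            if h.chrom not in idx or not 0 <= h.start < h.end <= idx.length_of(h.chrom):
                raise ValueError(f"hotspot interval outside chromosome: {h}")
            if h.het_multiplier <= 0 or h.dist_multiplier <= 0:
                raise ValueError(f"hotspot multipliers must be > 0: {h}")
        for sp, tracts in self.roh_plans.items():
            if sp not in self.species:
                raise ValueError(f"ROH plan for unknown species {sp!r}")
            for t in tracts:
                if t.chrom not in idx or not 0 <= t.start < t.end <= idx.length_of(t.chrom):
                    raise ValueError(f"ROH tract outside chromosome: {t}")
        return self

    # ------------------------------------------------------------- YAML I/O
    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["chroms"] = [ChromPlan(**c) for c in payload["chroms"]]
        payload["hotspots"] = [HotspotPlan(**h) for h in payload["hotspots"]]
        payload["roh_plans"] = {
            sp: [ROHTract(**t) for t in tracts] for sp, tracts in payload["roh_plans"].items()
        }
        payload["gene_plan"] = GenePlan(**payload["gene_plan"])
        return cls(**payload).validate()


# ------------------------------------------------------------ truth ledger
@dataclass
class TruthLedger:
    hotspots: list[dict]
    roh: dict[str, list[dict]]
    expected_chrom_het: dict[str, dict[str, float]]  # species -> chrom -> per-bp rate
    expected_froh: dict[str, float]
    family_counts: dict[str, dict[str, int]]  # family -> {total, planted_in_hotspot}

    def hotspot_intervals(self) -> IntervalSet:
        return IntervalSet.from_pairs((h["chrom"], h["start"], h["end"]) for h in self.hotspots)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        return cls(**json.loads(Path(path).read_text()))


# ----------------------------------------------------------------- cohort
@dataclass
class Cohort:
    config: SimConfig
    index: GenomeIndex
    sites: dict[str, pd.DataFrame]
    implicit_missing: dict[str, np.ndarray]  # per species, aligned to window grid
    window_grid: pd.DataFrame
    mask: IntervalSet
    tracks: dict[str, PairwiseTrack]  # keyed by "a__b"
    genes_gff3: str
    truth: TruthLedger

    def write(self, outdir) -> None:
        from .site_io import write_site_table_qc

        out = Path(outdir)
        (out / "sites").mkdir(parents=True, exist_ok=True)
        (out / "tracks").mkdir(exist_ok=True)
        self.index.to_tsv(out / "index.tsv")
        self.mask.to_bed(out / "mask.bed", chrom_order=self.index.names)
        grid = self.window_grid
        for sp in self.config.species:
            write_site_table_qc(self.sites[sp], out / "sites" / f"{sp}.sites.tsv")
            side = grid.copy()
            side["n_implicit_missing"] = self.implicit_missing[sp]
            side.to_csv(out / "sites" / f"{sp}.missing.tsv", sep="\t", index=False)
        for label, track in self.tracks.items():
            track.write(out / "tracks" / f"{label}.variants.tsv",
                        out / "tracks" / f"{label}.aligned.bed",
                        chrom_order=self.index.names)
        (out / "genes.gff3").write_text(self.genes_gff3)
        self.truth.to_json(out / "truth.json")
        self.config.to_yaml(out / "simconfig.yaml")


# --------------------------------------------------------------- internals
def _segments_with_rates(length, base_p, intervals_with_mult):
    """Split [0, length) at interval boundaries; yield (start, end, multiplier)."""
    points = {0, length}
    for s, e, _ in intervals_with_mult:
        points.update((s, e))
    bounds = sorted(points)
    for s, e in zip(bounds[:-1], bounds[1:]):
        mult = 1.0
        for is_, ie, m in intervals_with_mult:
            if is_ <= s and e <= ie:
                mult *= m
        yield s, e, base_p * mult


def _species_chrom_rate_map(config: SimConfig, species: str, chrom: ChromPlan):
    """Piecewise per-bp HET probability for one species on one chromosome."""
    base = config.baseline_het * (config.micro_het_multiplier if chrom.micro else 1.0)
    mods = []
    first = config.species[0]
    for h in config.hotspots:
        if h.chrom == chrom.name and (h.shared or species == first):
            mods.append((h.start, h.end, h.het_multiplier))
    for t in config.roh_plans.get(species, ()):
        if t.chrom == chrom.name:
            mods.append((t.start, t.end, config.roh_het_factor))
    return list(_segments_with_rates(chrom.length, base, mods))


def _simulate_species_sites(config: SimConfig, species: str, rng: np.random.Generator,
                            dense: bool = False):
    """Sample one species' site table + per-window implicit-missing counts."""
    m = config.missing_rate
    chroms_out, pos_out, gt_out = [], [], []
    implicit = []
    for chrom in config.chroms:
        rate_map = _species_chrom_rate_map(config, species, chrom)
        for wstart in range(0, chrom.length, config.window_size):
            wend = min(wstart + config.window_size, chrom.length)
            n_implicit = 0
            for s, e, p_het in rate_map:
                lo, hi = max(s, wstart), min(e, wend)
                if lo >= hi:
                    continue
                L = hi - lo
                p = [m, p_het * (1 - m), config.hom_alt_rate * (1 - m)]
                p.append(1.0 - sum(p))
                n_miss, n_het, n_alt, n_ref = rng.multinomial(L, p)
                k = n_het + n_alt
                if k:
                    offsets = rng.choice(L, size=k, replace=False)
                    offsets.sort()
                    gts = np.full(k, HOM_ALT, dtype=np.int8)
                    het_idx = rng.choice(k, size=n_het, replace=False)
                    gts[het_idx] = HET
                    chroms_out.extend([chrom.name] * k)
                    pos_out.append(offsets + lo + 1)
                    gt_out.append(gts)
                if dense and n_ref:
                    # materialise HOM_REF positions (everything not het/alt/missing)
                    taken = set((offsets + lo).tolist()) if k else set()
                    miss_pool = [x for x in range(lo, hi) if x not in taken]
                    miss_sel = rng.choice(len(miss_pool), size=n_miss, replace=False) if n_miss else []
                    miss_set = {miss_pool[i] for i in np.asarray(miss_sel, dtype=int)}
                    ref_positions = [x for x in miss_pool if x not in miss_set]
                    chroms_out.extend([chrom.name] * len(ref_positions))
                    pos_out.append(np.asarray(ref_positions, dtype=np.int64) + 1)
                    gt_out.append(np.zeros(len(ref_positions), dtype=np.int8))
                    chroms_out.extend([chrom.name] * len(miss_set))
                    pos_out.append(np.asarray(sorted(miss_set), dtype=np.int64) + 1)
                    gt_out.append(np.full(len(miss_set), MISSING, dtype=np.int8))
                else:
                    n_implicit += int(n_miss)
            implicit.append(n_implicit)

    pos = np.concatenate(pos_out) if pos_out else np.empty(0, dtype=np.int64)
    gt = np.concatenate(gt_out) if gt_out else np.empty(0, dtype=np.int8)
    n = len(pos)
    depth = rng.poisson(config.mean_depth, size=n).astype(float)
    mq = np.where(rng.random(n) < config.lowmq_rate, 20.0, 60.0)
    variant = (gt == HET) | (gt == HOM_ALT)
    biallelic = ~(variant & (rng.random(n) < config.multiallelic_rate))
    sites = make_sites(np.asarray(chroms_out, dtype=object), pos, gt, depth, mq, biallelic)
    # stable (chrom-order, pos) sort within chromosome blocks (already grouped)
    return sites, np.asarray(implicit, dtype=np.int64)


def _simulate_mask(config: SimConfig, rng: np.random.Generator) -> IntervalSet:
    pairs = []
    for chrom in config.chroms:
        n_blocks = chrom.length // config.mask_block
        k = int(round(config.mask_fraction * n_blocks))
        if k == 0:
            continue
        chosen = np.sort(rng.choice(n_blocks, size=k, replace=False))
        for b in chosen:
            s = int(b) * config.mask_block
            pairs.append((chrom.name, s, min(s + config.mask_block, chrom.length)))
    return IntervalSet.from_pairs(pairs) if pairs else IntervalSet()


def _aligned_intervals(config: SimConfig) -> IntervalSet:
    """Deterministic aligned-coverage pattern: within every window_size block,
    the first round(aligned_fraction * block / div_size) divergence windows
    are aligned, the remainder is an alignment gap."""
    per_block = int(round(config.aligned_fraction * config.window_size / config.div_window_size))
    pairs = []
    for chrom in config.chroms:
        for b in range(0, chrom.length, config.window_size):
            e = min(b + per_block * config.div_window_size, chrom.length)
            if e > b:
                pairs.append((chrom.name, b, e))
    return IntervalSet.from_pairs(pairs)


def _simulate_track(config: SimConfig, species_b: str, aligned: IntervalSet,
                    rng: np.random.Generator) -> PairwiseTrack:
    chroms_out, pos_out = [], []
    for chrom in config.chroms:
        mods = [(h.start, h.end, h.dist_multiplier) for h in config.hotspots if h.chrom == chrom.name]
        rate_map = list(_segments_with_rates(chrom.length, config.baseline_divergence, mods))
        for a_start, a_end in aligned.restricted_to(chrom.name):
            for s, e, d in rate_map:
                lo, hi = max(s, a_start), min(e, a_end)
                if lo >= hi:
                    continue
                L = hi - lo
                k = rng.binomial(L, min(d, 1.0))
                if k:
                    offsets = rng.choice(L, size=k, replace=False)
                    offsets.sort()
                    chroms_out.extend([chrom.name] * k)
                    pos_out.append(offsets + lo + 1)
    pos = np.concatenate(pos_out) if pos_out else np.empty(0, dtype=np.int64)
    variants = pd.DataFrame({"chrom": np.asarray(chroms_out, dtype=object), "pos": pos})
    return PairwiseTrack(config.species[0], species_b, variants, aligned).validate()


_FAMILY_TERM_TEMPLATES = {
    "MHC": "major histocompatibility complex class I antigen {i}",
    "OR": "olfactory receptor family member {i}",
    "GPCR": "G protein-coupled receptor {i}",
    "ZNF": "zinc finger protein {i}",
    "IMMUNE": "interleukin receptor subunit {i}",
    "OTHER": "hypothetical protein LOC{i}",
}


def _uniform_in_intervals(iset: IntervalSet, index: GenomeIndex, n: int,
                          rng: np.random.Generator):
    """n positions uniform over the bp of an interval set, as (chrom, pos0)."""
    chroms, arrs, cums = [], [], []
    total = 0
    for name in index.names:
        arr = iset.restricted_to(name)
        for s, e in arr:
            chroms.append(name)
            arrs.append((s, e))
            cums.append(total)
            total += e - s
    if total == 0:
        raise ValueError("cannot place genes in an empty interval set")
    draws = rng.integers(0, total, size=n)
    out = []
    cums = np.asarray(cums)
    for d in draws:
        i = int(np.searchsorted(cums, d, side="right") - 1)
        s, _ = arrs[i]
        out.append((chroms[i], int(s + (d - cums[i]))))
    return out


def _simulate_genes(config: SimConfig, index: GenomeIndex, hotspot_set: IntervalSet,
                    rng: np.random.Generator):
    """Place genes with family-conditional hotspot weights; return (gff3 text,
    family placement counts)."""
    gp = config.gene_plan
    frac_hot = hotspot_set.total_bp() / index.total_bp if hotspot_set else 0.0
    complement = hotspot_set.complement(index.as_dict()) if hotspot_set else None
    records = []
    counts: dict[str, dict[str, int]] = {}
    gid = 0
    for family in sorted(gp.family_sizes):
        n_f = gp.family_sizes[family]
        cf = gp.cluster_factors.get(family, 1.0)
        if frac_hot > 0:
            p_in = cf * frac_hot / (1 - frac_hot + cf * frac_hot)
        else:
            p_in = 0.0
        n_in = int(rng.binomial(n_f, p_in)) if p_in > 0 else 0
        placements = []
        if n_in:
            placements += _uniform_in_intervals(hotspot_set, index, n_in, rng)
        if n_f - n_in:
            outside = complement if complement is not None else IntervalSet.from_pairs(
                (name, 0, length) for name, length in index)
            placements += _uniform_in_intervals(outside, index, n_f - n_in, rng)
        counts[family] = {"total": n_f, "planted_in_hotspot": n_in}
        for chrom, start0 in placements:
            gid += 1
            length = int(rng.integers(gp.min_gene_len, gp.max_gene_len + 1))
            end0 = min(start0 + length, index.length_of(chrom))
            if end0 - start0 < 2:
                start0 = max(0, end0 - 2)
            term = _FAMILY_TERM_TEMPLATES[family].format(i=gid)
            two_isoforms = rng.random() < gp.second_isoform_fraction and end0 - start0 >= 1_000
            records.append((chrom, start0, end0, f"gene{gid:05d}", term, two_isoforms))

    order = {name: i for i, name in enumerate(index.names)}
    records.sort(key=lambda r: (order[r[0]], r[1], r[3]))
    lines = ["##gff-version 3"]
    for name, length in index:
        lines.append(f"##sequence-region {name} 1 {length}")
    for chrom, start0, end0, gene_id, term, two_isoforms in records:
        s1, e1 = start0 + 1, end0
        lines.append(
            f"{chrom}\tdivscan_sim\tgene\t{s1}\t{e1}\t.\t+\t.\t"
            f"ID={gene_id};functional_terms={term}"
        )
        lines.append(
            f"{chrom}\tdivscan_sim\tmRNA\t{s1}\t{e1}\t.\t+\t.\t"
            f"ID={gene_id}.t1;Parent={gene_id}"
        )
        lines.append(f"{chrom}\tdivscan_sim\texon\t{s1}\t{e1}\t.\t+\t.\t"
                     f"ID={gene_id}.t1.e1;Parent={gene_id}.t1")
        if two_isoforms:
            short_e = s1 + (e1 - s1) // 2
            lines.append(
                f"{chrom}\tdivscan_sim\tmRNA\t{s1}\t{short_e}\t.\t+\t.\t"
                f"ID={gene_id}.t2;Parent={gene_id}"
            )
            lines.append(f"{chrom}\tdivscan_sim\texon\t{s1}\t{short_e}\t.\t+\t.\t"
                         f"ID={gene_id}.t2.e1;Parent={gene_id}.t2")
    return "\n".join(lines) + "\n", counts


def _expected_chrom_het(config: SimConfig, species: str) -> dict[str, float]:
    """Length-weighted generative HET probability per chromosome (before
    missingness and QC, which thin sites uniformly)."""
    out = {}
    for chrom in config.chroms:
        total = sum((e - s) * p for s, e, p in _species_chrom_rate_map(config, species, chrom))
        out[chrom.name] = total / chrom.length
    return out


# ------------------------------------------------------------- entry points
def simulate_cohort(config: SimConfig, seed: int | None = None, dense: bool = False) -> Cohort:
    """Generate the full cohort; ``seed`` overrides ``config.seed``."""
    config.validate()
    index = config.index()
    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    # fixed spawn layout: mask, genes, then one stream per species, per track
    streams = ss.spawn(2 + len(config.species) + max(len(config.species) - 1, 0))
    rng_mask = np.random.default_rng(streams[0])
    rng_genes = np.random.default_rng(streams[1])
    species_streams = streams[2 : 2 + len(config.species)]
    track_streams = streams[2 + len(config.species):]

    mask = _simulate_mask(config, rng_mask)

    from .window_stats import make_windows
    grid = make_windows(index, size=config.window_size)[["chrom", "start", "end"]]

    sites, implicit = {}, {}
    for sp, stream in zip(config.species, species_streams):
        s, im = _simulate_species_sites(config, sp, np.random.default_rng(stream), dense=dense)
        sites[sp] = s
        implicit[sp] = im if not dense else np.zeros(len(grid), dtype=np.int64)

    aligned = _aligned_intervals(config)
    tracks = {}
    for sp, stream in zip(config.species[1:], track_streams):
        track = _simulate_track(config, sp, aligned, np.random.default_rng(stream))
        tracks[track.label] = track

    hotspot_set = (
        IntervalSet.from_pairs((h.chrom, h.start, h.end) for h in config.hotspots)
        if config.hotspots else IntervalSet()
    )
    gff3, family_counts = _simulate_genes(config, index, hotspot_set, rng_genes)

    truth = TruthLedger(
        hotspots=[dataclasses.asdict(h) for h in config.hotspots],
        roh={sp: [dataclasses.asdict(t) for t in tracts] for sp, tracts in config.roh_plans.items()},
        expected_chrom_het={sp: _expected_chrom_het(config, sp) for sp in config.species},
        expected_froh={
            sp: sum(t.end - t.start for t in config.roh_plans.get(sp, ())) / index.total_bp
            for sp in config.species
        },
        family_counts=family_counts,
    )
    return Cohort(config, index, sites, implicit, grid, mask, tracks, gff3, truth)


def scaled_default_config() -> SimConfig:
    """Desk-scale stand-in for a 7-species, 28-chromosome marine-turtle
    cohort: 11 macrochromosomes of 2 Mb, 17 microchromosomes of 0.5 Mb
    (macro threshold scaled to 1 Mb), shared diversity/divergence hotspots on
    chromosomes 13, 14 and 24, one species with high planted inbreeding
    (FROH 0.20), one with none, the rest moderate."""
    species = ["dermochelys", "chelonia", "caretta", "eretmochelys",
               "lepidochelys_olivacea", "lepidochelys_kempii", "natator"]
    chroms = [ChromPlan(f"chr{i}", 2_000_000, micro=False) for i in range(1, 12)]
    chroms += [ChromPlan(f"chr{i}", 500_000, micro=True) for i in range(12, 29)]
    hotspots = [
        HotspotPlan("chr13", 200_000, 250_000, het_multiplier=8.0, dist_multiplier=3.0),
        HotspotPlan("chr14", 300_000, 350_000, het_multiplier=8.0, dist_multiplier=3.0),
        HotspotPlan("chr24", 100_000, 150_000, het_multiplier=8.0, dist_multiplier=3.0),
    ]
    moderate = [ROHTract("chr7", 200_000, 800_000), ROHTract("chr8", 500_000, 1_500_000)]
    roh_plans = {
        "natator": [
            ROHTract("chr1", 0, 2_000_000),
            ROHTract("chr2", 0, 1_500_000),
            ROHTract("chr3", 0, 800_000),
            ROHTract("chr4", 0, 600_000),
            ROHTract("chr5", 0, 700_000),
            ROHTract("chr6", 500_000, 1_000_000),
        ],
        "lepidochelys_olivacea": [],
        "chelonia": list(moderate),
        "caretta": list(moderate),
        "eretmochelys": list(moderate),
        "lepidochelys_kempii": list(moderate),
        "dermochelys": list(moderate),
    }
    gene_plan = GenePlan(
        family_sizes={"OR": 300, "ZNF": 200, "GPCR": 150, "IMMUNE": 150, "MHC": 60, "OTHER": 1140},
        cluster_factors={"OR": 10.0},
    )
    return SimConfig(
        species=species,
        chroms=chroms,
        macro_threshold=1_000_000,
        baseline_het=1e-3,
        micro_het_multiplier=3.0,
        hotspots=hotspots,
        roh_plans=roh_plans,
        gene_plan=gene_plan,
    ).validate()
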