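"""Ground-truth simulator for every pipeline input.

Generates chromosome tables and gene models, peak sets with planted
emerging peaks, Poisson accessibility count matrices, DE gene lists
enriched near planted peaks, CNE intervals with a controlled overlap
fraction, and 400 bp positive/control sequence sets with planted
(optionally co-occurring) PWM instances. Identical (config, seed) yields
byte-identical output files.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as rio
from .core import GeneModel, Interval, Peak, overlaps
from .diff_accessibility import CountMatrix
from .cnn.model import CROP, ELEMENT_LENGTH, SequenceElement
from .motiflib import builtin_motifs, reverse_complement, sample_site

# distinct rng stream per operation, all derived from config.seed
_STREAM_GENOME = 1
_STREAM_PEAKS = 2
_STREAM_DE = 3
_STREAM_CNE = 4
_STREAM_SEQ = 5


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 4
    chromosome_length: int = 5_000_000
    n_genes: int = 100
    n_peaks_shared: int = 200
    n_peaks_emerging_per_celltype: int = 40
    n_cells_per_group: int = 50
    accessibility_rate_background: float = 1.0
    accessibility_fold_change: float = 4.0
    de_gene_fraction_near_rre: float = 0.8
    de_background_rate: float = 0.05
    cne_overlap_fraction: float = 0.5
    n_cnes_background: int = 40
    motif_plant_frequency: float = 0.3
    cooccur_plant_frequency: float = 0.6
    cooccur_distance_bp: int = 60
    gc_content: float = 0.40
    n_positives: int = 1000
    n_controls: Optional[int] = None
    peak_width: int = 200
    control_rate_factor: float = 0.05  # emerging-peak rate in control cells
    cell_types: Tuple[str, ...] = ("SC", "PC", "HC")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "de_gene_fraction_near_rre", "de_background_rate", "cne_overlap_fraction",
            "motif_plant_frequency", "cooccur_plant_frequency", "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in (
            "n_chromosomes", "n_genes", "n_peaks_shared",
            "n_peaks_emerging_per_celltype", "n_cells_per_group",
            "n_cnes_background", "n_positives",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chromosome_length < 10_000:
            raise ValueError("chromosome_length must be >= 10,000")
        if self.accessibility_fold_change < 1.0:
            raise ValueError("accessibility_fold_change must be >= 1")
        if not 0 < self.cooccur_distance_bp <= 90:
            raise ValueError("cooccur_distance_bp must be in (0, 90]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def holdout_chroms(self) -> Set[str]:
        """Last two chromosomes, the synthetic analogue of a chr8/9 holdout."""
        return set(self.chrom_names[-2:])


@dataclass
class TruthManifest:
    """Ground truth for planted structure, kept in step with emitted files."""

    emerging_peak_ids: Dict[str, List[str]] = field(default_factory=dict)
    emerging_peaks: Dict[str, List[Peak]] = field(default_factory=dict)
    de_gene_ids: List[str] = field(default_factory=list)
    genes_near_rre: List[str] = field(default_factory=list)
    planted_motif_instances: List[Tuple[str, str, int, str]] = field(default_factory=list)
    planted_cooccurring_pairs: List[Tuple[str, str]] = field(default_factory=list)
    planted_decoy_pairs: List[Tuple[str, str]] = field(default_factory=list)
    cne_overlapping_rre_ids: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "emerging_peak_ids": self.emerging_peak_ids,
            "de_gene_ids": self.de_gene_ids,
            "genes_near_rre": self.genes_near_rre,
            "planted_motif_instances": [list(t) for t in self.planted_motif_instances],
            "planted_cooccurring_pairs": [list(t) for t in self.planted_cooccurring_pairs],
            "planted_decoy_pairs": [list(t) for t in self.planted_decoy_pairs],
            "cne_overlapping_rre_ids": self.cne_overlapping_rre_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome


def make_genome(config: SyntheticConfig) -> Tuple[Dict[str, int], List[GeneModel]]:
    """Random non-overlapping gene bodies over chr1..chrN."""
    rng = config.rng(_STREAM_GENOME)
    sizes = {c: config.chromosome_length for c in config.chrom_names}
    genes: List[GeneModel] = []
    if config.n_genes == 0:
        return sizes, genes
    per_chrom = np.zeros(config.n_chromosomes, dtype=int)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    per_chrom += config.n_genes // config.n_chromosomes
    gi = 0
    for chrom, k in zip(config.chrom_names, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(1000, 5001, size=k)
        total = int(lengths.sum())
        if total > config.chromosome_length:
            raise ValueError(
                f"infeasible packing: {k} genes of total length {total} "
                f"do not fit in {chrom} ({config.chromosome_length} bp)"
            )
        slack = config.chromosome_length - total
        offsets = np.sort(rng.integers(0, slack + 1, size=k))
        starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.choice(["+", "-"], size=k)
        for s, length, strand in zip(starts, lengths, strands):
            gi += 1
            genes.append(
                GeneModel(f"gene{gi:05d}", chrom, int(s), int(s + length), str(strand))
            )
    return sizes, genes


# ---------------------------------------------------------------------------
# peaks and counts


@dataclass
class SimulatedAccessibility:
    control_peaks: Dict[str, List[Peak]]
    treated_peaks: Dict[str, List[Peak]]
    count_matrices: Dict[str, CountMatrix]  # per cell type; both groups' cells
    truth: TruthManifest


class _Placer:
    """Rejection-samples peak centers with a minimum same-chromosome spacing."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator,
                 min_spacing: int = 300):
        self.config = config
        self.rng = rng
        self.min_spacing = min_spacing
        self.centers: Dict[str, List[int]] = {c: [] for c in config.chrom_names}

    def _ok(self, chrom: str, center: int) -> bool:
        return all(abs(center - c) >= self.min_spacing for c in self.centers[chrom])

    def place_anywhere(self) -> Tuple[str, int]:
        half = self.config.peak_width // 2
        margin = half + 25  # leaves room for control-condition jitter
        for _ in range(1000):
            chrom = self.config.chrom_names[self.rng.integers(self.config.n_chromosomes)]
            center = int(self.rng.integers(margin, self.config.chromosome_length - margin))
            if self._ok(chrom, center):
                self.centers[chrom].append(center)
                return chrom, center
        raise RuntimeError("could not place peak: chromosome too crowded")

    def place_near(self, gene: GeneModel, max_dist: int = 45_000) -> Tuple[str, int]:
        half = self.config.peak_width // 2
        lo = max(half, gene.start - max_dist)
        hi = min(self.config.chromosome_length - half, gene.end + max_dist)
        for _ in range(1000):
            center = int(self.rng.integers(lo, hi))
            if self._ok(gene.chrom, center):
                self.centers[gene.chrom].append(center)
                return gene.chrom, center
        raise RuntimeError(f"could not place peak near gene {gene.gene_id}")


def simulate_peaks_and_counts(
    config: SyntheticConfig,
    genome: Tuple[Dict[str, int], List[GeneModel]],
    near_gene_fraction: float = 0.8,
) -> SimulatedAccessibility:
    """Shared + emerging peak sets and Poisson count matrices per cell type.

    Shared peaks appear in both conditions at the background rate. Emerging
    peaks appear in treated cells at background x fold_change and at
    control_rate_factor x background in control cells. At least
    near_gene_fraction of emerging peaks are placed within 50 kb of a gene
    body so peak-to-gene linkage is recoverable.
    """
    if config.n_cells_per_group < 2:
        raise ValueError("n_cells_per_group must be >= 2")
    sizes, genes = genome
    rng = config.rng(_STREAM_PEAKS)
    placer = _Placer(config, rng)
    half = config.peak_width // 2

    shared: List[Peak] = []
    for i in range(config.n_peaks_shared):
        chrom, center = placer.place_anywhere()
        shared.append(
            Peak(chrom, center - half, center + half, f"shared{i + 1:05d}")
        )

    truth = TruthManifest()
    control_peaks: Dict[str, List[Peak]] = {}
    treated_peaks: Dict[str, List[Peak]] = {}
    count_matrices: Dict[str, CountMatrix] = {}

    for ct in config.cell_types:
        emerging: List[Peak] = []
        n_emerging = config.n_peaks_emerging_per_celltype
        n_near = int(np.ceil(near_gene_fraction * n_emerging)) if genes else 0
        for i in range(n_emerging):
            if i < n_near and genes:
                gene = genes[rng.integers(len(genes))]
                chrom, center = placer.place_near(gene)
            else:
                chrom, center = placer.place_anywhere()
            emerging.append(
                Peak(chrom, center - half, center + half,
                     f"{ct}_emerging{i + 1:05d}", cell_type=ct, condition="treated")
            )
        truth.emerging_peak_ids[ct] = [p.peak_id for p in emerging]
        truth.emerging_peaks[ct] = emerging

        # control condition: same shared peaks, jittered <=20 bp, own ids
        jitter = rng.integers(-20, 21, size=len(shared))
        control_peaks[ct] = [
            Peak(p.chrom, p.start + int(j), p.end + int(j),
                 f"{ct}_ctrl_{p.peak_id}", cell_type=ct, condition="control")
            for p, j in zip(shared, jitter)
        ]
        treated_peaks[ct] = [
            Peak(p.chrom, p.start, p.end, f"{ct}_{p.peak_id}",
                 cell_type=ct, condition="treated")
            for p in shared
        ] + emerging

        n_peaks = len(treated_peaks[ct])
        peak_ids = [p.peak_id for p in treated_peaks[ct]]
        bg = config.accessibility_rate_background
        rate_ctrl = np.full(n_peaks, bg)
        rate_trt = np.full(n_peaks, bg)
        emerging_cols = np.arange(len(shared), n_peaks)
        rate_ctrl[emerging_cols] = config.control_rate_factor * bg
        rate_trt[emerging_cols] = config.accessibility_fold_change * bg

        n = config.n_cells_per_group
        counts_ctrl = rng.poisson(rate_ctrl, size=(n, n_peaks))
        counts_trt = rng.poisson(rate_trt, size=(n, n_peaks))
        count_matrices[ct] = CountMatrix(
            counts=np.vstack([counts_ctrl, counts_trt]),
            cell_ids=[f"{ct}_ctrl_cell{i + 1:04d}" for i in range(n)]
            + [f"{ct}_trt_cell{i + 1:04d}" for i in range(n)],
            peak_ids=peak_ids,
            groups=["control"] * n + ["treated"] * n,
        )

    return SimulatedAccessibility(control_peaks, treated_peaks, count_matrices, truth)


# ---------------------------------------------------------------------------
# DE genes


def make_de_genes(
    genome: Tuple[Dict[str, int], List[GeneModel]],
    truth: TruthManifest,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Declare genes DE, enriched near planted emerging peaks.

    A gene is "near" an emerging peak when the peak lies within 50 kb of the
    gene body. Near genes become DE with probability de_gene_fraction_near_rre,
    others with de_background_rate. Updates truth.de_gene_ids.
    """
    sizes, genes = genome
    if not genes:
        raise ValueError("genome has no genes")
    rng = config.rng(_STREAM_DE)
    all_emerging = [p for peaks in truth.emerging_peaks.values() for p in peaks]

    def near_rre(g: GeneModel) -> bool:
        return any(
            p.chrom == g.chrom
            and overlaps(p.start, p.end, g.start - 50_000, g.end + 50_000)
            for p in all_emerging
        )

    rows = []
    near_ids = []
    for g in genes:
        near = near_rre(g)
        if near:
            near_ids.append(g.gene_id)
        prob = config.de_gene_fraction_near_rre if near else config.de_background_rate
        if rng.random() < prob:
            lfc = float(rng.uniform(0.25, 2.0) * rng.choice([-1.0, 1.0]))
            rows.append((g.gene_id, float(rng.uniform(0.0, 0.01)), lfc))
    df = pd.DataFrame(rows, columns=["gene_id", "p_value", "avg_log2FC"])
    truth.de_gene_ids = list(df["gene_id"])
    truth.genes_near_rre = near_ids
    return df


# ---------------------------------------------------------------------------
# CNEs


def make_cnes(
    truth: TruthManifest,
    config: SyntheticConfig,
    prefer_ids: Optional[Set[str]] = None,
    cne_width: int = 150,
) -> List[Interval]:
    """Place CNEs so that exactly round(fraction x n_emerging) emerging peaks
    get an overlapping CNE (>=1 bp); the rest go to peak-free background.

    When prefer_ids is given, overlapping CNEs are assigned to those peaks
    first (e.g. to concentrate conservation on DE-linked RREs).
    """
    all_emerging = [p for peaks in truth.emerging_peaks.values() for p in peaks]
    if not all_emerging:
        raise ValueError("no emerging peaks in the truth manifest")
    rng = config.rng(_STREAM_CNE)
    n_overlap = int(round(config.cne_overlap_fraction * len(all_emerging)))

    order = list(rng.permutation(len(all_emerging)))
    if prefer_ids:
        order.sort(key=lambda i: all_emerging[i].peak_id not in prefer_ids)
    chosen = [all_emerging[i] for i in order[:n_overlap]]

    cnes: List[Interval] = []
    for k, p in enumerate(chosen):
        # offset such that [start, start+width) intersects [p.start, p.end)
        lo = max(0, p.start - cne_width + 1)
        hi = min(config.chromosome_length - cne_width, p.end - 1)
        start = int(rng.integers(lo, hi + 1))
        cnes.append(Interval(p.chrom, start, start + cne_width, f"cne_ov{k + 1:04d}"))
    truth.cne_overlapping_rre_ids = [p.peak_id for p in chosen]

    # background CNEs at least 1 kb from every emerging peak
    placed = 0
    guard = 0
    while placed < config.n_cnes_background:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("could not place background CNEs")
        chrom = config.chrom_names[rng.integers(config.n_chromosomes)]
        start = int(rng.integers(0, config.chromosome_length - cne_width))
        if any(
            p.chrom == chrom and overlaps(start - 1000, start + cne_width + 1000,
                                          p.start, p.end)
            for p in all_emerging
        ):
            continue
        placed += 1
        cnes.append(Interval(chrom, start, start + cne_width, f"cne_bg{placed:04d}"))
    return cnes


# ---------------------------------------------------------------------------
# sequences with planted motifs


@dataclass
class PlantPlan:
    """What to plant in positive sequences.

    singles: (motif_name, frequency) planted independently; names listed in
    exclusive_group never co-occur in one sequence (at most one is kept).
    pairs: (name_a, name_b, frequency, max_start_distance) planted jointly.
    """

    singles: List[Tuple[str, float]] = field(default_factory=list)
    pairs: List[Tuple[str, str, float, int]] = field(default_factory=list)
    exclusive_group: Tuple[str, ...] = ()


def default_plant_plan(config: SyntheticConfig) -> PlantPlan:
    """SOXLIKE+SIXLIKE planted as a co-occurring pair; CREBLIKE and ETSLIKE
    planted singly and mutually exclusively (the decoy non-co-occurring pair)."""
    return PlantPlan(
        singles=[
            ("CREBLIKE", config.motif_plant_frequency),
            ("ETSLIKE", config.motif_plant_frequency),
        ],
        pairs=[
            ("SOXLIKE", "SIXLIKE", config.cooccur_plant_frequency,
             config.cooccur_distance_bp)
        ],
        exclusive_group=("CREBLIKE", "ETSLIKE"),
    )


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _plant(seq: List[str], site: str, start: int, occupied: List[Tuple[int, int]]) -> None:
    seq[start : start + len(site)] = list(site)
    occupied.append((start, start + len(site)))


def _free_slot(rng, width: int, occupied, lo: int, hi: int, tries: int = 100) -> int:
    """A start in [lo, hi] whose [start, start+width) hits no occupied span.

    Starts are snapped to the stride-3 grid of the classifier's first layer
    (phase 0 relative to the 50 bp crop) so every planted instance is fully
    covered by one first-layer window and is recoverable downstream.
    """
    n_slots = (hi - lo) // 3
    for _ in range(tries):
        start = lo + 3 * int(rng.integers(0, n_slots + 1))
        if all(not overlaps(start, start + width, a, b) for a, b in occupied):
            return start
    raise RuntimeError("planting collision: no free slot after 100 retries")


def make_sequences(
    truth: TruthManifest,
    config: SyntheticConfig,
    motif_library: Optional[Dict[str, np.ndarray]] = None,
    plan: Optional[PlantPlan] = None,
) -> Tuple[List[SequenceElement], List[SequenceElement]]:
    """400 bp positive and control sequence sets with planted PWM instances.

    Positives carry planted motif draws only inside the central 300 bp
    ([50, 350)); co-occurring pairs are planted with start-to-start distance
    <= the plan's max distance. Controls are pure background. Sequence ids
    encode a synthetic chromosome so a chromosome holdout is possible.
    Updates truth.planted_motif_instances / planted_cooccurring_pairs /
    planted_decoy_pairs.
    """
    motif_library = motif_library if motif_library is not None else builtin_motifs()
    plan = plan if plan is not None else default_plant_plan(config)
    for name, _ in plan.singles:
        if name not in motif_library:
            raise KeyError(f"plant plan references unknown motif {name!r}")
    for a, b, _, _ in plan.pairs:
        for name in (a, b):
            if name not in motif_library:
                raise KeyError(f"plant plan references unknown motif {name!r}")

    rng = config.rng(_STREAM_SEQ)
    chroms = config.chrom_names
    plant_lo, plant_hi = CROP, ELEMENT_LENGTH - CROP  # [50, 350)

    positives: List[SequenceElement] = []
    for i in range(config.n_positives):
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq_id = f"pos_{chrom}_{i + 1:05d}"
        seq = list(_random_background(rng, ELEMENT_LENGTH, config.gc_content))
        occupied: List[Tuple[int, int]] = []

        for a, b, freq, max_dist in plan.pairs:
            if rng.random() >= freq:
                continue
            wa, wb = motif_library[a].shape[1], motif_library[b].shape[1]
            # start-to-start distance: >= wa (no overlap), <= max_dist, and a
            # multiple of 3 so both sites stay on the first-layer window grid
            dist = 3 * int(rng.integers((wa + 2) // 3, max_dist // 3 + 1))
            start_a = _free_slot(rng, wa + dist + wb, occupied,
                                 plant_lo, plant_hi - (dist + wb))
            start_b = start_a + dist
            for name, start in ((a, start_a), (b, start_b)):
                strand = "+" if rng.random() < 0.5 else "-"
                site = sample_site(motif_library[name], rng)
                if strand == "-":
                    site = reverse_complement(site)
                _plant(seq, site, start, occupied)
                truth.planted_motif_instances.append((seq_id, name, start, strand))

        fired = [name for name, freq in plan.singles if rng.random() < freq]
        exclusive_fired = [n for n in fired if n in plan.exclusive_group]
        if len(exclusive_fired) > 1:
            keep = exclusive_fired[int(rng.integers(len(exclusive_fired)))]
            fired = [n for n in fired if n not in plan.exclusive_group or n == keep]
        for name in fired:
            w = motif_library[name].shape[1]
            start = _free_slot(rng, w, occupied, plant_lo, plant_hi - w)
            strand = "+" if rng.random() < 0.5 else "-"
            site = sample_site(motif_library[name], rng)
            if strand == "-":
                site = reverse_complement(site)
            _plant(seq, site, start, occupied)
            truth.planted_motif_instances.append((seq_id, name, start, strand))

        positives.append(SequenceElement(seq_id, chrom, "".join(seq), 1))

    n_controls = (
        config.n_controls if config.n_controls is not None else 11 * config.n_positives
    )
    controls = [
        SequenceElement(
            f"ctrl_{chroms[int(rng.integers(len(chroms)))]}_{i + 1:05d}",
            chroms[0],  # placeholder, replaced below
            _random_background(rng, ELEMENT_LENGTH, config.gc_content),
            0,
        )
        for i in range(n_controls)
    ]
    # fix chrom field to match the id
    controls = [
        SequenceElement(c.id, c.id.split("_")[1], c.sequence, 0) for c in controls
    ]

    truth.planted_cooccurring_pairs = [(a, b) for a, b, _, _ in plan.pairs]
    if len(plan.exclusive_group) >= 2:
        truth.planted_decoy_pairs = [tuple(plan.exclusive_group[:2])]
    return positives, controls


# ---------------------------------------------------------------------------
# orchestrator


def simulate_all(config: SyntheticConfig, outdir) -> TruthManifest:
    """Run every generator and write all pipeline inputs under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = make_genome(config)
    sizes, genes = genome
    rio.write_genome_sizes(sizes, outdir / "genome.sizes")
    rio.write_gtf(genes, outdir / "genes.gtf")

    sim = simulate_peaks_and_counts(config, genome)
    truth = sim.truth
    from .diff_accessibility import call_differential_peaks, results_to_frame

    for ct in config.cell_types:
        rio.write_bed(sim.control_peaks[ct], outdir / f"peaks_control_{ct}.bed")
        rio.write_bed(sim.treated_peaks[ct], outdir / f"peaks_treated_{ct}.bed")
        cm = sim.count_matrices[ct]
        rio.write_counts_triplets(
            cm.cell_ids, cm.peak_ids, cm.counts, outdir / f"counts_{ct}.tsv"
        )
        pd.DataFrame({"cell_id": cm.cell_ids, "group": cm.groups}).to_csv(
            outdir / f"groups_{ct}.tsv", sep="\t", index=False
        )
        stats = call_differential_peaks(cm, "treated", "control")
        rio.write_tsv(results_to_frame(stats), outdir / f"peaks_stats_{ct}.tsv")

    de = make_de_genes(genome, truth, config)
    rio.write_tsv(de, outdir / "de_genes.tsv")

    cnes = make_cnes(truth, config)
    rio.write_bed(cnes, outdir / "cnes.bed")

    positives, controls = make_sequences(truth, config)
    rio.write_fasta({e.id: e.sequence for e in positives}, outdir / "positives.fa")
    rio.write_fasta({e.id: e.sequence for e in controls}, outdir / "controls.fa")

    truth.to_json(outdir / "truth.json")
    return truth
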