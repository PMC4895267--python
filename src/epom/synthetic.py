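"""Seeded synthetic datasets with known planted structure.

The generator emulates the pipeline's real inputs — chromatin-state
segmentations, per-mark signal tracks, a sample→group design, a TSS
table, gene sets and a SNP catalog — on a toy genome, with
group-specific high-signal windows planted so that every pipeline stage
(association testing, overlap scoring, target genes, enrichment) can be
checked against a recorded ground truth.

Background signal is truncated-normal noise on the -log10 p-value scale;
planted (group, window) pairs add a constant effect to that group's
samples in every mark. A sharing matrix plants extra windows common to
group pairs, giving the overlap test known structure to recover. All
randomness flows from a single integer seed through named SeedSequence
spawns, so identical configs produce identical datasets (and identical
bytes on disk).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ChromatinStateSegmentation,
    GeneAnnotation,
    GeneRecord,
    GeneSetCollection,
    GenomicWindow,
    GroupDesign,
    SignalTrack,
    SNPCatalog,
    SNPRecord,
)

logger = logging.getLogger(__name__)

#: States used to label synthetic windows (one enhancer, one promoter,
#: one neutral state outside both candidate classes).
ENHANCER_STATE = 13
PROMOTER_STATE = 1
NEUTRAL_STATE = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are desk-scale conditions under which the testing procedure
    should comfortably recover planted structure: 6 groups × 6 samples,
    10,000 windows, 5% planted per group, effect 10 signal units over
    noise sd 1 (a -log10 p-value shift far larger than the noise, as for
    a strong mark in its own tissue).
    """

    n_groups: int = 6
    samples_per_group: int = 6
    n_windows: int = 10_000
    planted_fraction_per_group: float = 0.05
    effect_size: float = 10.0
    noise_sd: float = 1.0
    baseline_mean: float = 1.0
    sharing_matrix: np.ndarray | None = None
    marks: tuple[str, ...] = ("H3K4me1", "H3K27ac")
    seed: int = 0
    window_size: int = 200
    signal_resolution: int = 200
    enhancer_fraction: float = 0.5
    state_noise_rate: float = 0.0
    noise_model: str = "normal"  # or "lognormal" (robustness mode)
    n_decoy_genes: int = 200
    n_decoy_terms: int = 5
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_groups < 2 or self.samples_per_group < 2:
            raise ValueError("need >= 2 groups and >= 2 samples per group")
        if not 0 <= self.planted_fraction_per_group < 1:
            raise ValueError("planted fraction must be in [0, 1)")
        if self.effect_size <= 0 or self.noise_sd <= 0:
            raise ValueError("effect_size and noise_sd must be positive")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be >= 0")
        if self.sharing_matrix is not None:
            sm = np.asarray(self.sharing_matrix, dtype=float)
            if sm.shape != (self.n_groups, self.n_groups):
                raise ValueError("sharing_matrix must be G x G")
            if not np.allclose(sm, sm.T) or np.any(np.diag(sm) != 0):
                raise ValueError("sharing_matrix must be symmetric with "
                                 "zero diagonal")
        if self.noise_model not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def groups(self) -> list[str]:
        return [f"group{i + 1}" for i in range(self.n_groups)]

    def samples_of(self, group_idx: int) -> list[str]:
        g = self.groups[group_idx]
        return [f"{g}_s{j + 1}" for j in range(self.samples_per_group)]


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, keyed by group label."""

    planted: dict[str, set[GenomicWindow]]
    shared: dict[tuple[str, str], set[GenomicWindow]]
    enriched_terms: dict[str, set[str]]
    snp_windows: dict[str, set[GenomicWindow]]
    gene_of_window: dict[GenomicWindow, str]


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    segmentations: list[ChromatinStateSegmentation]
    tracks: dict[str, dict[str, SignalTrack]]  # mark -> sample -> track
    design: GroupDesign
    annotation: GeneAnnotation
    gene_sets: GeneSetCollection
    snps: SNPCatalog
    truth: SyntheticTruth

    @property
    def windows(self) -> list[GenomicWindow]:
        return [w for w, _ in self.segmentations[0].records]


def _plant_windows(cfg: SimulationConfig, rng: np.random.Generator,
                   windows: list[GenomicWindow]
                   ) -> tuple[dict[str, set[GenomicWindow]],
                              dict[tuple[str, str], set[GenomicWindow]]]:
    """Choose disjoint planted window sets per group, honouring sharing.

    Each group receives round(fraction * R) planted windows; when the
    sharing matrix gives pair (i, j) fraction f, round(f * count) of each
    group's quota is drawn as windows common to both groups.
    """
    G = cfg.n_groups
    count = round(cfg.planted_fraction_per_group * cfg.n_windows)
    sm = (np.zeros((G, G)) if cfg.sharing_matrix is None
          else np.asarray(cfg.sharing_matrix, dtype=float))
    shared_counts = {(i, j): round(sm[i, j] * count)
                     for i in range(G) for j in range(i + 1, G)}
    for i in range(G):
        need = sum(c for (a, b), c in shared_counts.items() if i in (a, b))
        if need > count:
            raise ValueError(
                f"group {cfg.groups[i]}: shared quota {need} exceeds "
                f"planted count {count}"
            )
    total = G * count - sum(shared_counts.values())
    if total > len(windows):
        raise ValueError(f"planting needs {total} windows, have {len(windows)}")
    order = rng.permutation(len(windows))
    pool = iter(order)
    planted = {g: set() for g in cfg.groups}
    shared: dict[tuple[str, str], set[GenomicWindow]] = {}
    for (i, j), c in shared_counts.items():
        ws = {windows[next(pool)] for _ in range(c)}
        shared[(cfg.groups[i], cfg.groups[j])] = ws
        planted[cfg.groups[i]] |= ws
        planted[cfg.groups[j]] |= ws
    for i, g in enumerate(cfg.groups):
        own = count - len(planted[g])
        planted[g] |= {windows[next(pool)] for _ in range(own)}
    return planted, shared


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset with recorded planted truth."""
    root = np.random.SeedSequence(cfg.seed)
    seqs = root.spawn(6)
    rng_layout, rng_plant, rng_states, rng_genes, rng_sets, rng_snps = (
        np.random.default_rng(s) for s in seqs
    )
    W = cfg.window_size
    windows = [GenomicWindow(cfg.chrom, k * W, (k + 1) * W)
               for k in range(cfg.n_windows)]
    # enhancer/promoter split of the window grid
    is_enh = rng_layout.random(cfg.n_windows) < cfg.enhancer_fraction
    base_states = np.where(is_enh, ENHANCER_STATE, PROMOTER_STATE)

    planted, shared = _plant_windows(cfg, rng_plant, windows)

    design = GroupDesign({
        s: g for i, g in enumerate(cfg.groups) for s in cfg.samples_of(i)
    })

    segmentations = []
    shared_records = [(w, int(s)) for w, s in zip(windows, base_states)]
    for sample in design.samples:
        if cfg.state_noise_rate > 0:
            flip = rng_states.random(cfg.n_windows) < cfg.state_noise_rate
            states = np.where(flip, NEUTRAL_STATE, base_states)
            records = [(w, int(s)) for w, s in zip(windows, states)]
        else:
            records = shared_records  # identical candidate sets per sample
        segmentations.append(
            ChromatinStateSegmentation(sample_id=sample, records=records)
        )

    # signal tracks: one spawn per (mark, sample), in fixed order
    window_index = {w: k for k, w in enumerate(windows)}
    n_bins = cfg.n_windows * W // cfg.signal_resolution
    repeat = W // cfg.signal_resolution if cfg.signal_resolution < W else 1
    track_seqs = iter(root.spawn(len(cfg.marks) * len(design.samples)))
    tracks: dict[str, dict[str, SignalTrack]] = {}
    for mark in cfg.marks:
        tracks[mark] = {}
        for sample in design.samples:
            rng = np.random.default_rng(next(track_seqs))
            if cfg.noise_model == "normal":
                vals = rng.normal(cfg.baseline_mean, cfg.noise_sd,
                                  cfg.n_windows)
            else:
                vals = cfg.baseline_mean + rng.lognormal(
                    mean=0.0, sigma=cfg.noise_sd, size=cfg.n_windows) - 1.0
            group = design.group_of(sample)
            idx = [window_index[w] for w in planted[group]]
            vals[idx] += cfg.effect_size
            vals = np.maximum(vals, 0.0)  # -log10 p-values are non-negative
            if cfg.signal_resolution < W:
                vals = np.repeat(vals, repeat)
            assert len(vals) == n_bins
            tracks[mark][sample] = SignalTrack(
                sample_id=sample, mark=mark,
                resolution=cfg.signal_resolution,
                values={cfg.chrom: vals},
            )

    # one gene per planted window (TSS just downstream, '+' strand, so the
    # promoter directionality rule accepts it), plus decoys far away
    all_planted = sorted({w for s in planted.values() for w in s},
                         key=lambda w: (w.chrom, w.start))
    gene_of_window: dict[GenomicWindow, str] = {}
    records: list[GeneRecord] = []
    for w in all_planted:
        gid = f"G{w.start // W:06d}"
        gene_of_window[w] = gid
        # offset below half the window size: the window's own gene is
        # strictly nearer to its midpoint than any neighbour window's gene
        offset = int(rng_genes.integers(50, 100))
        records.append(GeneRecord(gid, w.chrom, w.end + offset, "+"))
    decoy_base = cfg.n_windows * W + 1_000_000
    decoy_ids = []
    for d in range(cfg.n_decoy_genes):
        gid = f"D{d:05d}"
        decoy_ids.append(gid)
        records.append(GeneRecord(gid, cfg.chrom,
                                  decoy_base + 10_000 * d, "+"))
    annotation = GeneAnnotation(records)

    # gene sets: one planted term per group plus random decoy terms
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    enriched_terms: dict[str, set[str]] = {}
    for g in cfg.groups:
        term = f"TERM_{g}"
        genes = frozenset(gene_of_window[w] for w in planted[g])
        if genes:
            sets[term] = (f"planted term for {g}", genes)
            enriched_terms[g] = {term}
        else:
            enriched_terms[g] = set()
    for t in range(cfg.n_decoy_terms):
        if not decoy_ids:
            break
        size = min(len(decoy_ids), 20)
        members = rng_sets.choice(decoy_ids, size=size, replace=False)
        sets[f"DECOY_{t:02d}"] = ("decoy term", frozenset(members))
    gene_sets = GeneSetCollection(sets)

    # SNPs: one per planted window, trait labelled by group
    snp_records: list[SNPRecord] = []
    snp_windows: dict[str, set[GenomicWindow]] = {}
    for g in cfg.groups:
        snp_windows[g] = set(planted[g])
        for w in sorted(planted[g], key=lambda w: (w.chrom, w.start)):
            pos = w.start + int(rng_snps.integers(0, W))
            snp_records.append(
                SNPRecord(w.chrom, pos, f"rs{g}_{w.start}", f"TRAIT_{g}")
            )
    snps = SNPCatalog(snp_records)

    truth = SyntheticTruth(
        planted=planted, shared=shared, enriched_terms=enriched_terms,
        snp_windows=snp_windows, gene_of_window=gene_of_window,
    )
    return SyntheticDataset(
        config=cfg, segmentations=segmentations, tracks=tracks,
        design=design, annotation=annotation, gene_sets=gene_sets,
        snps=snps, truth=truth,
    )


def simulate_null(cfg: SimulationConfig) -> SyntheticDataset:
    """Same generator with nothing planted (global null)."""
    cfg = dataclasses.replace(cfg, planted_fraction_per_group=0.0,
                              sharing_matrix=None)
    return simulate_dataset(cfg)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Emit the dataset in exactly the formats the readers consume.

    Layout: segmentations/<sample>.bed (BED4), signals/<mark>/<sample>.bedGraph,
    design.tsv, genes.tsv, gene_sets.gmt, snps.tsv, manifest.json.
    Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    (outdir / "segmentations").mkdir(parents=True, exist_ok=True)
    for seg in ds.segmentations:
        with (outdir / "segmentations" / f"{seg.sample_id}.bed").open("w") as fh:
            for w, s in seg.records:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{s}\n")
    for mark, per_sample in ds.tracks.items():
        mdir = outdir / "signals" / mark
        mdir.mkdir(parents=True, exist_ok=True)
        for sample, track in per_sample.items():
            with (mdir / f"{sample}.bedGraph").open("w") as fh:
                res = track.resolution
                for chrom, vals in track.values.items():
                    for k, v in enumerate(vals):
                        fh.write(f"{chrom}\t{k * res}\t{(k + 1) * res}"
                                 f"\t{v:.6g}\n")
    with (outdir / "design.tsv").open("w") as fh:
        fh.write("sample\tgroup\n")
        for s in ds.design.samples:
            fh.write(f"{s}\t{ds.design.group_of(s)}\n")
    with (outdir / "genes.tsv").open("w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for r in ds.annotation.records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.tss}\t{r.strand}\n")
    with (outdir / "gene_sets.gmt").open("w") as fh:
        for term in ds.gene_sets.terms:
            desc, genes = ds.gene_sets.sets[term]
            fh.write("\t".join([term, desc] + sorted(genes)) + "\n")
    with (outdir / "snps.tsv").open("w") as fh:
        fh.write("chrom\tposition\tsnp_id\ttrait\n")
        for r in ds.snps.records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.snp_id}\t{r.trait}\n")
    manifest = {
        "config": {
            k: (v.tolist() if isinstance(v, np.ndarray) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(ds.config).items()
        },
        "truth": {
            "planted": {g: sorted([w.chrom, w.start, w.end] for w in s)
                        for g, s in ds.truth.planted.items()},
            "shared": {f"{a}|{b}": sorted([w.chrom, w.start, w.end]
                                          for w in s)
                       for (a, b), s in ds.truth.shared.items()},
            "enriched_terms": {g: sorted(t)
                               for g, t in ds.truth.enriched_terms.items()},
        },
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
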