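"""Readers and writers for the text formats the pipeline touches.

All coordinates are 0-based, half-open (BED convention), everywhere.
Inputs in other dialects must be converted at this boundary.

Formats handled: BED4 chromatin-state segmentations, bedGraph / fixedStep
wiggle signal tracks (values are -log10 enrichment p-values), sample→group
design tables (TSV), TSS tables (TSV or BED6), GMT gene-set collections,
and SNP catalogs (TSV with trait labels).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

#: Default width of a candidate window in bp.
WINDOW_SIZE = 200


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


class GenomicWindow(NamedTuple):
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ChromatinStateSegmentation:
    """Per-sample chromatin-state assignment on the unit window grid.

    ``records`` maps each window to a state number in 1..25. Windows within
    a chromosome are non-overlapping and sorted.
    """

    sample_id: str
    records: list[tuple[GenomicWindow, int]]

    def states_by_window(self) -> dict[GenomicWindow, int]:
        return {w: s for w, s in self.records}


@dataclass
class SignalTrack:
    """Dense per-chromosome signal at a fixed resolution.

    Values are -log10 p-values of mark enrichment: non-negative, finite.
    """

    sample_id: str
    mark: str
    resolution: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def value_at(self, window: GenomicWindow) -> float:
        """Signal value over ``window``; 0 beyond the track end (gap rule)."""
        arr = self.values.get(window.chrom)
        if arr is None:
            return 0.0
        idx = window.start // self.resolution
        if idx >= len(arr):
            return 0.0
        return float(arr[idx])


@dataclass
class GroupDesign:
    """sample_id → group label; groups with fewer than 2 samples dropped."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for g in self.assignments.values():
            counts[g] = counts.get(g, 0) + 1
        singletons = {g for g, c in counts.items() if c < 2}
        if singletons:
            dropped = [s for s, g in self.assignments.items() if g in singletons]
            logger.warning(
                "dropping %d singleton group(s) %s (%d sample(s))",
                len(singletons), sorted(singletons), len(dropped),
            )
            self.assignments = {
                s: g for s, g in self.assignments.items() if g not in singletons
            }

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    @property
    def samples(self) -> list[str]:
        return sorted(self.assignments)

    def group_of(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def samples_in(self, group: str) -> list[str]:
        return sorted(s for s, g in self.assignments.items() if g == group)


class GeneRecord(NamedTuple):
    gene_id: str
    chrom: str
    tss: int
    strand: str


@dataclass
class GeneAnnotation:
    """TSS-level gene records used for target-gene assignment."""

    records: list[GeneRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.gene_id in seen:
                raise FormatError(f"duplicate gene id {r.gene_id!r}")
            seen.add(r.gene_id)
            if r.strand not in ("+", "-"):
                raise FormatError(f"unknown strand {r.strand!r} for {r.gene_id}")
            if r.tss < 0:
                raise FormatError(f"negative TSS for {r.gene_id}")


@dataclass
class GeneSetCollection:
    """term_id → (term name, set of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"empty gene set for term {term!r}")

    def genes_of(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    @property
    def terms(self) -> list[str]:
        return sorted(self.sets)


class SNPRecord(NamedTuple):
    chrom: str
    position: int  # 0-based bp
    snp_id: str
    trait: str


@dataclass
class SNPCatalog:
    """Trait/disease-associated SNPs; one record per (SNP, trait label)."""

    records: list[SNPRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.position < 0:
                raise FormatError(f"negative position for SNP {r.snp_id}")

    @property
    def traits(self) -> list[str]:
        return sorted({r.trait for r in self.records})


_STATE_RE = re.compile(r"^E?(\d+)")


def parse_state_token(token: str) -> int:
    """Parse a chromatin-state token: '13', 'E13' or '13_EnhA1' → 13."""
    m = _STATE_RE.match(token)
    if not m:
        raise FormatError(f"cannot parse state token {token!r}")
    state = int(m.group(1))
    if not 1 <= state <= 25:
        raise FormatError(f"state {state} outside 1..25")
    return state


def read_segmentation(
    path: str | Path,
    sample_id: str | None = None,
    window_size: int = WINDOW_SIZE,
) -> ChromatinStateSegmentation:
    """Read a BED4-like segmentation, splitting multi-window records.

    A record spanning k unit windows (end-start = k*window_size) becomes k
    unit-window records with the same state. Records must be aligned to the
    window grid and non-overlapping within each chromosome.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    records: list[tuple[GenomicWindow, int]] = []
    for lineno, line in enumerate(_data_lines(path), 1):
        fields = line.split()
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        chrom, start_s, end_s, token = fields[:4]
        start, end = int(start_s), int(end_s)
        if start < 0 or end <= start:
            raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
        if start % window_size or (end - start) % window_size:
            raise FormatError(
                f"{path}:{lineno}: interval {start}-{end} off the "
                f"{window_size} bp grid"
            )
        state = parse_state_token(token)
        for s in range(start, end, window_size):
            records.append((GenomicWindow(chrom, s, s + window_size), state))
    records.sort(key=lambda r: (r[0].chrom, r[0].start))
    prev: GenomicWindow | None = None
    for w, _ in records:
        if prev is not None and w.chrom == prev.chrom and w.start < prev.end:
            raise FormatError(f"{path}: overlapping records at {w.chrom}:{w.start}")
        prev = w
    return ChromatinStateSegmentation(sample_id=sample_id, records=records)


def read_signal(
    path: str | Path,
    resolution: int = 25,
    sample_id: str | None = None,
    mark: str = "",
) -> SignalTrack:
    """Read a bedGraph or fixedStep wiggle track into dense arrays.

    Gaps between intervals are filled with 0 (imputed tracks are dense;
    gaps indicate trimming, not biology) and the fill count is logged.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    text = path.read_text().splitlines()
    if any(ln.startswith("fixedStep") for ln in text[:5]):
        values = _read_fixedstep(text, resolution, path)
    else:
        values = _read_bedgraph(text, resolution, path)
    return SignalTrack(
        sample_id=sample_id,
        mark=mark,
        resolution=resolution,
        values={c: np.asarray(v, dtype=float) for c, v in values.items()},
    )


def _read_bedgraph(
    lines: list[str], resolution: int, path: Path
) -> dict[str, list[float]]:
    values: dict[str, list[float]] = {}
    gaps = 0
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if not np.isfinite(value) or value < 0:
            raise FormatError(f"{path}:{lineno}: invalid signal value {fields[3]}")
        if start % resolution or (end - start) % resolution:
            raise FormatError(
                f"{path}:{lineno}: interval {start}-{end} not a multiple "
                f"of resolution {resolution}"
            )
        seq = values.setdefault(chrom, [])
        expected = len(seq) * resolution
        if start < expected:
            raise FormatError(f"{path}:{lineno}: overlapping/unsorted interval")
        if start > expected:
            nfill = (start - expected) // resolution
            seq.extend([0.0] * nfill)
            gaps += nfill
        seq.extend([value] * ((end - start) // resolution))
    if gaps:
        logger.info("%s: filled %d gap bin(s) with 0", path, gaps)
    return values


def _read_fixedstep(
    lines: list[str], resolution: int, path: Path
) -> dict[str, list[float]]:
    values: dict[str, list[float]] = {}
    chrom: str | None = None
    pos = 0
    gaps = 0
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        if line.startswith("fixedStep"):
            decl = dict(kv.split("=") for kv in line.split()[1:])
            chrom = decl["chrom"]
            # wiggle declarations are 1-based
            start0 = int(decl["start"]) - 1
            step = int(decl.get("step", resolution))
            if step != resolution:
                raise FormatError(f"{path}:{lineno}: step {step} != resolution {resolution}")
            if start0 % resolution:
                raise FormatError(f"{path}:{lineno}: start off the {resolution} bp grid")
            seq = values.setdefault(chrom, [])
            expected = len(seq) * resolution
            if start0 < expected:
                raise FormatError(f"{path}:{lineno}: overlapping fixedStep block")
            nfill = (start0 - expected) // resolution
            seq.extend([0.0] * nfill)
            gaps += nfill
            pos = start0
            continue
        if chrom is None:
            raise FormatError(f"{path}:{lineno}: data before fixedStep declaration")
        value = float(line)
        if not np.isfinite(value) or value < 0:
            raise FormatError(f"{path}:{lineno}: invalid signal value {line}")
        values[chrom].append(value)
        pos += resolution
    if gaps:
        logger.info("%s: filled %d gap bin(s) with 0", path, gaps)
    return values


def read_design(path: str | Path) -> GroupDesign:
    """Read a two-column (sample_id, group) TSV; header optional."""
    path = Path(path)
    assignments: dict[str, str] = {}
    for lineno, line in enumerate(_data_lines(path), 1):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        sample, group = fields[0], fields[1]
        if lineno == 1 and sample.lower() in ("sample", "sample_id"):
            continue
        if sample in assignments:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        assignments[sample] = group
    return GroupDesign(assignments)


def read_tss(path: str | Path) -> GeneAnnotation:
    """Read a TSS table: TSV (gene_id, chrom, tss, strand) or BED6.

    BED6 is detected by its column order (chrom first, numeric cols 2-3);
    for BED6 the TSS is the strand-aware 5' end of the interval.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    for lineno, line in enumerate(_data_lines(path), 1):
        fields = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and fields[0].lower() in ("gene", "gene_id"):
            continue
        if len(fields) >= 6 and _is_int(fields[1]) and _is_int(fields[2]):
            # BED6: chrom start end name score strand
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            gene_id, strand = fields[3], fields[5]
            tss = start if strand == "+" else end - 1
        elif len(fields) >= 4:
            gene_id, chrom, tss, strand = fields[0], fields[1], int(fields[2]), fields[3]
        else:
            raise FormatError(f"{path}:{lineno}: unrecognised TSS record")
        records.append(GeneRecord(gene_id, chrom, tss, strand))
    return GeneAnnotation(records)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(_data_lines(path), 1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs term, desc, >=1 gene")
        term, desc = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: empty gene set for {term!r}")
        sets[term] = (desc, genes)
    return GeneSetCollection(sets)


def read_snps(path: str | Path) -> SNPCatalog:
    """Read a SNP catalog TSV: chrom, position (0-based), snp_id, trait."""
    path = Path(path)
    records: list[SNPRecord] = []
    for lineno, line in enumerate(_data_lines(path), 1):
        fields = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and fields[0].lower() in ("chrom", "chr"):
            continue
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        records.append(SNPRecord(fields[0], int(fields[1]), fields[2], fields[3]))
    return SNPCatalog(records)


def write_regions(
    windows: Iterable[tuple[GenomicWindow, str]] | Iterable[GenomicWindow],
    path: str | Path,
) -> None:
    """Write windows as BED3, or BED3 + group column when given pairs."""
    path = Path(path)
    with path.open("w") as fh:
        for item in windows:
            if isinstance(item, GenomicWindow):
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")
            else:
                w, group = item
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{group}\n")


def read_regions(path: str | Path) -> list[tuple[GenomicWindow, str | None]]:
    """Read BED3(+group) regions written by :func:`write_regions`."""
    path = Path(path)
    out: list[tuple[GenomicWindow, str | None]] = []
    for lineno, line in enumerate(_data_lines(path), 1):
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 columns")
        w = GenomicWindow(fields[0], int(fields[1]), int(fields[2]))
        if w.start >= w.end or w.start < 0:
            raise FormatError(f"{path}:{lineno}: bad interval")
        out.append((w, fields[3] if len(fields) > 3 else None))
    return out


def _data_lines(path: Path) -> Iterable[str]:
    for line in path.read_text().splitlines():
        line = line.rstrip("\n")
        if line and not line.startswith("#"):
            yield line


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False
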