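"""Readers and writers for the standard files the pipeline touches.

All interval I/O is 0-based half-open internally.  GTF-style gene input is
converted on ingestion (tss = start for "+", end-1 for "-").  BED output is
deterministically sorted with a fixed 4-decimal float format so identical
inputs produce bit-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .region_builder import (
    MIXED,
    PURE_FORWARD,
    PURE_REVERSE,
    RepeatRegion,
)

logger = logging.getLogger(__name__)

_VALID_ALPHABET = set("ACGTN")


@dataclass
class GenomeSequence:
    """Per-chromosome uppercase nucleotide strings plus a soft-mask track.

    ``soft_mask`` records the intervals that were lowercase in the source
    FASTA (repeat-masked); scanning uses the uppercased sequence and only
    consults the mask when masked regions are explicitly excluded.
    """

    chrom_names: List[str]
    sequences: Dict[str, str]
    soft_mask: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}

    def total_length(self) -> int:
        return sum(self.lengths.values())


def _lowercase_runs(seq: str) -> List[Tuple[int, int]]:
    runs: List[Tuple[int, int]] = []
    start = None
    for i, ch in enumerate(seq):
        if ch.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def read_fasta(path) -> GenomeSequence:
    """Read a (possibly wrapped, multi-record) FASTA file.

    Sequences are uppercased; lowercase runs are preserved in the soft-mask
    track.  Duplicate chromosome names or characters outside A/C/G/T/N are
    fatal parse errors.
    """
    path = Path(path)
    names: List[str] = []
    seqs: Dict[str, str] = {}
    mask: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise ValueError(f"{path}: empty FASTA header")
            if name in seqs:
                raise ValueError(f"{path}: duplicate chromosome name {name!r}")
            upper = seq.upper()
            bad = set(upper) - _VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"{path}: record {name!r} contains invalid characters {sorted(bad)}"
                )
            names.append(name)
            seqs[name] = upper
            runs = _lowercase_runs(seq)
            if runs:
                mask[name] = runs
    return GenomeSequence(chrom_names=names, sequences=seqs, soft_mask=mask)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as out:
        for name in genome.chrom_names:
            out.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Peak:
    """A binding interval with its summit position and fold-enrichment."""

    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    qvalue: Optional[float] = None
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.name}: start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"peak {self.name}: summit outside interval")


def read_peaks(path, dialect: str = "narrowpeak") -> List[Peak]:
    """Read peaks from ENCODE narrowPeak (BED6+4) or plain BED6.

    narrowPeak: summit = start + column-10 offset, fold-enrichment from
    column 7; an offset of -1 falls back to the interval midpoint with a
    warning.  BED6: summit = floor midpoint, fold-enrichment = score / 100
    (documented rescaling; narrowPeak is preferred).  Records with
    end <= start are rejected, counted and reported.
    """
    if dialect not in ("narrowpeak", "bed6"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    path = Path(path)
    peaks: List[Peak] = []
    n_rejected = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "narrowpeak" and len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            if dialect == "bed6" and len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                n_rejected += 1
                continue
            name = fields[3] if fields[3] != "" else "."
            if dialect == "narrowpeak":
                fe = float(fields[6])
                qvalue: Optional[float] = float(fields[8])
                offset = int(fields[9])
                if offset < 0:
                    logger.warning(
                        "%s:%d: summit offset -1; using interval midpoint", path, lineno
                    )
                    summit = (start + end) // 2
                else:
                    summit = start + offset
            else:
                fe = float(fields[4]) / 100.0
                qvalue = None
                summit = (start + end) // 2
            peaks.append(
                Peak(chrom=chrom, start=start, end=end, summit=summit,
                     fold_enrichment=fe, qvalue=qvalue, name=name)
            )
    if n_rejected:
        logger.warning("%s: rejected %d records with end <= start", path, n_rejected)
    return peaks


def write_peaks_narrowpeak(peaks: Sequence[Peak], path) -> None:
    path = Path(path)
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
    with open(path, "w") as out:
        for p in ordered:
            q = -1.0 if p.qvalue is None else p.qvalue
            out.write(
                "\t".join(
                    [
                        p.chrom, str(p.start), str(p.end), p.name, "0", ".",
                        f"{p.fold_enrichment:.4f}", "-1", f"{q:.4f}",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class GeneRecord:
    """TSS-bearing gene annotation (0-based TSS coordinate)."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    tss: int


@dataclass(frozen=True)
class DERecord:
    """Differential-expression call for one gene.

    ``log2fc`` is oriented fusion-present minus fusion-absent, so positive
    values mean the gene is activated by the fusion protein.
    """

    gene_id: str
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.gene_id}: fdr must be in [0, 1]")


def _is_pseudo(value: str) -> bool:
    v = value.strip().lower()
    return v in ("1", "true", "yes") or "pseudogene" in v


def read_gene_table(path, filter_pseudo: bool = True) -> List[GeneRecord]:
    """Read a gene TSV with header.

    Requires gene_id, chrom, strand and either a ``tss`` column or
    ``start``/``end`` columns (GTF-subset ingestion: tss = start for "+",
    end-1 for "-").  Pseudo-genes (an ``is_pseudo`` truthy column or a
    ``gene_biotype`` containing "pseudogene") are excluded at load time
    unless ``filter_pseudo`` is False.  Records with unknown strand symbols
    are rejected and reported.
    """
    path = Path(path)
    genes: List[GeneRecord] = []
    n_rejected = 0
    seen = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for required in ("gene_id", "chrom", "strand"):
            if required not in idx:
                raise ValueError(f"{path}: missing required column {required!r}")
        if "tss" not in idx and not ("start" in idx and "end" in idx):
            raise ValueError(f"{path}: needs a tss column or start/end columns")
        for lineno, line in enumerate(handle, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            strand = fields[idx["strand"]]
            if strand not in ("+", "-"):
                logger.warning("%s:%d: unknown strand %r; record rejected",
                               path, lineno, strand)
                n_rejected += 1
                continue
            pseudo = False
            if "is_pseudo" in idx:
                pseudo = _is_pseudo(fields[idx["is_pseudo"]])
            if "gene_biotype" in idx:
                pseudo = pseudo or "pseudogene" in fields[idx["gene_biotype"]].lower()
            if pseudo and filter_pseudo:
                continue
            if "tss" in idx:
                tss = int(fields[idx["tss"]])
            else:
                start, end = int(fields[idx["start"]]), int(fields[idx["end"]])
                tss = start if strand == "+" else end - 1
            gene_id = fields[idx["gene_id"]]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            name = fields[idx["name"]] if "name" in idx else gene_id
            genes.append(GeneRecord(gene_id=gene_id, name=name,
                                    chrom=fields[idx["chrom"]], strand=strand, tss=tss))
    if n_rejected:
        logger.warning("%s: rejected %d gene records", path, n_rejected)
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path,
                     pseudo_ids: Optional[set] = None) -> None:
    path = Path(path)
    pseudo_ids = pseudo_ids or set()
    with open(path, "w") as out:
        out.write("gene_id\tname\tchrom\tstrand\ttss\tis_pseudo\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            flag = "1" if g.gene_id in pseudo_ids else "0"
            out.write(f"{g.gene_id}\t{g.name}\t{g.chrom}\t{g.strand}\t{g.tss}\t{flag}\n")


def read_de_table(path, flip_lfc: bool = False) -> List[DERecord]:
    """Read a differential-expression TSV (gene_id, log2fc, fdr).

    Rows with a missing fdr are rejected and reported.  ``flip_lfc`` negates
    the fold-changes for tables oriented knockdown-minus-control.
    """
    path = Path(path)
    records: List[DERecord] = []
    n_rejected = 0
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for required in ("gene_id", "log2fc", "fdr"):
            if required not in idx:
                raise ValueError(f"{path}: missing required column {required!r}")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            raw_fdr = fields[idx["fdr"]].strip()
            if raw_fdr in ("", "NA", "nan", "NaN"):
                n_rejected += 1
                continue
            lfc = float(fields[idx["log2fc"]])
            if flip_lfc:
                lfc = -lfc
            records.append(
                DERecord(gene_id=fields[idx["gene_id"]], log2fc=lfc, fdr=float(raw_fdr))
            )
    if n_rejected:
        logger.warning("%s: rejected %d DE rows with missing fdr", path, n_rejected)
    return records


def write_de_table(records: Sequence[DERecord], path) -> None:
    path = Path(path)
    with open(path, "w") as out:
        out.write("gene_id\tlog2fc\tfdr\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            out.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.fdr:.6g}\n")


_STRAND_TO_CLASS = {"+": PURE_FORWARD, "-": PURE_REVERSE, ".": MIXED}


def write_regions_bed(regions: Sequence[RepeatRegion], path) -> None:
    """Write regions as BED6+4: chrom, start, end, name, score=max_consecutive,
    strand, total_motifs, max_consecutive, density (4 decimals), class.

    Output ordering is deterministic: (chrom, start, end, strand).
    """
    path = Path(path)
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.strand))
    with open(path, "w") as out:
        for i, r in enumerate(ordered):
            out.write(
                "\t".join(
                    [
                        r.chrom, str(r.start), str(r.end), f"rr{i:07d}",
                        str(r.max_consecutive), r.strand, str(r.total_motifs),
                        str(r.max_consecutive), f"{r.density:.4f}", r.strand_class,
                    ]
                )
                + "\n"
            )


def read_regions_bed(path) -> List[RepeatRegion]:
    """Re-read a BED6+4 region file; occurrence-level data is not recoverable,
    only the summary statistics."""
    path = Path(path)
    regions: List[RepeatRegion] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: expected 10 BED6+4 columns")
            regions.append(
                RepeatRegion(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    occurrences=None,
                    strand_class=fields[9],
                    total_motifs=int(fields[6]),
                    max_consecutive=int(fields[7]),
                    density=float(fields[8]),
                )
            )
    return regions
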