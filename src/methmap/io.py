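"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; BED6, GFF3, bedGraph, PSL and
the truth TSV are simple line formats written directly, with line-numbered
validation on read. Everything internal is 0-based half-open; GFF3 converts
to 1-based inclusive at this boundary only. Round-trips are lossless for
every format this package writes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from . import __version__
from .library_sim import SimRead
from .site_caller import AlignmentRecord, PutativeSite
from .synthetic_genome import (Annotations, FeatureInterval, GeneModel,
                               MethylomeTrack, read_truth_set, write_truth_set)

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "read_reads",
    "BedRecord", "read_bed", "write_bed", "write_sites_bed",
    "read_gff3", "write_gff3", "read_psl", "write_bedgraph",
    "read_truth_set", "write_truth_set", "write_provenance",
]

HEADER_PREFIX = f"#methmap v{__version__}"


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fastq(path) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_reads(path, stage: str = "") -> List[SimRead]:
    """Load FASTA or FASTQ reads (format sniffed from the first byte)."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [SimRead(rec.id, str(rec.seq).upper(), rec.id, stage, "+", 0)
            for rec in SeqIO.parse(str(path), fmt)]


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0
    strand: str = "."


def read_bed(path, chrom_lengths: Optional[Mapping[str, int]] = None) -> List[BedRecord]:
    records: List[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if chrom_lengths is not None:
                if chrom not in chrom_lengths or end > chrom_lengths[chrom]:
                    raise ValueError(f"{path}:{lineno}: interval outside {chrom} bounds")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            records.append(BedRecord(chrom, start, end, name, score, strand))
    return records


def write_bed(records: Sequence[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def write_sites_bed(sites: Sequence[PutativeSite], path,
                    member_counts: Optional[Mapping[str, int]] = None) -> None:
    """Sites as BED6: name = method:mark:stage, score = source-contig
    member count when available."""
    records = []
    for s in sorted(sites, key=lambda s: (s.chrom, s.position)):
        score = member_counts.get(s.contig_id, 0) if member_counts else 0
        records.append(BedRecord(s.chrom, s.position, s.position + 1,
                                 f"{s.method}:{s.mark}:{s.stage}", score, s.strand))
    write_bed(records, path)


def write_bedgraph(bins: Mapping[str, Sequence[int]], bin_bp: int, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{HEADER_PREFIX} bedGraph bin={bin_bp}\n")
        for chrom in sorted(bins):
            for i, count in enumerate(bins[chrom]):
                fh.write(f"{chrom}\t{i * bin_bp}\t{(i + 1) * bin_bp}\t{count}\n")


def write_repeat_bed(repeats: Sequence[FeatureInterval], path) -> None:
    write_bed([BedRecord(r.chrom, r.start, r.end, r.name, 0, "+") for r in repeats],
              path)


def read_feature_bed(path, chrom_lengths: Optional[Mapping[str, int]] = None
                     ) -> List[FeatureInterval]:
    return [FeatureInterval(r.chrom, r.start, r.end, r.name)
            for r in read_bed(path, chrom_lengths)]


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene/exon features; internal 0-based half-open coordinates are
    converted to GFF3 1-based inclusive here and only here."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tmethmap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tmethmap\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")


def read_gff3(path) -> List[GeneModel]:
    genes: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: empty feature interval")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields.get("ID")
                if not gid:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {"chrom": chrom, "start": start0, "end": end0,
                              "strand": strand, "exons": []}
                order.append(gid)
            elif ftype == "exon":
                parent = fields.get("Parent")
                if parent in genes:
                    genes[parent]["exons"].append((start0, end0))
    return [GeneModel(gid, g["chrom"], g["start"], g["end"], g["strand"],
                      tuple(sorted(g["exons"])))
            for gid, g in ((gid, genes[gid]) for gid in order)]


# ---------------------------------------------------------------------------
# PSL import (the tabular alignment format produced by BLAT)
# ---------------------------------------------------------------------------

def read_psl(path) -> List[AlignmentRecord]:
    """Parse PSL alignments into placement records.

    Identity is matches/(matches+mismatches+repMatches); coverage is the
    aligned query span over the query length. Block sizes inconsistent with
    the stated spans are a parse error naming the line. ``n_best_loci`` is
    left at 1 per record; the unique-placement filter recounts per contig.
    """
    records: List[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] not in "0123456789":
                continue  # header lines of psLayout
            parts = line.split("\t")
            if len(parts) < 21:
                raise ValueError(f"{path}:{lineno}: PSL needs 21 columns")
            (matches, mismatches, rep_matches, _n_count, _qgap_c, _qgap_b,
             _tgap_c, _tgap_b, strand, qname, qsize, qstart, qend,
             tname, _tsize, tstart, tend, block_count, block_sizes,
             _qstarts, _tstarts) = parts[:21]
            matches, mismatches, rep = int(matches), int(mismatches), int(rep_matches)
            qsize, qstart, qend = int(qsize), int(qstart), int(qend)
            tstart, tend = int(tstart), int(tend)
            sizes = [int(x) for x in block_sizes.rstrip(",").split(",") if x]
            if len(sizes) != int(block_count):
                raise ValueError(f"{path}:{lineno}: blockCount does not match blockSizes")
            if sum(sizes) > tend - tstart or sum(sizes) > qend - qstart:
                raise ValueError(f"{path}:{lineno}: block sizes inconsistent with span")
            aligned = matches + mismatches + rep
            identity = matches / aligned if aligned else 0.0
            coverage = (qend - qstart) / qsize if qsize else 0.0
            records.append(AlignmentRecord(qname, tname, tstart, tend,
                                           strand[0], identity, coverage))
    return records


# ---------------------------------------------------------------------------
# Provenance TSV
# ---------------------------------------------------------------------------

def write_provenance(reads: Sequence[SimRead],
                     fragments: Mapping[str, tuple], path) -> None:
    """Read provenance: read id, source fragment coordinates, protocol and
    true bounding-site marks (the recovery-scoring ground truth)."""
    with open(path, "w") as fh:
        fh.write(f"{HEADER_PREFIX}\n#read_id\tchrom\tstart\tend\tprotocol\t"
                 "true_left_mark\ttrue_right_mark\n")
        for read in reads:
            chrom, start, end, protocol, lm, rm = fragments[read.source_fragment_id]
            fh.write(f"{read.read_id}\t{chrom}\t{start}\t{end}\t{protocol}\t{lm}\t{rm}\n")
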