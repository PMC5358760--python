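"""Readers and writers for the interchange formats used across the pipeline.

Internal coordinates are 0-based half-open; GFF3 records are converted to
1-based closed on write and back on read. The tag table is a TSV dialect::

    tag_id  multiplicity  n_matches  contig:start-end:strand;contig:...

bedGraph tracks carry a ``# read_length=<float>`` header comment so that
per-base signal mass can be converted back to tag counts after a round trip.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, Interval
from .tagweight import CoverageTrack, Match, TagAlignment


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_alignment(path: str | Path, fmt: str = "fasta") -> dict[str, str]:
    """Read a multiple alignment (aligned FASTA or Clustal) as name -> row."""
    aln = AlignIO.read(str(path), fmt)
    return {rec.id: str(rec.seq).upper() for rec in aln}


# ---------------------------------------------------------------- BED / GFF3

def write_bed6(intervals: list[Interval], path: str | Path, scores=None) -> None:
    scores = scores if scores is not None else [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, sc in zip(intervals, scores):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{sc}\t{iv.strand}\n")


def read_bed6(path: str | Path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            name = f[3] if len(f) > 3 and f[3] != "." else ""
            out.append(Interval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "pol3roadblock") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            start, end = int(f[3]) - 1, int(f[4])
            if f[2] == "gene":
                gid = attrs["ID"]
                genes[gid] = GeneModel(gid, f[0], start, end, f[6])
            elif f[2] == "exon" and "Parent" in attrs:
                exons.setdefault(attrs["Parent"], []).append((start, end))
    for gid, ex in exons.items():
        if gid in genes:
            genes[gid].exons = sorted(ex)
    return list(genes.values())


# ---------------------------------------------------------------- tag TSV

def write_tags(tags: list[TagAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#tag_id\tmultiplicity\tn_matches\tmatches\n")
        for t in tags:
            ms = ";".join(f"{m.contig}:{m.start}-{m.end}:{m.strand}" for m in t.matches)
            fh.write(f"{t.tag_id}\t{t.c}\t{t.m}\t{ms}\n")


def read_tags(path: str | Path) -> list[TagAlignment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            tag_id, c, n, ms = line.rstrip("\n").split("\t")
            matches = []
            for tok in ms.split(";"):
                loc, strand = tok.rsplit(":", 1)
                contig, span = loc.rsplit(":", 1)
                s, e = span.split("-")
                matches.append(Match(contig, int(s), int(e), strand))
            if len(matches) != int(n):
                raise ValueError(f"tag {tag_id}: n_matches={n} but {len(matches)} matches listed")
            out.append(TagAlignment(tag_id, int(c), matches))
    return out


def write_fastq(tags: list[TagAlignment], path: str | Path) -> None:
    """Unaligned reads: each tag repeated ``c`` times at uniform quality."""
    with open(path, "w") as fh:
        for t in tags:
            if not t.seq:
                raise ValueError(f"tag {t.tag_id} has no stored sequence")
            for i in range(t.c):
                fh.write(f"@{t.tag_id}/{i + 1}\n{t.seq}\n+\n{'I' * len(t.seq)}\n")


def read_tags_sam(path: str | Path) -> list[TagAlignment]:
    """Collapse a SAM/BAM file into multiplicity-annotated tags.

    Multiplicity ``c`` is the number of distinct read names sharing an
    identical (forward-strand) sequence; the match list is the set of
    distinct alignment locations of that sequence. The NH tag, when present,
    is only a cross-check — the collapsed records are authoritative.
    """
    import pysam

    by_seq: dict[str, dict] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            seq = rec.get_forward_sequence() or rec.query_sequence
            seq = seq.upper()
            entry = by_seq.setdefault(seq, {"names": set(), "matches": {}})
            entry["names"].add(rec.query_name)
            strand = "-" if rec.is_reverse else "+"
            entry["matches"][(rec.reference_name, rec.reference_start,
                              rec.reference_end, strand)] = None
    tags = []
    for i, (seq, entry) in enumerate(sorted(by_seq.items())):
        matches = [Match(*k) for k in sorted(entry["matches"])]
        tags.append(TagAlignment(f"tag{i:06d}", len(entry["names"]), matches, seq=seq))
    return tags


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(track: CoverageTrack, path: str | Path, name: str = "coverage") -> None:
    with open(path, "w") as fh:
        fh.write(f"# read_length={track.read_length:.6f}\n")
        fh.write(f"# total_weight={track.total_weight:.6f}\n")
        fh.write(f'track type=bedGraph name="{name}"\n')
        for contig in sorted(track.bins):
            arr = track.bins[contig]
            bs = track.bin_size
            for b, v in enumerate(arr):
                if v != 0:
                    fh.write(f"{contig}\t{b * bs}\t{(b + 1) * bs}\t{v:.6f}\n")


def read_bedgraph(track_path: str | Path, bin_size: int | None = None,
                  contig_lengths: dict[str, int] | None = None) -> CoverageTrack:
    read_length, total_weight = 1.0, None
    rows: list[tuple[str, int, int, float]] = []
    with open(track_path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "read_length=" in line:
                    read_length = float(line.split("read_length=")[1])
                elif "total_weight=" in line:
                    total_weight = float(line.split("total_weight=")[1])
                continue
            if line.startswith(("track", "browser")) or not line.strip():
                continue
            c, s, e, v = line.rstrip("\n").split("\t")
            rows.append((c, int(s), int(e), float(v)))
    if not rows:
        raise ValueError(f"empty bedGraph: {track_path}")
    if bin_size is None:
        bin_size = min(e - s for _, s, e, _ in rows)
    if contig_lengths is None:
        contig_lengths = {}
        for c, s, e, _ in rows:
            contig_lengths[c] = max(contig_lengths.get(c, 0), e)
    bins = {c: np.zeros(-(-length // bin_size)) for c, length in contig_lengths.items()}
    for c, s, e, v in rows:
        if s % bin_size or (e - s) != bin_size and e != contig_lengths[c]:
            # tolerate ragged last bin only
            if (e - s) > bin_size:
                raise ValueError(f"bedGraph interval {c}:{s}-{e} wider than bin {bin_size}")
        bins[c][s // bin_size] = v
    if total_weight is None:
        total_weight = sum(float(a.sum()) for a in bins.values()) * bin_size / read_length
    return CoverageTrack(bins=bins, bin_size=bin_size,
                         total_weight=total_weight, read_length=read_length)


# ---------------------------------------------------------------- JSON

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
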