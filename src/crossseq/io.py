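"""Standard-format I/O: SAM/BAM alignments, FASTA genomes, BED/TSV reports.

Exposes a uniform :class:`AlignedRead` record to the scoring modules so
they never touch pysam objects directly.  All coordinates are 0-based,
half-open, both internally and in BED output; 1-based coordinates appear
only in human-facing alignment rendering.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

log = logging.getLogger("crossseq")

# CIGAR vocabulary shared with the simulator: reference-consuming ops are
# match/deletion; query-consuming ops are match/insertion/softclip.
OP_MATCH, OP_INS, OP_DEL, OP_SOFT = "match", "insertion", "deletion", "softclip"
_PYSAM_OP = {0: OP_MATCH, 7: OP_MATCH, 8: OP_MATCH, 1: OP_INS, 2: OP_DEL, 4: OP_SOFT}
_TO_PYSAM = {OP_MATCH: 0, OP_INS: 1, OP_DEL: 2, OP_SOFT: 4}


@dataclass
class AlignedRead:
    """A mapped single-end read, strand-aware, with its CIGAR.

    ``start``/``end`` delimit the reference-aligned span (soft clips
    excluded); ``query_seq`` is stored in forward-strand orientation as
    in SAM.
    """

    chrom: str
    start: int
    end: int
    strand: str
    cigar: tuple[tuple[str, int], ...]
    query_seq: str
    mapq: int = 60
    name: str = ""

    def __post_init__(self):
        ref = sum(n for op, n in self.cigar if op in (OP_MATCH, OP_DEL))
        qry = sum(n for op, n in self.cigar if op in (OP_MATCH, OP_INS, OP_SOFT))
        if self.end - self.start != ref:
            raise ValueError("CIGAR reference span inconsistent with start/end")
        if self.query_seq and len(self.query_seq) != qry:
            raise ValueError("CIGAR query span inconsistent with sequence")
        if self.start < 0:
            raise ValueError("negative start")

    def base_at(self, ref_pos: int) -> str | None:
        """Query base aligned to ``ref_pos``; None if deleted/outside."""
        r, q = self.start, 0
        for op, n in self.cigar:
            if op == OP_MATCH:
                if r <= ref_pos < r + n:
                    return self.query_seq[q + (ref_pos - r)]
                r += n
                q += n
            elif op == OP_DEL:
                if r <= ref_pos < r + n:
                    return None
                r += n
            elif op in (OP_INS, OP_SOFT):
                q += n
        return None

    def insertion_at(self, ref_boundary: int) -> str | None:
        """Inserted bases placed between ``ref_boundary - 1`` and
        ``ref_boundary``, or None if the alignment has no insertion there."""
        r, q = self.start, 0
        for op, n in self.cigar:
            if op == OP_MATCH:
                r += n
                q += n
            elif op == OP_DEL:
                r += n
            elif op == OP_INS:
                if r == ref_boundary:
                    return self.query_seq[q:q + n]
                q += n
            else:  # softclip
                q += n
        return None

    def spans(self, start: int, end: int) -> bool:
        """True if the aligned span covers [start, end) entirely."""
        return self.start <= start and self.end >= end


class GenomeIndex:
    """Random-access uppercase base fetch over named contigs.

    Backed either by an in-memory dict of sequences (simulator output,
    tests) or by an indexed FASTA through pyfaidx.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {name: s.upper() for name, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 0 or end > len(self._seqs[chrom]) or start > end:
            raise IndexError(
                f"fetch({chrom}, {start}, {end}) outside contig of length "
                f"{len(self._seqs[chrom])}")
        return self._seqs[chrom][start:end]

    def write_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
        try:
            import pyfaidx

            pyfaidx.Faidx(str(path))  # sidecar .fai
        except Exception:  # pragma: no cover - index is a convenience
            pass


# ---------------------------------------------------------------------------
# SAM/BAM


def read_alignments(path: str | os.PathLike, region: tuple[str, int, int] | None = None,
                    min_mapq: int = 20) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments with mapq >= ``min_mapq``.

    Unmapped, secondary and supplementary records are dropped; malformed
    records are skipped with a logged warning.  Region queries require an
    index (BAM); plain SAM supports only whole-file streaming.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        if region is not None:
            if not fh.has_index():
                raise OSError(f"region query on {path} requires an index")
            records = fh.fetch(region[0], region[1], region[2])
        else:
            records = fh
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            try:
                cigar = tuple((_PYSAM_OP[op], n) for op, n in rec.cigartuples)
                yield AlignedRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    cigar=cigar,
                    query_seq=rec.query_sequence or "",
                    mapq=rec.mapping_quality,
                    name=rec.query_name,
                )
            except (KeyError, ValueError) as exc:
                log.warning("skipping malformed record %s: %s", rec.query_name, exc)


def write_alignments(reads: Iterable[AlignedRead], path: str | os.PathLike,
                     contig_lengths: dict[str, int]) -> int:
    """Write coordinate-sorted SAM/BAM with proper header; returns count."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    order = {c: i for i, c in enumerate(contig_lengths)}
    reads = sorted(reads, key=lambda r: (order[r.chrom], r.start))
    mode = "wb" if str(path).endswith(".bam") else "w"
    n = 0
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name or f"read{i}"
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigartuples = [(_TO_PYSAM[op], ln) for op, ln in r.cigar]
            a.query_sequence = r.query_seq
            a.flag = 16 if r.strand == "-" else 0
            out.write(a)
            n += 1
    if mode == "wb":
        pysam.index(str(path))
    return n


# ---------------------------------------------------------------------------
# Site reports

#: TSV report columns, in order.
SITE_COLUMNS = [
    "rank", "chrom", "cut_pos", "cross_score", "control_score",
    "end_count_fwd", "end_count_rev", "depth", "target_seq",
    "n_mismatches", "bulge", "alignment_string", "editor_signal",
]


def _site_row(site) -> dict:
    if isinstance(site, dict):
        row = dict(site)
    else:
        row = {k: getattr(site, k, None) for k in SITE_COLUMNS}
        if row.get("depth") is None:
            row["depth"] = getattr(site, "local_depth", None)
    return {k: ("." if row.get(k) is None else row.get(k)) for k in SITE_COLUMNS}


def write_sites(sites: Sequence, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write candidate sites as a TSV report or BED6.

    TSV: tab-delimited, UTF-8, one ``#``-prefixed header line, columns
    :data:`SITE_COLUMNS`.  BED6: ``chrom  cut_pos  cut_pos+1  name  score
    strand`` with the CROSS score in the score column.
    """
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#" + "\t".join(SITE_COLUMNS) + "\n")
            for site in sites:
                row = _site_row(site)
                fh.write("\t".join(str(row[k]) for k in SITE_COLUMNS) + "\n")
    elif format == "bed":
        with open(path, "w", encoding="utf-8") as fh:
            for site in sites:
                row = _site_row(site)
                name = f"site_{row['rank']}"
                strand = getattr(site, "strand", None) or "."
                fh.write(f"{row['chrom']}\t{row['cut_pos']}\t{int(row['cut_pos']) + 1}"
                         f"\t{name}\t{row['cross_score']}\t{strand}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_sites(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV site report back into a DataFrame (inverse of write_sites)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    for col in ("rank", "cut_pos", "end_count_fwd", "end_count_rev", "depth",
                "n_mismatches"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in ("cross_score", "control_score"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_bedgraph(values, chrom: str, path: str | os.PathLike) -> None:
    """Write a per-base integer track as bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        run_start, run_val = None, 0
        for i, v in enumerate(values):
            v = int(v)
            if v != run_val:
                if run_val != 0:
                    fh.write(f"{chrom}\t{run_start}\t{i}\t{run_val}\n")
                run_start, run_val = i, v
        if run_val != 0:
            fh.write(f"{chrom}\t{run_start}\t{len(values)}\t{run_val}\n")
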