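"""Independent brute-force oracles used by the tests.

Deliberately written from the definitions, without importing the library
implementations they check: naive per-read recounting for the end
pileup / CROSS evidence, and exhaustive enumeration for bulge-aware
guide alignment.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def recount_pileup(reads, contig_lengths):
    """Per-position F, R and per-strand depth, recounted read by read."""
    F = {c: np.zeros(n, dtype=int) for c, n in contig_lengths.items()}
    R = {c: np.zeros(n, dtype=int) for c, n in contig_lengths.items()}
    Df = {c: np.zeros(n, dtype=int) for c, n in contig_lengths.items()}
    Dr = {c: np.zeros(n, dtype=int) for c, n in contig_lengths.items()}
    for r in reads:
        if r.strand == "+":
            F[r.chrom][r.start] += 1
            for pos in range(r.start, r.end):
                Df[r.chrom][pos] += 1
        else:
            R[r.chrom][r.end - 1] += 1
            for pos in range(r.start, r.end):
                Dr[r.chrom][pos] += 1
    return F, R, Df, Dr


def cross_evidence_naive(reads, contig_lengths, chrom, cut_pos):
    """(F, R, D) at one putative cut position, straight from the read list.

    D is the forward-strand coverage at cut_pos plus the reverse-strand
    coverage at cut_pos - 1: each fragment of a cut duplex counted at the
    position where its terminus is informative.
    """
    F = sum(1 for r in reads
            if r.chrom == chrom and r.strand == "+" and r.start == cut_pos)
    R = sum(1 for r in reads
            if r.chrom == chrom and r.strand == "-" and r.end - 1 == cut_pos - 1)
    D = sum(1 for r in reads
            if r.chrom == chrom and r.strand == "+"
            and r.start <= cut_pos < r.end)
    if cut_pos > 0:
        D += sum(1 for r in reads
                 if r.chrom == chrom and r.strand == "-"
                 and r.start <= cut_pos - 1 < r.end)
    return F, R, D


def _pam_ok(pattern: str, s: str) -> bool:
    return len(pattern) == len(s) and all(b in _IUPAC[p] for p, b in zip(pattern, s))


def exhaustive_align(context: str, spacer: str, pam: str,
                     max_mm: int, max_bulge: int):
    """Enumerate every orientation x PAM placement x bulge placement and
    return the minimal admissible (bulge_count, n_mismatches), or None."""
    context = context.upper()
    S, P = len(spacer), len(pam)
    best = None
    for seq in (context, rc(context)):
        for pstart in range(len(seq) - P + 1):
            if not _pam_ok(pam, seq[pstart:pstart + P]):
                continue
            cands = []
            if pstart >= S:
                t = seq[pstart - S:pstart]
                cands.append((0, sum(a != b for a, b in zip(spacer, t))))
            if max_bulge >= 1:
                if pstart >= S + 1:
                    t = seq[pstart - S - 1:pstart]
                    for skip in range(S + 1):
                        aligned = t[:skip] + t[skip + 1:]
                        cands.append((1, sum(a != b for a, b
                                             in zip(spacer, aligned))))
                if pstart >= S - 1:
                    t = seq[pstart - S + 1:pstart]
                    for skip in range(S):
                        gspacer = spacer[:skip] + spacer[skip + 1:]
                        cands.append((1, sum(a != b for a, b
                                             in zip(gspacer, t))))
            for cand in cands:
                if cand[0] <= max_bulge and cand[1] <= max_mm:
                    if best is None or cand < best:
                        best = cand
    return best


def find_pam_naive(seq: str, pattern: str, offset: int = 0):
    """Regex-free PAM scan over both strands of a plain string."""
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k].upper()
        if _pam_ok(pattern, kmer):
            hits.append((offset + i, "+"))
        if _pam_ok(pattern, rc(kmer)):
            hits.append((offset + i, "-"))
    return hits
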