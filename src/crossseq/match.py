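"""Bulge-aware alignment of candidate loci to the guide, PAM search,
consensus matrices and guanine-availability checks.

Candidate loci come from the score, not from an a priori genome-wide
search; this module explains them: the best mismatch-plus-single-bulge
alignment of the locus to the spacer (a DNA bulge is an extra unpaired
base on the target, making the protospacer one base longer; an sgRNA
bulge leaves a guide base unpaired, making it one base shorter), the
PAM instance, a consensus/position-frequency view over the called set,
and the guanine count on the displaced strand (the labeling substrate:
sites with no G on the non-target strand are invisible to a
guanine-reactive probe).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .guides import GuideSpec, IUPAC, iupac_match, revcomp
from .io import GenomeIndex

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class GuideAlignment:
    """Best mismatch/bulge alignment of a candidate locus to the spacer.

    ``bulge_pos`` is the 1-based protospacer position adjacent to the
    bulge (PAM-distal = 1); ``projected`` is the target protospacer
    projected onto spacer coordinates (length = spacer length, ``-`` at
    an sgRNA-bulge gap), used for consensus building.
    """

    target_seq: str            # matched protospacer(+/- bulge) + PAM, site orientation
    n_mismatches: int
    bulge_type: str            # none | rna | dna
    bulge_pos: int | None
    pam_matches: bool
    alignment_string: str
    orientation: str           # strand of the site in the supplied context
    projected: str = ""
    pam_seq: str = ""


@dataclass
class ConsensusMatrix:
    """Per-column base frequencies and information content over called sites."""

    frequencies: np.ndarray    # (spacer_len, 4) over A,C,G,T; rows sum to 1
    information: np.ndarray    # bits per column, in [0, 2]
    counts: np.ndarray         # (spacer_len, 4) raw counts
    alphabet: str = "ACGT"


def find_pam(genome: GenomeIndex, chrom: str, window: tuple[int, int],
             pattern: str) -> list[tuple[int, str]]:
    """All PAM matches on both strands within ``window``.

    Returns ``(pos, strand)`` pairs where ``pos`` is the 0-based forward
    coordinate of the leftmost base of the matched span; for ``-`` the
    pattern matches the reverse complement of that span.
    """
    for p in pattern.upper():
        if p not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {p!r}")
    start, end = window
    seq = genome.fetch(chrom, start, end)
    k = len(pattern)
    out: list[tuple[int, str]] = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if iupac_match(pattern, kmer):
            out.append((start + i, "+"))
        if iupac_match(pattern, revcomp(kmer)):
            out.append((start + i, "-"))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _render(spacer_row: str, target_row: str, pam: str) -> str:
    bars = "".join(" " if "-" in (s, t) else ("|" if s == t else ".")
                   for s, t in zip(spacer_row, target_row))
    return (f"spacer  5'-{spacer_row} {'-' * len(pam)}-3'\n"
            f"           {bars} {' ' * len(pam)}\n"
            f"target  5'-{target_row} {pam}-3'")


def align_guide(target_context: str, guide: GuideSpec, max_mm: int = 6,
                max_bulge: int = 1) -> GuideAlignment | None:
    """Best (bulge_count, n_mismatches)-lexicographic alignment of the
    context to the spacer, both orientations, PAM required.

    Evaluates the ungapped alignment, every single-base DNA-bulge
    placement (one extra target base skipped) and every single-base
    sgRNA-bulge placement (one spacer base skipped) at every valid PAM
    position.  Ties prefer the most PAM-proximal bulge, then the ``+``
    orientation.  Returns None when no alignment satisfies
    (``max_mm``, ``max_bulge``).
    """
    context = target_context.upper()
    S = guide.spacer_len
    if len(context) < S - 1 + len(guide.pam):
        raise ValueError("target context shorter than spacer-1 + PAM")
    spacer = guide.spacer
    P = len(guide.pam)
    best = None   # (bulges, mm, -bulge_pos, orient_penalty, pam_start, payload)

    for orient in "+-":
        s = context if orient == "+" else revcomp(context)
        for pam_start in range(len(s) - P + 1):
            pam = s[pam_start:pam_start + P]
            if not iupac_match(guide.pam, pam):
                continue
            cands: list[tuple[int, int, int, dict]] = []
            if pam_start >= S:
                t = s[pam_start - S:pam_start]
                cands.append((0, _hamming(spacer, t), 0, dict(
                    kind="none", target=t, spacer_row=spacer, target_row=t,
                    projected=t)))
            if max_bulge >= 1 and pam_start >= S + 1:
                t = s[pam_start - S - 1:pam_start]      # one extra target base
                for b in range(S + 1):
                    aligned = t[:b] + t[b + 1:]
                    cands.append((1, _hamming(spacer, aligned), b, dict(
                        kind="dna", target=t,
                        spacer_row=spacer[:b] + "-" + spacer[b:],
                        target_row=t, projected=aligned)))
            if max_bulge >= 1 and pam_start >= S - 1:
                t = s[pam_start - S + 1:pam_start]      # one spacer base unpaired
                for j in range(S):
                    aligned = spacer[:j] + spacer[j + 1:]
                    cands.append((1, _hamming(aligned, t), j + 1, dict(
                        kind="rna", target=t, spacer_row=spacer,
                        target_row=t[:j] + "-" + t[j:],
                        projected=t[:j] + "-" + t[j:])))
            for bulges, mm, bpos, payload in cands:
                if mm > max_mm or bulges > max_bulge:
                    continue
                key = (bulges, mm, -bpos, 0 if orient == "+" else 1, pam_start)
                if best is None or key < best[0]:
                    best = (key, orient, pam, bpos, payload)
    if best is None:
        return None
    key, orient, pam, bpos, payload = best
    bulges, mm = key[0], key[1]
    return GuideAlignment(
        target_seq=payload["target"] + pam,
        n_mismatches=mm,
        bulge_type=payload["kind"],
        bulge_pos=bpos if payload["kind"] != "none" else None,
        pam_matches=True,
        alignment_string=_render(payload["spacer_row"], payload["target_row"], pam),
        orientation=orient,
        projected=payload["projected"],
        pam_seq=pam,
    )


def consensus_matrix(alignments: Sequence[GuideAlignment]) -> ConsensusMatrix:
    """Position frequency matrix over called sites, projected onto spacer
    coordinates, with per-column information content 2 - H (bits).

    Bulged targets are projected by dropping the extra DNA-bulge base and
    leaving a gap at an sgRNA-bulge position (gaps contribute nothing to
    their column).  No pseudocounts and no small-sample correction.
    """
    if not alignments:
        raise ValueError("consensus_matrix requires at least one alignment")
    S = len(alignments[0].projected)
    counts = np.zeros((S, 4), dtype=np.int64)
    for aln in alignments:
        if len(aln.projected) != S:
            raise ValueError("alignments project to different spacer lengths")
        for i, b in enumerate(aln.projected):
            if b in _BASE_IDX:
                counts[i, _BASE_IDX[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.25)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=1)
    info = np.where(totals[:, 0] > 0, 2.0 - entropy, 0.0)
    return ConsensusMatrix(frequencies=freqs, information=info, counts=counts)


def g_content(target_context: str, orientation: str) -> tuple[int, bool]:
    """Guanine count on the labeled (displaced, non-target) strand.

    The non-target strand is the site-orientation strand, so for a ``+``
    site this is simply the G count of the forward context; for a ``-``
    site it is the G count of the reverse complement (= C count of the
    forward context).  ``labelable`` is True when at least one G exists
    for the probe to react with.
    """
    seq = target_context.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-ACGTN symbols")
    n = seq.count("G") if orientation == "+" else seq.count("C")
    return n, n >= 1


def logo_dataframe(matrix: ConsensusMatrix):
    """Information-scaled letter heights (bits) as a DataFrame, one row per
    spacer position — the numbers behind a sequence logo."""
    import pandas as pd

    heights = matrix.frequencies * matrix.information[:, None]
    df = pd.DataFrame(heights, columns=list(matrix.alphabet))
    df.index = np.arange(1, len(df) + 1)
    df.index.name = "position"
    return df
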