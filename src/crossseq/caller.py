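"""Read-end pileups, CROSS scoring and candidate cleavage-site calling.

The central statistic is the CROSS score: the number of cleavage-signal
reads at a locus under library-size normalization.  A cleavage-signal
read is one whose aligned terminus coincides with the modeled cut: a
forward read starting exactly at ``cut_pos`` (the fragment 3' of the
cut) or a reverse read ending exactly at ``cut_pos - 1`` (the fragment
5' of the cut).  With F and R those strand-resolved end counts and
``total_mapped`` the library size,

    cross_score = 1e6 * (F + R) / total_mapped      (reads per million)

reported together with the local end fraction f = (F + R) / D, where D
is the strand-aware coverage flanking the scissile bond: forward-strand
depth at ``cut_pos`` plus reverse-strand depth at ``cut_pos - 1`` (each
fragment counted at its informative position, so f lies in [0, 1]).  A position is a candidate only
if it has bidirectional support (F >= m and R >= m; relaxed to
unidirectional for nickase-based editors), f >= f_min, and it survives
the no-guide control test.  Soft-clipped bases never move a terminus:
the terminus is the first/last reference-aligned base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import AlignedRead, GenomeIndex


@dataclass
class CallerParams:
    """Gates and knobs for candidate calling (all config-exposed)."""

    min_end_reads: int = 3        # m: per-strand end-count floor
    min_end_fraction: float = 0.2  # f_min: local end-fraction floor
    control_max_ends: int = 1     # c_max: control end count tolerated outright
    control_ratio: float = 5.0    # ratio_min: treated/control score ratio
    merge_window: int = 10        # bp; nearby candidates merged, max kept
    require_bidirectional: bool = True


@dataclass
class EndPileup:
    """Per-contig strand-resolved read-terminus and coverage arrays."""

    fwd_starts: dict[str, np.ndarray]
    rev_ends: dict[str, np.ndarray]
    depth_fwd: dict[str, np.ndarray]
    depth_rev: dict[str, np.ndarray]
    total_mapped: int

    @property
    def contigs(self) -> list[str]:
        return list(self.fwd_starts)

    def depth(self, chrom: str, pos: int) -> int:
        """Both-strand coverage at one position."""
        return int(self.depth_fwd[chrom][pos] + self.depth_rev[chrom][pos])

    def cut_depth(self, chrom: str, cut_pos: int) -> int:
        """Strand-aware coverage at a cut: + depth at ``cut_pos`` plus
        - depth at ``cut_pos - 1`` (0 on the edge)."""
        d = int(self.depth_fwd[chrom][cut_pos])
        if cut_pos > 0:
            d += int(self.depth_rev[chrom][cut_pos - 1])
        return d


@dataclass
class CrossEvidence:
    """Score plus the raw counts behind it."""

    score: float          # reads per million of cleavage-signal reads
    end_fraction: float   # (F + R) / D, 0 when D = 0
    end_count_fwd: int    # F
    end_count_rev: int    # R
    depth: int            # D: + depth at cut_pos plus - depth at cut_pos - 1
    candidate: bool
    flags: tuple[str, ...] = ()


@dataclass
class CleavageSite:
    """A scored candidate locus with treated and control evidence."""

    chrom: str
    cut_pos: int
    cross_score: float
    end_count_fwd: int
    end_count_rev: int
    local_depth: int
    control_score: float
    rank: int = 0
    end_fraction: float = 0.0
    # annotation filled in by guide matching / editor scoring
    strand: str | None = None
    target_seq: str | None = None
    n_mismatches: int | None = None
    bulge: str | None = None
    alignment_string: str | None = None
    editor_signal: str | None = None


def build_end_pileup(reads: Iterable[AlignedRead], genome: GenomeIndex) -> EndPileup:
    """Accumulate strand-resolved terminus counts and coverage.

    The terminus is the first/last reference-aligned base, so soft clips
    are ignored by construction (``AlignedRead.start``/``end`` already
    exclude them).  Coverage counts every reference-aligned base,
    including deletion gaps spanned by the alignment.
    """
    lengths = genome.lengths
    fwd = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
    rev = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
    dfd = {c: np.zeros(n + 1, dtype=np.int64) for c, n in lengths.items()}
    drd = {c: np.zeros(n + 1, dtype=np.int64) for c, n in lengths.items()}
    total = 0
    for r in reads:
        if r.chrom not in fwd:
            raise KeyError(f"read {r.name!r} on unknown contig {r.chrom!r}")
        total += 1
        if r.strand == "+":
            fwd[r.chrom][r.start] += 1
            dfd[r.chrom][r.start] += 1
            dfd[r.chrom][r.end] -= 1
        else:
            rev[r.chrom][r.end - 1] += 1
            drd[r.chrom][r.start] += 1
            drd[r.chrom][r.end] -= 1
    depth_fwd = {c: np.cumsum(a[:-1]) for c, a in dfd.items()}
    depth_rev = {c: np.cumsum(a[:-1]) for c, a in drd.items()}
    return EndPileup(fwd, rev, depth_fwd, depth_rev, total)


def cross_score(pileup: EndPileup, chrom: str, cut_pos: int,
                params: CallerParams | None = None) -> CrossEvidence:
    """CROSS score and candidate gating at one position.

    At ``cut_pos == 0`` there is no position for a reverse-end partner;
    R is taken as 0 and the evidence is flagged ``edge``.
    """
    params = params or CallerParams()
    if not (0 <= cut_pos < len(pileup.fwd_starts[chrom])):
        raise IndexError(f"cut_pos {cut_pos} outside contig {chrom}")
    F = int(pileup.fwd_starts[chrom][cut_pos])
    flags: list[str] = []
    if cut_pos == 0:
        R = 0
        flags.append("edge")
    else:
        R = int(pileup.rev_ends[chrom][cut_pos - 1])
    D = pileup.cut_depth(chrom, cut_pos)
    score = 1e6 * (F + R) / pileup.total_mapped if pileup.total_mapped else 0.0
    frac = (F + R) / D if D else 0.0
    df = int(pileup.depth_fwd[chrom][cut_pos])
    dr = int(pileup.depth_rev[chrom][cut_pos - 1]) if cut_pos > 0 else 0
    if params.require_bidirectional:
        support = F >= params.min_end_reads and R >= params.min_end_reads
        gate_frac = frac
    else:
        # nickase modes sever one strand only: gate on the better of the
        # per-strand truncation fractions, not on the diluted joint one
        support = max(F, R) >= params.min_end_reads
        gate_frac = max(F / df if df else 0.0, R / dr if dr else 0.0)
    candidate = support and gate_frac >= params.min_end_fraction
    if not support:
        flags.append("no_bidirectional_support" if params.require_bidirectional
                     else "insufficient_ends")
    if gate_frac < params.min_end_fraction:
        flags.append("low_end_fraction")
    return CrossEvidence(score, frac, F, R, D, candidate, tuple(flags))


def truncation_fraction(pileup: EndPileup, chrom: str, pos: int, strand: str) -> float:
    """Strand-specific fraction of covering reads whose terminus is at ``pos``.

    The read-out of nickase activity: a nick truncates reads on the
    severed strand toward the cut, so this fraction rises on that strand
    only.  Returns 0 when strand depth is 0.
    """
    if strand == "+":
        ends = int(pileup.fwd_starts[chrom][pos])
        depth = int(pileup.depth_fwd[chrom][pos])
    else:
        ends = int(pileup.rev_ends[chrom][pos])
        depth = int(pileup.depth_rev[chrom][pos])
    return ends / depth if depth else 0.0


def _merge_candidates(positions: np.ndarray, scores: np.ndarray,
                      window: int) -> np.ndarray:
    """Merge candidates within ``window`` bp, keeping the max-score one
    (leftmost on ties).  Positions must be sorted ascending."""
    keep: list[int] = []
    i, n = 0, len(positions)
    while i < n:
        j = i
        best = i
        while j + 1 < n and positions[j + 1] - positions[j] <= window:
            j += 1
            if scores[j] > scores[best]:
                best = j
        keep.append(best)
        i = j + 1
    return np.array(keep, dtype=np.int64)


def scan_genome(pileup_treated: EndPileup, pileup_control: EndPileup | None,
                params: CallerParams | None = None) -> list[CleavageSite]:
    """Score every position, apply candidate and control gates, merge and rank.

    The control test passes if the control end count at the position is
    <= ``control_max_ends`` or the treated score is at least
    ``control_ratio`` times the control score.  Sites within
    ``merge_window`` bp are merged keeping the max-score position.
    Result is sorted by descending score with dense 1-based ranks, ties
    broken by (chrom, cut_pos).
    """
    params = params or CallerParams()
    if pileup_control is not None and \
            set(pileup_treated.contigs) != set(pileup_control.contigs):
        raise ValueError("treated and control pileups cover different contigs")
    sites: list[CleavageSite] = []
    for chrom in pileup_treated.contigs:
        F = pileup_treated.fwd_starts[chrom]
        R = np.concatenate(([0], pileup_treated.rev_ends[chrom][:-1]))
        ends = F + R
        if params.require_bidirectional:
            support = (F >= params.min_end_reads) & (R >= params.min_end_reads)
        else:
            support = np.maximum(F, R) >= params.min_end_reads
        cand_pos = np.flatnonzero(support)
        if cand_pos.size == 0:
            continue
        drev = np.concatenate(([0], pileup_treated.depth_rev[chrom][:-1]))
        dfwd = pileup_treated.depth_fwd[chrom][cand_pos]
        drev = drev[cand_pos]
        if params.require_bidirectional:
            D = dfwd + drev
            frac = np.divide(ends[cand_pos], D, out=np.zeros(cand_pos.size),
                             where=D > 0)
        else:
            ff = np.divide(F[cand_pos], dfwd, out=np.zeros(cand_pos.size),
                           where=dfwd > 0)
            fr = np.divide(R[cand_pos], drev, out=np.zeros(cand_pos.size),
                           where=drev > 0)
            frac = np.maximum(ff, fr)
        cand_pos = cand_pos[frac >= params.min_end_fraction]
        if cand_pos.size == 0:
            continue
        tscore = 1e6 * ends[cand_pos] / max(pileup_treated.total_mapped, 1)
        if pileup_control is not None:
            cF = pileup_control.fwd_starts[chrom][cand_pos]
            cR = np.concatenate(([0], pileup_control.rev_ends[chrom][:-1]))[cand_pos]
            cends = cF + cR
            cscore = 1e6 * cends / max(pileup_control.total_mapped, 1)
            ok = (cends <= params.control_max_ends) | \
                 (tscore >= params.control_ratio * cscore)
            cand_pos, tscore, cscore = cand_pos[ok], tscore[ok], cscore[ok]
        else:
            cscore = np.zeros(cand_pos.size)
        if cand_pos.size == 0:
            continue
        keep = _merge_candidates(cand_pos, tscore, params.merge_window)
        for k in keep:
            pos = int(cand_pos[k])
            ev = cross_score(pileup_treated, chrom, pos, params)
            sites.append(CleavageSite(
                chrom=chrom, cut_pos=pos, cross_score=ev.score,
                end_count_fwd=ev.end_count_fwd, end_count_rev=ev.end_count_rev,
                local_depth=ev.depth, control_score=float(cscore[k]),
                end_fraction=ev.end_fraction))
    sites.sort(key=lambda s: (-s.cross_score, s.chrom, s.cut_pos))
    # dense 1-based ranks: equal scores share a rank
    rank, prev = 0, None
    for s in sites:
        if s.cross_score != prev:
            rank += 1
            prev = s.cross_score
        s.rank = rank
    return sites
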