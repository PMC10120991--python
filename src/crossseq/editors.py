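"""Editor-specific read signatures at candidate loci.

Base editors leave no double-strand break, so the cleavage-end score is
supplemented (and the candidate gate adjusted) with the ratio of reads
carrying the programmed base conversion inside the editing window —
C->T for CBE, A->G for ABE, both evaluated on the non-target strand of
the site.  Prime editors are read out through the programmed insertion
placed at position +1, the first nucleotide following the pegRNA-induced
nick, recognized as a CIGAR insertion with exactly the expected bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .caller import CallerParams, CrossEvidence, EndPileup, cross_score
from .guides import GuideSpec, ConfigError, revcomp
from .io import AlignedRead, GenomeIndex


@dataclass
class EditingSignal:
    """Read-level editing evidence at one site.

    ``ratio`` is reads-with-signature over reads spanning the assayed
    span; it is ``None`` (missing) when no read spans the span.
    ``per_position`` maps 1-based protospacer window positions to
    conversion counts (empty for prime editing).
    """

    chrom: str
    cut_pos: int
    n_spanning: int
    n_signal: int
    per_position: dict[int, int] = field(default_factory=dict)

    @property
    def ratio(self) -> float | None:
        return self.n_signal / self.n_spanning if self.n_spanning else None


def _site_orientation(site) -> str:
    strand = getattr(site, "strand", None)
    if strand not in ("+", "-"):
        raise ValueError(f"site orientation undetermined for {site!r}")
    return strand


def conversion_ratio(reads: Iterable[AlignedRead], genome: GenomeIndex,
                     site, guide: GuideSpec) -> EditingSignal:
    """Ratio of editing-window-spanning reads with >= 1 programmed conversion.

    A read is signal if it spans the entire editing window and carries at
    least one reference-mismatching base equal to the conversion product
    (reference C read as T for CBE, on the non-target strand orientation
    of the site); reads with only other mismatches are not signal.  A
    read counts once however many window positions are converted;
    per-position counts are reported separately.
    """
    if guide.editor_mode not in ("cbe", "abe"):
        raise ConfigError(f"conversion_ratio requires cbe/abe, got {guide.editor_mode}")
    strand = _site_orientation(site)
    a, b = guide.window_span(site.cut_pos, strand)
    src, dst = guide.conversion
    if strand == "-":                      # non-target strand is the - strand:
        src, dst = revcomp(src), revcomp(dst)  # C->T there reads G->A on +
    ref = genome.fetch(site.chrom, a, b)
    n_span = n_sig = 0
    per_pos: dict[int, int] = {}
    lo, hi = guide.editing_window
    for w in range(lo, hi + 1):
        per_pos[w] = 0
    for r in reads:
        if r.chrom != site.chrom or not r.spans(a, b):
            continue
        n_span += 1
        hit = False
        for g in range(a, b):
            if ref[g - a] != src:
                continue
            base = r.base_at(g)
            if base == dst:
                hit = True
                # map genomic position back to 1-based protospacer coords
                if strand == "+":
                    w = g - guide.protospacer_start(site.cut_pos, "+") + 1
                else:
                    w = guide.protospacer_start(site.cut_pos, "-") \
                        + guide.spacer_len - g
                per_pos[w] = per_pos.get(w, 0) + 1
        if hit:
            n_sig += 1
    return EditingSignal(site.chrom, site.cut_pos, n_span, n_sig, per_pos)


def insertion_fraction(reads: Iterable[AlignedRead], site,
                       guide: GuideSpec, tolerance: int = 0) -> EditingSignal:
    """Fraction of nick-spanning reads carrying the programmed insert at +1.

    Signal requires a CIGAR insertion whose reference placement is the
    nick boundary (within ``tolerance`` bp, default exact) and whose
    bases equal ``pe_insert`` in the orientation of the site.  Spanning
    reads are those covering ``[nick - 1, nick + 1)``.
    """
    if guide.editor_mode != "pe" or not guide.pe_insert:
        raise ConfigError("insertion_fraction requires editor_mode='pe' with pe_insert")
    strand = _site_orientation(site)
    nick = site.cut_pos
    want = guide.pe_insert if strand == "+" else revcomp(guide.pe_insert)
    n_span = n_sig = 0
    for r in reads:
        if r.chrom != site.chrom or not r.spans(nick - 1, nick + 1):
            continue
        n_span += 1
        for shift in range(-tolerance, tolerance + 1):
            if r.insertion_at(nick + shift) == want:
                n_sig += 1
                break
    return EditingSignal(site.chrom, site.cut_pos, n_span, n_sig)


@dataclass
class SiteModeScore:
    """Composite per-site record: cleavage evidence plus editor signal."""

    mode: str
    cross: CrossEvidence
    editing: EditingSignal | None
    candidate: bool


def score_site_by_mode(site, pileup: EndPileup, reads: Sequence[AlignedRead],
                       genome: GenomeIndex, guide: GuideSpec,
                       params: CallerParams | None = None,
                       r_min: float = 0.01,
                       pe_tolerance: int = 0) -> SiteModeScore:
    """Score one locus with the signature matching the guide's editor mode.

    Nuclease: cleavage evidence only.  CBE/ABE: cleavage evidence plus
    conversion ratio; candidacy additionally requires ratio >= ``r_min``.
    PE: cleavage evidence plus insertion fraction, same ``r_min`` gate.
    Nickase-based modes drop the bidirectional end-support requirement
    (only one strand is cut).
    """
    params = params or CallerParams()
    mode = guide.editor_mode
    if mode != "nuclease":
        from dataclasses import replace

        params = replace(params, require_bidirectional=False)
    ev = cross_score(pileup, site.chrom, site.cut_pos, params)
    if mode == "nuclease":
        return SiteModeScore(mode, ev, None, ev.candidate)
    if mode in ("cbe", "abe"):
        sig = conversion_ratio(reads, genome, site, guide)
    else:
        sig = insertion_fraction(reads, site, guide, tolerance=pe_tolerance)
    candidate = ev.candidate and sig.ratio is not None and sig.ratio >= r_min
    return SiteModeScore(mode, ev, sig, candidate)
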