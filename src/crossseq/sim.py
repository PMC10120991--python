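"""Planted-signal simulator for ssDNA-enrichment off-target experiments.

Generates a toy reference genome, plants one on-target plus configurable
degenerate off-target copies of a guide's protospacer+PAM, and emits
already-aligned single-end reads for a treated library and a no-guide
control.  Treated reads around each planted site carry the editor's
signature:

* nuclease: a fraction of cut-spanning reads on each severed strand is
  re-anchored so its terminus sits exactly at the cut (forward reads
  start at ``cut_pos``, reverse reads end at ``cut_pos - 1``) — the
  read-end pileup signature of a double-strand break;
* cbe/abe: termini anchored on the nicked strand only, plus reference
  C->T (or A->G, non-target-strand orientation) substitutions in reads
  spanning the editing window;
* pe: termini anchored on the nicked strand, plus the programmed insert
  as a CIGAR insertion at position +1 after the nick.

Background endogenous ssDNA is modeled as uniformly placed reads; a
configurable fraction suffers a random internal truncation so background
termini land at arbitrary positions, and optional "hotspots" present in
both libraries create guide-independent end stacks so that control
subtraction is exercised non-trivially.

Everything is driven by a single integer seed: identical
:class:`SimConfig` values produce byte-identical read streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .guides import GuideSpec, ConfigError, IUPAC, revcomp
from .io import AlignedRead, GenomeIndex, OP_MATCH, OP_INS

BASES = np.array(list("ACGT"))


class PlacementError(RuntimeError):
    """Could not place planted sites without overlap."""


@dataclass
class SimConfig:
    """Full description of a planted-signal simulation.

    ``mean_depth`` is fold coverage of the background; per-site signal
    fractions are Bernoulli probabilities applied to the reads covering
    the relevant span.  ``background_end_rate`` is the per-read
    probability of a random internal truncation of a background read
    (spurious endogenous ssDNA break).
    """

    seed: int = 0
    genome_length: int = 100_000
    gc_fraction: float = 0.41
    n_offtargets: int = 5
    mismatch_range: tuple[int, int] = (2, 4)
    planted_bulges: int = 1
    read_length: int = 100
    mean_depth: float = 200.0
    cleavage_fraction: float = 0.3
    conversion_fraction: float = 0.3
    insertion_fraction: float = 0.5
    background_end_rate: float = 0.01
    control_included: bool = True
    # extras beyond the headline knobs
    contig: str = "sim1"
    n_hotspots: int = 0
    hotspot_depth: float = 50.0
    mismatch_placement: str = "uniform"  # or "pam_distal"
    min_margin_reads: int = 2            # site margin from contig ends, in read lengths

    def __post_init__(self):
        for name in ("gc_fraction", "cleavage_fraction", "conversion_fraction",
                     "insertion_fraction", "background_end_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 50 * self.read_length:
            raise ConfigError("genome_length must be >= 50 x read_length")
        if self.n_offtargets < 0:
            raise ConfigError("n_offtargets must be >= 0")
        lo, hi = self.mismatch_range
        if not (0 <= lo <= hi):
            raise ConfigError("invalid mismatch_range")
        if self.mismatch_placement not in ("uniform", "pam_distal"):
            raise ConfigError("mismatch_placement must be uniform|pam_distal")


@dataclass
class PlantedSite:
    """Ground truth for one planted locus (for recovery tests)."""

    chrom: str
    cut_pos: int
    strand_of_pam: str                 # strand carrying protospacer + PAM
    target_seq: str                    # protospacer(+/-1 with bulge) + PAM, site strand
    n_mismatches: int
    bulge: str = "none"                # none | rna | dna
    signal_fractions: dict = field(default_factory=dict)
    span: tuple[int, int] = (0, 0)     # forward-strand half-open written span

    @property
    def strand(self) -> str:
        return self.strand_of_pam


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> GenomeIndex:
    """Random genome of the configured length and GC content."""
    rng = _rng(config, 0)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(BASES, size=config.genome_length, p=p))
    return GenomeIndex({config.contig: seq})


# ---------------------------------------------------------------------------
# site planting


def _concrete_pam(pattern: str, rng: np.random.Generator) -> str:
    return "".join(b if len(IUPAC[b]) == 1 else rng.choice(list(IUPAC[b]))
                   for b in pattern)


def _mutate_spacer(spacer: str, n_mm: int, placement: str,
                   rng: np.random.Generator) -> tuple[str, int]:
    s = list(spacer)
    if placement == "pam_distal":
        pool = list(range(min(10, len(s))))          # positions 1-10, PAM-distal
    else:
        pool = list(range(len(s)))
    pos = rng.choice(pool, size=min(n_mm, len(pool)), replace=False)
    for i in pos:
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s), len(pos)


def plant_sites(genome: GenomeIndex, guide: GuideSpec,
                config: SimConfig) -> tuple[GenomeIndex, list[PlantedSite]]:
    """Write one exact on-target plus ``n_offtargets`` degenerate copies
    into the genome at non-overlapping positions; return modified genome
    and the ground truth."""
    rng = _rng(config, 1)
    chrom = config.contig
    L = genome.length(chrom)
    seq = list(genome.fetch(chrom, 0, L))
    S, P = guide.spacer_len, len(guide.pam)
    margin = config.min_margin_reads * config.read_length
    spacing = max(3 * config.read_length, 300)
    if L <= 2 * margin + S + P:
        raise ConfigError("genome too short for planting with margins")

    sites: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    for idx in range(1 + config.n_offtargets):
        if idx == 0:
            proto, n_mm, bulge = guide.spacer, 0, "none"
        else:
            n_mm = int(rng.integers(config.mismatch_range[0],
                                    config.mismatch_range[1] + 1))
            proto, n_mm = _mutate_spacer(guide.spacer, n_mm,
                                         config.mismatch_placement, rng)
            bulge = "none"
            if idx <= config.planted_bulges:
                if idx % 2 == 1:
                    bulge = "dna"    # extra base in the DNA target
                    j = int(rng.integers(1, len(proto)))
                    proto = proto[:j] + rng.choice(list("ACGT")) + proto[j:]
                else:
                    bulge = "rna"    # unpaired guide base: target one shorter
                    j = int(rng.integers(1, len(proto) - 1))
                    proto = proto[:j] + proto[j + 1:]
        pam = _concrete_pam(guide.pam, rng)
        site_seq = proto + pam
        strand = "+" if idx % 2 == 0 else "-"
        written = site_seq if strand == "+" else revcomp(site_seq)

        placed = False
        for _ in range(200):
            pos0 = int(rng.integers(margin, L - margin - len(written)))
            a, b = pos0 - spacing, pos0 + len(written) + spacing
            if all(b <= oa or a >= ob for oa, ob in occupied):
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place site {idx} without overlap")
        seq[pos0:pos0 + len(written)] = list(written)
        occupied.append((pos0, pos0 + len(written)))
        if strand == "+":
            cut_pos = pos0 + len(proto) + guide.cut_offset
        else:
            cut_pos = pos0 + P - guide.cut_offset
        sites.append(PlantedSite(
            chrom=chrom, cut_pos=cut_pos, strand_of_pam=strand,
            target_seq=site_seq, n_mismatches=n_mm, bulge=bulge,
            signal_fractions={
                "cleavage": config.cleavage_fraction,
                "conversion": config.conversion_fraction if guide.editor_mode in ("cbe", "abe") else 0.0,
                "insertion": config.insertion_fraction if guide.editor_mode == "pe" else 0.0,
            },
            span=(pos0, pos0 + len(written)),
        ))
    return GenomeIndex({chrom: "".join(seq)}), sites


# ---------------------------------------------------------------------------
# reads


def _window_bounds(guide: GuideSpec, site: PlantedSite) -> tuple[int, int]:
    return guide.window_span(site.cut_pos, site.strand)


def _emit_reads(genome: GenomeIndex, chrom: str, starts, lengths, is_rev,
                conv_windows, ins_reads, ins_bases_by_read, prefix: str) -> list[AlignedRead]:
    """Materialize AlignedRead records from coordinate arrays.

    ``conv_windows`` maps read index -> (win_start, win_end, src, dst) for
    base-converted reads; ``ins_reads`` maps read index -> insertion
    boundary for insert-bearing reads.
    """
    seqs = genome._seqs[chrom]  # noqa: SLF001 - hot path, package-internal
    out: list[AlignedRead] = []
    for i in range(len(starts)):
        s, ln = int(starts[i]), int(lengths[i])
        strand = "-" if is_rev[i] else "+"
        if i in ins_reads:
            boundary = ins_reads[i]
            ins = ins_bases_by_read[i]
            qseq = seqs[s:boundary] + ins + seqs[boundary:s + ln]
            cigar = ((OP_MATCH, boundary - s), (OP_INS, len(ins)),
                     (OP_MATCH, s + ln - boundary))
        else:
            qseq = seqs[s:s + ln]
            cigar = ((OP_MATCH, ln),)
        if i in conv_windows:
            a, b, src, dst = conv_windows[i]
            q = list(qseq)
            for g in range(max(a, s), min(b, s + ln)):
                if seqs[g] == src:
                    q[g - s] = dst
            qseq = "".join(q)
        out.append(AlignedRead(chrom=chrom, start=s, end=s + ln, strand=strand,
                               cigar=cigar, query_seq=qseq, mapq=60,
                               name=f"{prefix}{i}"))
    out.sort(key=lambda r: (r.start, r.name))
    return out


def _background_arrays(config: SimConfig, L: int, rng: np.random.Generator):
    rl = config.read_length
    n = int(round(config.mean_depth * L / rl))
    starts = rng.integers(0, L - rl + 1, size=n)
    lengths = np.full(n, rl, dtype=np.int64)
    is_rev = rng.random(n) < 0.5
    trunc = rng.random(n) < config.background_end_rate
    if trunc.any():
        new_len = rng.integers(min(20, rl), rl + 1, size=int(trunc.sum()))
        lengths[trunc] = new_len
    return starts.astype(np.int64), lengths, is_rev


def _hotspot_positions(config: SimConfig, L: int) -> np.ndarray:
    rng = _rng(config, 4)
    if config.n_hotspots == 0:
        return np.empty(0, dtype=np.int64)
    lo, hi = 2 * config.read_length, L - 2 * config.read_length
    return rng.integers(lo, hi, size=config.n_hotspots).astype(np.int64)


def _add_hotspots(config: SimConfig, positions, starts, lengths, is_rev,
                  rng: np.random.Generator):
    """End-stacked guide-independent reads at shared loci (both libraries)."""
    rl = config.read_length
    add_s, add_l, add_r = [], [], []
    for h in positions:
        n = rng.poisson(config.hotspot_depth / 2, size=2)
        add_s += [h] * int(n[0]) + [h - rl] * int(n[1])
        add_l += [rl] * int(n[0] + n[1])
        add_r += [False] * int(n[0]) + [True] * int(n[1])
    if add_s:
        starts = np.concatenate([starts, np.array(add_s, dtype=np.int64)])
        lengths = np.concatenate([lengths, np.array(add_l, dtype=np.int64)])
        is_rev = np.concatenate([is_rev, np.array(add_r)])
    return starts, lengths, is_rev


def simulate_reads(genome: GenomeIndex, sites: Sequence[PlantedSite],
                   guide: GuideSpec, config: SimConfig
                   ) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Emit (treated, control) aligned-read lists, coordinate-sorted.

    The control carries background (and hotspots) only; the treated
    library additionally carries the editor signatures at every planted
    site.  Reads never extend past contig ends.
    """
    chrom = config.contig
    L = genome.length(chrom)
    hot = _hotspot_positions(config, L)

    rng_t = _rng(config, 2)
    starts, lengths, is_rev = _background_arrays(config, L, rng_t)
    starts, lengths, is_rev = _add_hotspots(config, hot, starts, lengths, is_rev, rng_t)

    conv_windows: dict[int, tuple[int, int, str, str]] = {}
    ins_reads: dict[int, int] = {}
    ins_bases: dict[int, str] = {}

    for site in sites:
        cut = site.cut_pos
        # terminus anchoring on each severed strand
        for gstrand in guide.nicked_strands(site.strand):
            want_rev = gstrand == "-"
            covering = ((is_rev == want_rev)
                        & (starts <= cut - 1) & (starts + lengths >= cut + 1))
            idx = np.flatnonzero(covering)
            sel = idx[rng_t.random(idx.size) < config.cleavage_fraction]
            if want_rev:
                starts[sel] = np.maximum(0, cut - lengths[sel])
                lengths[sel] = cut - starts[sel]
            else:
                lengths[sel] = np.minimum(lengths[sel], L - cut)
                starts[sel] = cut
        # base-editor conversions in window-spanning reads
        if guide.editor_mode in ("cbe", "abe"):
            a, b = _window_bounds(guide, site)
            src, dst = guide.conversion
            if site.strand == "-":
                src, dst = revcomp(src), revcomp(dst)
            spanning = (starts <= a) & (starts + lengths >= b)
            idx = np.flatnonzero(spanning)
            sel = idx[rng_t.random(idx.size) < config.conversion_fraction]
            for i in sel:
                conv_windows[int(i)] = (a, b, src, dst)
        # prime-editor insertion at +1 after the nick
        if guide.editor_mode == "pe":
            ins = guide.pe_insert if site.strand == "+" else revcomp(guide.pe_insert)
            spanning = (starts <= cut - 1) & (starts + lengths >= cut + 1)
            idx = np.flatnonzero(spanning)
            sel = idx[rng_t.random(idx.size) < config.insertion_fraction]
            for i in sel:
                ins_reads[int(i)] = cut
                ins_bases[int(i)] = ins

    treated = _emit_reads(genome, chrom, starts, lengths, is_rev,
                          conv_windows, ins_reads, ins_bases, "t")

    control: list[AlignedRead] = []
    if config.control_included:
        rng_c = _rng(config, 3)
        cs, cl, cr = _background_arrays(config, L, rng_c)
        cs, cl, cr = _add_hotspots(config, hot, cs, cl, cr, rng_c)
        control = _emit_reads(genome, chrom, cs, cl, cr, {}, {}, {}, "c")
    return treated, control


# ---------------------------------------------------------------------------
# convenience: one-call fixture generation


def simulate_dataset(config: SimConfig, guide: GuideSpec):
    """Genome + planted sites + (treated, control) reads in one call."""
    genome = simulate_genome(config)
    genome, sites = plant_sites(genome, guide, config)
    treated, control = simulate_reads(genome, sites, guide, config)
    return genome, sites, treated, control


def write_truth(sites: Sequence[PlantedSite], path) -> None:
    """Ground-truth TSV: chrom, cut_pos, strand, n_mismatches, bulge, fractions."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tcut_pos\tstrand\tn_mismatches\tbulge\ttarget_seq\t"
                 "cleavage\tconversion\tinsertion\n")
        for s in sites:
            f = s.signal_fractions
            fh.write(f"{s.chrom}\t{s.cut_pos}\t{s.strand_of_pam}\t{s.n_mismatches}\t"
                     f"{s.bulge}\t{s.target_seq}\t{f.get('cleavage', 0)}\t"
                     f"{f.get('conversion', 0)}\t{f.get('insertion', 0)}\n")
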