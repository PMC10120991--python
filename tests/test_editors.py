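"""Base-editor conversion ratios and prime-editor insertion fractions."""

import math

import pytest

from crossseq import (AlignedRead, CleavageSite, ConfigError, GenomeIndex,
                      GuideSpec, SimConfig, build_end_pileup, conversion_ratio,
                      insertion_fraction, score_site_by_mode, simulate_dataset)
from crossseq.guides import revcomp
from crossseq.io import OP_MATCH, OP_INS

SPACER = "GACTGACTGACTGACTGACT"


def _locus(strand="+", cut_pos=117, chrom="sim1"):
    return CleavageSite(chrom=chrom, cut_pos=cut_pos, cross_score=0,
                        end_count_fwd=0, end_count_rev=0, local_depth=0,
                        control_score=0, strand=strand)


def _genome_with_site(strand="+"):
    """Protospacer+PAM planted at [100, 123) of a fixed background."""
    bg = ("T" * 100) + "N" * 23 + ("T" * 127)
    site_seq = SPACER + "AGG"
    insert = site_seq if strand == "+" else revcomp(site_seq)
    return GenomeIndex({"sim1": bg[:100] + insert + bg[123:]})


def _read_from(genome, start, length, strand="+", edits=None, ins=None):
    """A read matching the reference except for point edits / one insertion."""
    seq = list(genome.fetch("sim1", start, start + length))
    for pos, base in (edits or {}).items():
        seq[pos - start] = base
    if ins is None:
        return AlignedRead("sim1", start, start + length, strand,
                           ((OP_MATCH, length),), "".join(seq))
    boundary, bases = ins
    q = "".join(seq[:boundary - start]) + bases + "".join(seq[boundary - start:])
    cigar = ((OP_MATCH, boundary - start), (OP_INS, len(bases)),
             (OP_MATCH, start + length - boundary))
    return AlignedRead("sim1", start, start + length, strand, cigar, q)


class TestConversionRatio:
    def test_no_spanning_reads_gives_missing_ratio(self):
        guide = GuideSpec(SPACER, editor_mode="cbe")
        genome = _genome_with_site()
        sig = conversion_ratio([], genome, _locus("+"), guide)
        assert sig.n_spanning == 0 and sig.ratio is None

    def test_counted_fraction_on_constructed_reads(self):
        """5 of 20 window-spanning reads carrying C->T at protospacer
        position 7 -> ratio 0.25."""
        guide = GuideSpec(SPACER, editor_mode="cbe")
        genome = _genome_with_site("+")
        site = _locus("+", cut_pos=117)
        pos7 = guide.genomic_pos(117, "+", 7)         # a spacer C position
        assert genome.fetch("sim1", pos7, pos7 + 1) == "C"
        reads = [_read_from(genome, 60, 80, edits={pos7: "T"} if i < 5 else None)
                 for i in range(20)]
        sig = conversion_ratio(reads, genome, site, guide)
        assert (sig.n_spanning, sig.n_signal) == (20, 5)
        assert sig.ratio == pytest.approx(0.25)
        assert sig.per_position[7] == 5
        assert sig.per_position[4] == 0

    def test_other_mismatches_are_not_signal(self):
        guide = GuideSpec(SPACER, editor_mode="cbe")
        genome = _genome_with_site("+")
        pos7 = guide.genomic_pos(117, "+", 7)
        reads = [_read_from(genome, 60, 80, edits={pos7: "G"})]  # C->G, not C->T
        sig = conversion_ratio(reads, genome, _locus("+"), guide)
        assert sig.n_signal == 0 and sig.n_spanning == 1

    def test_minus_site_counts_complement_conversion(self):
        """On a - oriented site, C->T on the non-target strand appears as
        G->A in the forward-strand read and must count as signal."""
        guide = GuideSpec(SPACER, editor_mode="cbe")
        genome = _genome_with_site("-")
        site = _locus("-", cut_pos=106)
        pos7 = guide.genomic_pos(106, "-", 7)
        assert genome.fetch("sim1", pos7, pos7 + 1) == "G"
        reads = [_read_from(genome, 60, 80, edits={pos7: "A"}),
                 _read_from(genome, 60, 80)]
        sig = conversion_ratio(reads, genome, site, guide)
        assert (sig.n_spanning, sig.n_signal) == (2, 1)
        assert sig.per_position[7] == 1

    def test_strand_involution(self):
        """Complementing genome and reads and flipping site orientation
        leaves the ratio unchanged."""
        guide = GuideSpec(SPACER, editor_mode="abe")
        genome = _genome_with_site("+")
        site = _locus("+", cut_pos=117)
        posA = guide.genomic_pos(117, "+", 2)  # spacer pos 2 is 'A'
        reads = [_read_from(genome, 60, 80, edits={posA: "G"}),
                 _read_from(genome, 60, 80)]
        sig = conversion_ratio(reads, genome, site, guide)

        L = genome.length("sim1")
        flipped = GenomeIndex({"sim1": revcomp(genome.fetch("sim1", 0, L))})
        fsite = _locus("-", cut_pos=L - 117)
        freads = [AlignedRead("sim1", L - r.end, L - r.start,
                              "-" if r.strand == "+" else "+",
                              tuple(reversed(r.cigar)), revcomp(r.query_seq))
                  for r in reads]
        fsig = conversion_ratio(freads, flipped, fsite, guide)
        assert (fsig.n_spanning, fsig.n_signal) == (sig.n_spanning, sig.n_signal)

    def test_orientation_required(self):
        guide = GuideSpec(SPACER, editor_mode="cbe")
        with pytest.raises(ValueError, match="orientation"):
            conversion_ratio([], _genome_with_site(), _locus(strand=None), guide)

    def test_mode_mismatch_raises(self):
        with pytest.raises(ConfigError):
            conversion_ratio([], _genome_with_site(), _locus(),
                             GuideSpec(SPACER))  # nuclease guide


class TestInsertionFraction:
    guide = GuideSpec(SPACER, editor_mode="pe", pe_insert="CTT")

    def test_no_insertions_gives_zero(self):
        genome = _genome_with_site("+")
        reads = [_read_from(genome, 60, 80) for _ in range(10)]
        sig = insertion_fraction(reads, _locus("+"), self.guide)
        assert sig.ratio == 0.0 and sig.n_spanning == 10

    def test_counted_fraction(self):
        """7 of 10 nick-spanning reads with a +1 CTT insertion -> 0.7."""
        genome = _genome_with_site("+")
        reads = [_read_from(genome, 60, 80,
                            ins=(117, "CTT") if i < 7 else None)
                 for i in range(10)]
        sig = insertion_fraction(reads, _locus("+", 117), self.guide)
        assert (sig.n_spanning, sig.n_signal) == (10, 7)
        assert sig.ratio == pytest.approx(0.7)

    def test_wrong_bases_not_signal(self):
        genome = _genome_with_site("+")
        reads = [_read_from(genome, 60, 80, ins=(117, "CTA"))]
        assert insertion_fraction(reads, _locus("+", 117),
                                  self.guide).n_signal == 0

    def test_permuted_insert_spec_yields_zero_on_original_reads(self):
        genome = _genome_with_site("+")
        reads = [_read_from(genome, 60, 80, ins=(117, "CTT"))]
        permuted = GuideSpec(SPACER, editor_mode="pe", pe_insert="TTC")
        assert insertion_fraction(reads, _locus("+", 117),
                                  permuted).n_signal == 0

    def test_placement_must_be_exact_unless_tolerant(self):
        genome = _genome_with_site("+")
        reads = [_read_from(genome, 60, 80, ins=(118, "CTT"))]
        site = _locus("+", 117)
        assert insertion_fraction(reads, site, self.guide).n_signal == 0
        assert insertion_fraction(reads, site, self.guide,
                                  tolerance=1).n_signal == 1

    def test_minus_site_insert_is_reverse_complemented(self):
        genome = _genome_with_site("-")
        site = _locus("-", cut_pos=106)
        reads = [_read_from(genome, 60, 80, ins=(106, "AAG"))]  # rc(CTT)
        assert insertion_fraction(reads, site, self.guide).n_signal == 1

    def test_nuclease_guide_rejected(self):
        with pytest.raises(ConfigError):
            insertion_fraction([], _locus("+"), GuideSpec(SPACER))


class TestScoreSiteByMode:
    def test_mode_dispatch_and_error(self, small_dataset):
        _, genome, sites, treated, _ = small_dataset
        pileup = build_end_pileup(treated, genome)
        nuc = score_site_by_mode(sites[0], pileup, treated, genome,
                                 GuideSpec(SPACER))
        assert nuc.mode == "nuclease" and nuc.editing is None
        with pytest.raises(ConfigError):
            conversion_ratio(treated, genome, sites[0], GuideSpec(SPACER))

    def test_planted_abe_ratio_within_three_sds(self):
        guide = GuideSpec(SPACER, editor_mode="abe")
        cfg = SimConfig(seed=30, genome_length=10_000, mean_depth=200,
                        n_offtargets=0, planted_bulges=0,
                        conversion_fraction=0.3)
        genome, sites, treated, control = simulate_dataset(cfg, guide)
        pileup = build_end_pileup(treated, genome)
        rec = score_site_by_mode(sites[0], pileup, treated, genome, guide)
        sig = rec.editing
        p = cfg.conversion_fraction
        sd = math.sqrt(p * (1 - p) / sig.n_spanning)
        assert abs(sig.ratio - p) <= 3 * sd
        assert rec.candidate
        # matched control locus: no conversions were simulated there
        csig = conversion_ratio(control, genome, sites[0], guide)
        assert csig.n_signal == 0
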