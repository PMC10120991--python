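# Methods

## Problem and model

CRISPR editors (Cas9 nuclease, cytosine/adenine base editors, prime
editors) recognize their targets through an R-loop: the guide RNA pairs
with one DNA strand and the other — the non-target strand, which reads
the same as the spacer and carries the PAM — is displaced as single-
stranded DNA. Enrichment sequencing of that ssDNA concentrates reads
around every locus the editor engaged, on- or off-target. `crossseq`
implements the downstream computation: it starts from aligned reads and
calls, scores and annotates the engaged loci.

The signal exploited is a read-terminus property. When a duplex is cut
between positions `cut_pos − 1` and `cut_pos` (0-based; SpCas9 cuts
bluntly 3 bp 5′ of the PAM, between protospacer positions 17 and 18),
the fragments released have fixed ends: forward-strand reads of the
right-hand fragment begin exactly at `cut_pos`, and reverse-strand reads
of the left-hand fragment end exactly at `cut_pos − 1`. With

* `F` = forward read starts at `cut_pos`,
* `R` = reverse read ends at `cut_pos − 1`,
* `N` = mapped reads in the library,

the CROSS score of a position is the library-normalized cleavage-signal
read count

```
CROSS(cut_pos) = 1e6 · (F + R) / N        [reads per million]
```

Alongside the score we keep the local end fraction
`f = (F + R) / D`, where `D` is the strand-aware coverage flanking the
scissile bond — forward depth at `cut_pos` plus reverse depth at
`cut_pos − 1` — so each fragment is counted at the position where its
terminus is informative and `f ∈ [0, 1]`. The score ranks sites across a
library; the fraction separates a genuine end stack from mere deep
coverage. Soft-clipped bases never move a terminus: the terminus is the
first/last reference-aligned base.

### Candidate gates

A position is a candidate cleavage site when all of these hold
(defaults in parentheses; all config-exposed):

1. **End support** — `F ≥ m` and `R ≥ m` (`m = 3`). For nickase-based
   editors only one strand is severed, so the gate relaxes to
   `max(F, R) ≥ m` and the fraction gate uses the better per-strand
   truncation fraction `max(F/D₊, R/D₋)` instead of the diluted joint
   `f`.
2. **End fraction** — `f ≥ f_min` (`f_min = 0.2`).
3. **Control test** — the no-guide control has at most `c_max = 1` end
   reads at the position, or the treated score exceeds the control
   score `ratio_min = 5`-fold. The no-guide control is integral: it is
   what removes endogenous ssDNA regions (replication/transcription
   bubbles, fragile loci) that enrich identically in both libraries.
4. Candidates within `merge_window = 10` bp are merged keeping the
   max-score position (repair and resection blur ends by a few bases
   in cellular data); ranking is dense, by descending score, ties
   broken by coordinate.

The exact published formula and cutoffs for this score are not public;
the definition above is this package's declared reconstruction in the
spirit of cleavage-score methods that count read ends at candidate cuts
under depth normalization. Acceptance of the implementation is
therefore property-based (oracle equivalence, planted-signal recovery,
null calibration), not a reproduction of any published site list.

### Editor-specific signatures

* **CBE/ABE** — the nickase (D10A) cuts the target strand, giving a
  one-sided truncation signature, and the deaminase converts bases in
  an editing window (default protospacer positions 4–8, PAM-distal
  = 1). The editing read-out is the ratio of window-spanning reads that
  carry ≥ 1 reference-mismatching base equal to the conversion product
  (C→T for CBE, A→G for ABE) in the non-target-strand orientation of
  the site; a read counts once regardless of how many window positions
  are converted, with per-position counts reported separately. Reads
  carrying only other mismatches are not signal. Candidacy requires
  ratio ≥ `r_min` (default 0.01).
* **PE** — the nickase (H840A) cuts the non-target strand and the
  programmed edit is written starting at position +1, the first
  nucleotide following the nick. Signal is a CIGAR insertion whose
  reference placement is exactly the nick boundary and whose bases
  equal the programmed insert (orientation-resolved); a placement
  tolerance (default 0 bp) is available for repair-shifted insertions.

### Guide matching

Candidates are explained, not pre-enumerated: each called locus is
aligned to the spacer allowing substitutions and at most one
single-base bulge. A DNA bulge is an extra unpaired target base
(protospacer one base longer); an sgRNA bulge leaves a guide base
unpaired (one base shorter). The search evaluates, at every valid PAM
placement in both orientations, the ungapped alignment and every
single-base bulge placement, and minimizes `(bulge_count, mismatches)`
lexicographically over the admissible set (`mismatches ≤ max_mm = 6`,
`bulges ≤ max_bulge = 1`); ties prefer the most PAM-proximal bulge,
then the forward orientation. Bulges are penalized before mismatches
because bulged engagement is the rarer, weaker binding mode. Loci with
no admissible alignment are reported unmatched rather than dropped, so
guide-independent background stays visible.

Consensus matrices over called sites project each target onto spacer
coordinates (DNA-bulge base dropped, sgRNA-bulge position left as a
gap contributing nothing to its column) and report per-column base
frequencies plus information content `2 − H` bits, no pseudocounts and
no background correction — the numbers behind a standard sequence logo.

The guanine check counts G on the displaced (non-target) strand, which
is the substrate of guanine-reactive ssDNA labeling; a site with zero G
there is flagged as invisible to the assay regardless of engagement.

## Simulator

The simulator generates the study conditions end-to-end so every stage
is testable offline; defaults are one 100-kb contig, GC 0.41
(mammalian-like), single-end 100-nt reads at 200× background depth, one
exact on-target plus 5 off-targets carrying 2–4 substitutions (uniform
over spacer positions, or confined to the PAM-distal half for
consensus experiments) with one single-base bulge, alternating
strands, placed ≥ 300 bp apart and away from contig ends.

Background endogenous ssDNA is uniform read placement; 1% of background
reads (`background_end_rate`) suffer a random internal truncation so
that background termini land at arbitrary positions. Optional hotspots
— loci where end-stacked reads appear identically in treated and
control — make the control subtraction non-trivial. Signal is planted
by re-anchoring: each read covering a planted cut on a severed strand
is, with probability `cleavage_fraction` (default 0.3), truncated so
its terminus sits exactly at the cut. This keeps read totals equal to
the background budget and makes the empirical end fraction an unbiased
binomial estimate of the planted fraction, which the recovery tests
check to 3 binomial SDs. Conversions are substituted into
window-spanning reads and insertions written as CIGAR `I` operations
with the same Bernoulli logic. Everything derives from one integer
seed through independent named streams, so identical configurations
are byte-identical.

Deliberately not modeled: sequencing errors and base qualities, PCR
duplicates, paired-end geometry, mapping ambiguity, structured
(non-uniform) endogenous ssDNA domains, and chromatin accessibility.
Consequently, passing tests demonstrate correctness of the scoring,
gating, subtraction and annotation logic under clean alignments — not
robustness to mapping artifacts or error-rich reads, which real
libraries would add on top.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally and in BED;
  1-based numbering appears only in rendered alignments and logo rows.
* `min_mapq` default 20; duplicates kept by default (`--dedup` to
  collapse) since enrichment legitimately produces identical fragments.
* Library-size (RPM) normalization is the headline scale because the
  score is a per-library screening statistic; per-locus end fraction is
  deliberately a gate, not the score.
* Degenerate inputs: empty read sets give all-zero pileups and empty
  candidate lists; `cut_pos = 0` scores with `R = 0` and an `edge`
  flag; zero spanning reads give a missing (not zero) editing ratio;
  zero-depth positions give fraction 0.
* Problem sizes in tests and the acceptance script (10-kb genomes for
  oracle checks, 100-kb for recovery, 10–20 seeds per property) were
  chosen so each property is measured at binomial SDs small enough to
  be decisive while the whole suite stays desk-scale.

## Known limitations

* The score reconstruction above may differ in constants from the
  original supplementary definition; all gates are config-exposed for
  recalibration against real libraries.
* Bidirectional end support assumes clean double-strand cuts; cellular
  nuclease data with extensive resection may need the unidirectional
  gate plus a wider merge window.
* The bulge search considers at most one bulge; multi-bulge engagement
  is reported as unmatched.
* Conversion calling attributes any window conversion to editing; in
  real data SNVs and sequencing errors require the matched control
  comparison (provided) and ideally an error model (not provided).
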