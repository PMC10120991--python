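"""Guide specification and cut-site geometry.

A CRISPR editor is described by a :class:`GuideSpec`: the spacer sequence
(written 5'->3' as DNA), the PAM pattern it requires, where the enzyme cuts
relative to the PAM, and the editor chemistry (nuclease, cytosine/adenine
base editor, or prime editor).

Coordinate conventions used throughout the package:

* All genomic coordinates are 0-based, half-open.
* A *site* is oriented by the strand carrying the protospacer (the
  non-target strand, which reads the same as the spacer and carries the
  PAM).  ``strand='+'`` means protospacer and PAM lie on the forward
  strand with the PAM 3' (rightward) of the protospacer.
* ``cut_pos`` is the 0-based coordinate of the base immediately 3' of the
  scissile phosphate on the forward strand: the duplex is cut between
  ``cut_pos - 1`` and ``cut_pos``.  For SpCas9 (blunt cut 3 bp 5' of the
  PAM) on a '+' site with a 20-nt spacer, ``cut_pos`` is the coordinate of
  protospacer position 18.
* Protospacer positions are 1-based with position 1 at the PAM-distal end,
  the numbering used for base-editor editing windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                           "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

#: IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

EDITOR_MODES = ("nuclease", "cbe", "abe", "pe")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` (equal lengths)."""
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern.upper(), seq.upper()):
        allowed = IUPAC.get(p)
        if allowed is None:
            raise ValueError(f"invalid IUPAC symbol {p!r} in pattern")
        if s not in allowed:
            return False
    return True


class ConfigError(ValueError):
    """Raised for invalid guide or simulation configuration."""


@dataclass(frozen=True)
class GuideSpec:
    """Spacer / PAM / editor-mode bundle that drives every scorer.

    Parameters
    ----------
    spacer
        Protospacer-matching guide segment, 5'->3', DNA alphabet,
        15-25 nt (20 nt for SpCas9 guides).
    pam
        PAM pattern in IUPAC codes, 3' of the protospacer (``NGG``).
    cut_offset
        Signed offset of the cut from the PAM-proximal spacer end; -3 is
        the canonical SpCas9 blunt cut between protospacer positions 17
        and 18.
    editor_mode
        One of ``nuclease``, ``cbe``, ``abe``, ``pe``.
    editing_window
        Inclusive protospacer position range (PAM-distal = 1) where base
        editors deaminate; default 4-8.
    conversion
        ``(ref, alt)`` observed on the non-target strand; inferred from
        the mode when omitted (C->T for CBE, A->G for ABE).
    pe_insert
        Programmed insertion written at position +1 after the pegRNA nick
        (prime editing only), e.g. ``CTT``.
    nick_strand
        Which strand the nickase cuts: ``target`` (D10A, base editors) or
        ``nontarget`` (H840A, prime editor); nucleases cut both.
    """

    spacer: str
    pam: str = "NGG"
    cut_offset: int = -3
    editor_mode: str = "nuclease"
    editing_window: tuple[int, int] = (4, 8)
    conversion: tuple[str, str] | None = None
    pe_insert: str = ""
    nick_strand: str | None = None

    def __post_init__(self):
        spacer = self.spacer.upper()
        object.__setattr__(self, "spacer", spacer)
        object.__setattr__(self, "pam", self.pam.upper())
        object.__setattr__(self, "pe_insert", self.pe_insert.upper())
        if not (15 <= len(spacer) <= 25):
            raise ConfigError(f"spacer length {len(spacer)} outside 15-25")
        if set(spacer) - set("ACGT"):
            raise ConfigError("spacer must be over A/C/G/T")
        for p in self.pam:
            if p not in IUPAC:
                raise ConfigError(f"invalid IUPAC symbol {p!r} in PAM")
        if self.editor_mode not in EDITOR_MODES:
            raise ConfigError(f"unknown editor_mode {self.editor_mode!r}")
        lo, hi = self.editing_window
        if not (1 <= lo <= hi <= len(spacer)):
            raise ConfigError("editing_window outside [1, spacer length]")
        if (self.editor_mode == "pe") != bool(self.pe_insert):
            raise ConfigError("pe_insert must be nonempty iff editor_mode='pe'")
        if self.conversion is None and self.editor_mode in ("cbe", "abe"):
            conv = ("C", "T") if self.editor_mode == "cbe" else ("A", "G")
            object.__setattr__(self, "conversion", conv)
        if self.nick_strand is None:
            default_nick = {"cbe": "target", "abe": "target", "pe": "nontarget"}
            object.__setattr__(self, "nick_strand",
                               default_nick.get(self.editor_mode, "both"))
        if self.nick_strand not in ("target", "nontarget", "both"):
            raise ConfigError(f"unknown nick_strand {self.nick_strand!r}")

    # ---- geometry -------------------------------------------------------

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)

    def protospacer_start(self, cut_pos: int, strand: str) -> int:
        """Forward-strand coordinate of the leftmost protospacer base."""
        if strand == "+":
            return cut_pos - self.spacer_len - self.cut_offset
        return cut_pos + self.cut_offset

    def cut_pos_from_protospacer(self, proto_start: int, strand: str) -> int:
        """Inverse of :meth:`protospacer_start`."""
        if strand == "+":
            return proto_start + self.spacer_len + self.cut_offset
        return proto_start - self.cut_offset

    def site_span(self, cut_pos: int, strand: str) -> tuple[int, int]:
        """Forward-strand half-open interval covering protospacer + PAM."""
        p = self.protospacer_start(cut_pos, strand)
        if strand == "+":
            return p, p + self.spacer_len + len(self.pam)
        return p - len(self.pam), p + self.spacer_len

    def genomic_pos(self, cut_pos: int, strand: str, proto_position: int) -> int:
        """Forward-strand coordinate of 1-based protospacer ``proto_position``
        (PAM-distal = 1)."""
        p = self.protospacer_start(cut_pos, strand)
        if strand == "+":
            return p + proto_position - 1
        return p + self.spacer_len - proto_position

    def window_span(self, cut_pos: int, strand: str) -> tuple[int, int]:
        """Half-open forward-strand interval of the editing window."""
        lo, hi = self.editing_window
        a = self.genomic_pos(cut_pos, strand, lo)
        b = self.genomic_pos(cut_pos, strand, hi)
        return (min(a, b), max(a, b) + 1)

    def nicked_strands(self, site_strand: str) -> tuple[str, ...]:
        """Genomic strands severed at the cut for a site on ``site_strand``.

        The target strand (paired with the gRNA) is the opposite of the
        site strand; the non-target (displaced) strand is the site strand.
        """
        other = "-" if site_strand == "+" else "+"
        if self.nick_strand == "both":
            return (site_strand, other)
        if self.nick_strand == "target":
            return (other,)
        return (site_strand,)
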