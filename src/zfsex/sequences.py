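"""In-silico representation of the Zinc-Finger sexing assay.

The assay is a single primer pair flanking a 74 bp amplicon of the
Zinc-Finger gene (single-copy, present on both X and Y), plus two 13 nt
allele-specific MGB TaqMan probes (ZFX / ZFY) that differ at two positions.
Specificity against non-elephantid DNA rests on the final 3' base of the
forward primer, a 'G' fixed across elephantine taxa but an 'A' in most
other mammals (including humans), and on the single-mismatch intolerance
of MGB probes.

This module provides exact-string genomics only: 3'-anchored primer-site
scanning, amplicon extraction, and probe-binding prediction against
user-supplied reference panels.  No thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "AssayDefinition",
    "PrimingSite",
    "SpecificityRow",
    "hamming_distance",
    "find_priming_site",
    "extract_amplicon",
    "specificity_screen",
    "read_reference_panel",
    "DEFAULT_ASSAY",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC ambiguity codes -> set of concrete bases they stand for
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_STRICT_ALPHABET = frozenset("ACGT")
_AMBIG_ALPHABET = frozenset(IUPAC)


class SequenceError(ValueError):
    """Invalid nucleotide sequence."""


class AmbiguousTemplateError(ValueError):
    """More than one qualifying primer-site pair on a template."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            f"ambiguous template: {len(self.candidates)} qualifying "
            f"forward/reverse site pairs: {self.candidates}"
        )


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase DNA string.

    Primers and probes must be strict A/C/G/T; references may carry IUPAC
    ambiguity codes (``allow_ambiguity=True``).
    """

    bases: str
    allow_ambiguity: bool = False

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if not bases:
            raise SequenceError("empty sequence")
        alphabet = _AMBIG_ALPHABET if self.allow_ambiguity else _STRICT_ALPHABET
        bad = set(bases) - alphabet
        if bad:
            raise SequenceError(
                f"illegal characters {sorted(bad)} for "
                f"{'ambiguous' if self.allow_ambiguity else 'strict'} alphabet"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def reverse_complement(self) -> "NucleotideSequence":
        rc = self.bases.translate(_COMPLEMENT)[::-1]
        return NucleotideSequence(rc, allow_ambiguity=self.allow_ambiguity)


@dataclass(frozen=True)
class AssayDefinition:
    """Primer pair + two dye-labelled allele-specific probes.

    Both primers are given 5'->3'.  The forward primer matches the plus
    strand; the reverse primer anneals to the plus strand's complement.
    """

    forward_primer: NucleotideSequence
    reverse_primer: NucleotideSequence
    probe_x: NucleotideSequence
    probe_y: NucleotideSequence
    dye_x: str = "VIC"
    dye_y: str = "FAM"
    name: str = "ZF-sexing"

    def __post_init__(self) -> None:
        if len(self.probe_x) != len(self.probe_y):
            raise ValueError("allele probes must have equal length")
        if self.dye_x == self.dye_y:
            raise ValueError("probe dye labels must differ")


#: The published Zinc-Finger sexing assay: 23 nt forward / 21 nt reverse
#: primers and the two 13 nt MGB probes (X allele on VIC, Y allele on FAM).
DEFAULT_ASSAY = AssayDefinition(
    forward_primer=NucleotideSequence("ACAAAATGGTGCATAAGGAAAAG"),
    reverse_primer=NucleotideSequence("CTCAGCTGTCTCGTATTCACA"),
    probe_x=NucleotideSequence("AGCCAACAAAATG"),
    probe_y=NucleotideSequence("ATCCAGCAAAATG"),
)


def hamming_distance(a: NucleotideSequence | str, b: NucleotideSequence | str) -> int:
    """Count of differing positions between two equal-length sequences."""
    sa, sb = str(a), str(b)
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


def _bases_compatible(primer_base: str, ref_base: str) -> bool:
    """A primer base matches any reference base whose IUPAC set contains it."""
    return primer_base in IUPAC.get(ref_base, ())


@dataclass(frozen=True)
class PrimingSite:
    """One candidate primer annealing site on a reference.

    position/strand describe the primer footprint as a 0-based half-open
    interval [position, position+len(primer)) on the plus strand.  On '+'
    the primer 3' end sits at the interval's right edge, on '-' at its left
    edge.  ``terminal_match`` reports whether the very last 3' base matches;
    ``qualifies`` whether the site passed both the mismatch budget and the
    exact 3'-anchor requirement.
    """

    position: int
    strand: str  # '+' or '-'
    mismatches: int
    terminal_match: bool
    qualifies: bool


def _scan_one_strand(
    ref: str, primer: str, max_mismatches: int, anchor: int, strand: str
) -> Iterator[PrimingSite]:
    # On '-' we slide the reverse complement of the primer along the plus
    # strand; its 3' terminus then maps to the window's first position.
    probe = (
        primer
        if strand == "+"
        else primer.translate(_COMPLEMENT)[::-1]
    )
    L = len(probe)
    anchor_idx = (
        range(L - anchor, L) if strand == "+" else range(anchor - 1, -1, -1)
    )
    term_idx = L - 1 if strand == "+" else 0
    for pos in range(len(ref) - L + 1):
        window = ref[pos : pos + L]
        mism = sum(
            not _bases_compatible(p, r) for p, r in zip(probe, window)
        )
        if mism > max_mismatches:
            continue
        anchor_ok = all(
            _bases_compatible(probe[i], window[i]) for i in anchor_idx
        )
        terminal = _bases_compatible(probe[term_idx], window[term_idx])
        yield PrimingSite(
            position=pos,
            strand=strand,
            mismatches=mism,
            terminal_match=terminal,
            qualifies=anchor_ok,
        )


def find_priming_site(
    reference: NucleotideSequence,
    primer: NucleotideSequence,
    max_mismatches: int = 2,
    anchor_3prime: int = 1,
) -> list[PrimingSite]:
    """Scan both strands of *reference* for annealing sites of *primer*.

    Returns every window within the mismatch budget; a site *qualifies*
    only if additionally its final ``anchor_3prime`` 3'-terminal bases match
    exactly.  The default single-base anchor encodes the assay's
    discriminating 3' 'G' of the forward primer.
    """
    ref, prm = str(reference), str(primer)
    if not ref:
        raise SequenceError("empty reference")
    if len(prm) > len(ref):
        raise SequenceError("primer longer than reference")
    sites = list(_scan_one_strand(ref, prm, max_mismatches, anchor_3prime, "+"))
    sites += list(_scan_one_strand(ref, prm, max_mismatches, anchor_3prime, "-"))
    return sites


def _qualifying(sites: Iterable[PrimingSite]) -> list[PrimingSite]:
    return [s for s in sites if s.qualifies]


def extract_amplicon(
    reference: NucleotideSequence,
    assay: AssayDefinition,
    max_mismatches: int = 2,
) -> Optional[tuple[NucleotideSequence, int]]:
    """Extract the PCR product delimited by the assay's primers.

    The amplicon runs from the forward primer's 5' end to the reverse
    primer's 5' end inclusive, so its length includes both primers (the
    published assay yields 74 bp).  Returns ``None`` when either primer has
    no qualifying site; raises :class:`AmbiguousTemplateError` when more
    than one convergent site pair qualifies.
    """
    fwd = _qualifying(find_priming_site(reference, assay.forward_primer, max_mismatches))
    rev = _qualifying(find_priming_site(reference, assay.reverse_primer, max_mismatches))
    if not fwd or not rev:
        return None
    lf, lr = len(assay.forward_primer), len(assay.reverse_primer)
    ref = str(reference)
    pairs = []
    for f in fwd:
        for r in rev:
            if f.strand == "+" and r.strand == "-" and f.position < r.position:
                # product on the plus strand
                pairs.append((f.position, r.position + lr, "+"))
            elif f.strand == "-" and r.strand == "+" and r.position < f.position:
                # product read off the minus strand
                pairs.append((r.position, f.position + lf, "-"))
    if not pairs:
        return None
    if len(pairs) > 1:
        raise AmbiguousTemplateError(pairs)
    start, end, strand = pairs[0]
    amp = NucleotideSequence(ref[start:end], allow_ambiguity=True)
    if strand == "-":
        amp = amp.reverse_complement()
    return amp, len(amp)


def _probe_binds(probe: NucleotideSequence, amplicon: NucleotideSequence) -> bool:
    """Exact-match binding only: MGB probes tolerate no mismatch, and
    ambiguity codes in the template never count as probe support."""
    amp = str(amplicon)
    for needle in (str(probe), str(probe.reverse_complement())):
        i = amp.find(needle)
        while i != -1:
            window = amp[i : i + len(needle)]
            if all(w in _STRICT_ALPHABET for w in window):
                return True
            i = amp.find(needle, i + 1)
    return False


@dataclass(frozen=True)
class SpecificityRow:
    taxon: str
    allele: str
    amplifiable: bool
    probe_x_binds: bool
    probe_y_binds: bool
    note: str = ""


def specificity_screen(
    assay: AssayDefinition,
    panel: list[tuple[str, str, NucleotideSequence]],
) -> list[SpecificityRow]:
    """Predict assay behaviour against a panel of reference sequences.

    A row is amplifiable when both primers have 3'-anchored qualifying
    sites in convergent orientation; each probe binds only on an exact
    occurrence within the amplicon.  A sequence can be amplifiable and yet
    yield no fluorescence when neither probe binds (the canid-ZFY case).
    """
    if not panel:
        raise ValueError("empty reference panel")
    rows = []
    for taxon, allele, ref in panel:
        try:
            hit = extract_amplicon(ref, assay)
        except AmbiguousTemplateError:
            rows.append(SpecificityRow(taxon, allele, True, False, False,
                                       note="ambiguous: multiple site pairs"))
            continue
        except SequenceError as exc:
            rows.append(SpecificityRow(taxon, allele, False, False, False,
                                       note=f"degenerate sequence: {exc}"))
            continue
        if hit is None:
            rows.append(SpecificityRow(taxon, allele, False, False, False))
            continue
        amp, _ = hit
        rows.append(SpecificityRow(
            taxon, allele, True,
            _probe_binds(assay.probe_x, amp),
            _probe_binds(assay.probe_y, amp),
        ))
    return rows


def read_reference_panel(path) -> list[tuple[str, str, NucleotideSequence]]:
    """Read a multi-FASTA reference panel.

    The description line is parsed as ``taxon|allele``; a missing ``|``
    leaves the allele field empty.
    """
    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.description.strip()
        taxon, _, allele = label.partition("|")
        panel.append((taxon.strip(), allele.strip(),
                      NucleotideSequence(str(rec.seq), allow_ambiguity=True)))
    return panel
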