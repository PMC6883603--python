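"""Reference checking and 1-based left-shift normalization of coordinates.

Representative coordinates use 1-based inclusive start/stop with trimmed
alleles: ``"-"`` marks the empty side of an indel, and an insertion spans its
two flanking bases (stop = start + 1). Many equivalent representations of an
indel exist inside repeats; the canonical one is the leftmost. Normalization
works on an internal untrimmed (allele-string) representation and converts to
the trimmed dialect at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import GenomicCoordinates, Violation
from .rules import make_violation


class CoordinateRangeError(ValueError):
    """Coordinates fall outside the reference contig."""


class DegenerateVariantError(ValueError):
    """Reference and variant alleles are identical (no-op variant)."""


@dataclass(frozen=True)
class ReferenceContig:
    """A named reference sequence, indexable by 1-based position."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("contig sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise CoordinateRangeError(
                f"position {position} outside contig {self.name} (1-{len(self.sequence)})"
            )
        return self.sequence[position - 1]

    def slice(self, start: int, stop: int) -> str:
        """Bases on the 1-based inclusive interval [start, stop]."""
        if start > stop:
            raise CoordinateRangeError(f"start {start} > stop {stop}")
        if not (1 <= start and stop <= len(self.sequence)):
            raise CoordinateRangeError(
                f"[{start},{stop}] outside contig {self.name} (1-{len(self.sequence)})"
            )
        return self.sequence[start - 1 : stop]


def load_fasta(path: str) -> dict[str, ReferenceContig]:
    """Whole-contig FASTA load; contig names are matched case-insensitively."""
    from Bio import SeqIO

    contigs: dict[str, ReferenceContig] = {}
    for record in SeqIO.parse(path, "fasta"):
        contigs[record.id.lower()] = ReferenceContig(record.id, str(record.seq))
    return contigs


def lookup_contig(contigs: dict[str, ReferenceContig], name: str) -> ReferenceContig:
    try:
        return contigs[name.lower()]
    except KeyError:
        raise CoordinateRangeError(f"unknown contig {name!r}") from None


@dataclass(frozen=True)
class NormalizationResult:
    normalized: GenomicCoordinates
    shifted_by: int
    trimmed: bool


def check_reference(
    coords: GenomicCoordinates, contig: ReferenceContig
) -> list[Violation]:
    """Verify the stated reference allele (or insertion span) against the contig."""
    ref = coords.reference_base
    entity = f"{coords.chromosome}:{coords.start}-{coords.stop}"
    out: list[Violation] = []
    if ref == "-":
        # insertion: alleles carry no reference bases; the span must bracket
        # the insertion point between two adjacent flanking bases
        contig.base(coords.start)
        contig.base(coords.stop)
        if coords.stop != coords.start + 1:
            out.append(
                make_violation(
                    "COORD_INSERTION_SPAN", entity,
                    f"insertion span [{coords.start},{coords.stop}] is not two flanking bases",
                )
            )
        return out
    observed = contig.slice(coords.start, coords.stop)
    if observed != ref.upper():
        out.append(
            make_violation(
                "COORD_REF_MISMATCH", entity,
                f"expected {ref!r} at [{coords.start},{coords.stop}], found {observed!r}",
            )
        )
    return out


def _to_internal(coords: GenomicCoordinates) -> tuple[int, str, str]:
    """Trimmed dialect -> (pos, ref, alt) where ref occupies [pos, pos+len-1].

    For insertions (ref ``"-"``) the inserted bases sit between start and stop,
    i.e. immediately before position start + 1.
    """
    ref = "" if coords.reference_base == "-" else coords.reference_base.upper()
    alt = "" if coords.variant_base == "-" else coords.variant_base.upper()
    pos = coords.start + 1 if not ref else coords.start
    return pos, ref, alt


def _from_internal(
    pos: int, ref: str, alt: str, template: GenomicCoordinates
) -> GenomicCoordinates:
    if ref:
        start, stop = pos, pos + len(ref) - 1
    else:
        start, stop = pos - 1, pos
    return GenomicCoordinates(
        chromosome=template.chromosome,
        start=start,
        stop=stop,
        reference_base=ref or "-",
        variant_base=alt or "-",
        reference_build=template.reference_build,
        representative_transcript=template.representative_transcript,
    )


def left_shift_normalize(
    coords: GenomicCoordinates, contig: ReferenceContig
) -> NormalizationResult:
    """Return the leftmost trimmed representation equivalent to ``coords``.

    Shared suffix bases are trimmed first, then shared prefix bases (advancing
    start); an empty-allele indel is then shifted left one base at a time while
    the preceding reference base matches the last base of the non-empty allele,
    re-trimming after each step. The result is idempotent and applies to the
    contig with an identical alternate sequence as the input.
    """
    pos, ref, alt = _to_internal(coords)
    original_ref, original_alt = ref, alt
    if ref and contig.slice(pos, pos + len(ref) - 1) != ref:
        raise ValueError(
            f"reference allele {ref!r} does not match contig at {pos}; "
            "run check_reference first"
        )
    if not 1 <= pos <= len(contig) + (0 if ref else 1):
        raise CoordinateRangeError(f"position {pos} outside contig {contig.name}")

    # right-trim shared suffix
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-trim shared prefix
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref and not alt:
        raise DegenerateVariantError("alleles are identical after trimming")

    # left shift a pure insertion/deletion through matching upstream bases;
    # an insertion keeps pos >= 2 so a flanking start base remains expressible
    is_insertion = not ref
    while not ref or not alt:
        moving = ref or alt
        min_pos = 3 if is_insertion else 2
        if pos < min_pos or contig.base(pos - 1) != moving[-1]:
            break
        prev = contig.base(pos - 1)
        ref, alt = prev + ref, prev + alt
        pos -= 1
        while ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]

    normalized = _from_internal(pos, ref, alt, coords)
    trimmed = (ref != original_ref) or (alt != original_alt)
    shifted_by = coords.start - normalized.start
    return NormalizationResult(
        normalized=normalized, shifted_by=max(shifted_by, 0), trimmed=trimmed
    )


def apply_variant(contig: ReferenceContig, coords: GenomicCoordinates) -> str:
    """Alternate sequence produced by applying the variant to the contig.

    Independent of normalization; equal outputs mean equivalent representations.
    """
    pos, ref, alt = _to_internal(coords)
    seq = contig.sequence
    left = seq[: pos - 1]
    right = seq[pos - 1 + len(ref) :]
    if ref and seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(f"reference allele {ref!r} absent at position {pos}")
    return left + alt + right
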