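"""Exon-aware conversion of peptide (amino-acid) coordinates to genomic
coordinates.

Amino acid ``i`` of a transcript occupies coding-sequence nucleotides
``(i-1)*3 + 1`` through ``i*3`` (1-based, stop codon excluded).  Converting a
peptide range therefore means collecting those CDS nucleotides and reading
off their genomic positions, splitting wherever an intron interrupts the
CDS.  Codons are allowed to straddle exon boundaries; a domain may start and
end in different exons.

Reported endpoints follow transcript orientation: on the reverse strand the
reported start is numerically *larger* than the reported end.  Interval
queries downstream always normalise to (min, max).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from smdtools.genemodel import FORWARD, GenomicInterval, TranscriptModel, cds_blocks
from smdtools.pfam_io import DomainHit


class CoordinateError(ValueError):
    """Raised when an amino-acid range falls outside the peptide."""


@dataclass(frozen=True)
class DomainGenomicMapping:
    """Genomic footprint of one protein-domain occurrence.

    ``blocks`` are the exonic genomic intervals of the domain's coding
    nucleotides, in transcript (5'→3') order; their inclusive lengths sum to
    ``3 * (aa_end - aa_start + 1)``.
    """

    transcript_id: str
    domain_acc: str
    aa_start: int
    aa_end: int
    blocks: tuple[GenomicInterval, ...]
    reported_start: int
    reported_end: int
    strand: str

    def __post_init__(self) -> None:
        n_nt = sum(len(b) for b in self.blocks)
        expected = 3 * (self.aa_end - self.aa_start + 1)
        if n_nt != expected:
            raise ValueError(
                f"{self.transcript_id}/{self.domain_acc}: blocks cover {n_nt} nt "
                f"but aa {self.aa_start}-{self.aa_end} requires {expected}"
            )
        if self.strand == FORWARD and self.reported_start > self.reported_end:
            raise ValueError("forward-strand mapping with start > end")
        if self.strand != FORWARD and self.reported_start < self.reported_end:
            raise ValueError("reverse-strand mapping with start < end")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def family(self) -> str:
        """Accession without version suffix."""
        return self.domain_acc.split(".")[0]

    @property
    def aa_length(self) -> int:
        return self.aa_end - self.aa_start + 1


def peptide_to_genome(
    t: TranscriptModel, aa_start: int, aa_end: int, domain_acc: str = ""
) -> DomainGenomicMapping:
    """Convert the peptide range ``aa_start..aa_end`` (1-based, inclusive)
    on transcript ``t`` to genomic coordinates.

    Returns the exonic blocks in 5'→3' order plus the transcript-orientation
    endpoints: the genomic position of the first base of the ``aa_start``
    codon and of the last base of the ``aa_end`` codon.
    """
    if not (1 <= aa_start <= aa_end <= t.peptide_length):
        raise CoordinateError(
            f"amino-acid range {aa_start}-{aa_end} outside peptide of length "
            f"{t.peptide_length} on transcript {t.transcript_id}"
        )
    nt_lo = (aa_start - 1) * 3 + 1
    nt_hi = aa_end * 3
    blocks = _slice_blocks(cds_blocks(t), nt_lo, nt_hi)
    first = blocks[0]
    last = blocks[-1]
    if t.strand == FORWARD:
        reported_start, reported_end = first.start, last.end
    else:
        reported_start, reported_end = first.end, last.start
    return DomainGenomicMapping(
        transcript_id=t.transcript_id,
        domain_acc=domain_acc,
        aa_start=aa_start,
        aa_end=aa_end,
        blocks=tuple(blocks),
        reported_start=reported_start,
        reported_end=reported_end,
        strand=t.strand,
    )


def _slice_blocks(
    blocks: Sequence[GenomicInterval], nt_lo: int, nt_hi: int
) -> list[GenomicInterval]:
    """Extract transcript-coordinate nt range [nt_lo, nt_hi] from ordered
    coding blocks, preserving 5'→3' order and exon splits."""
    out: list[GenomicInterval] = []
    offset = 0
    for iv in blocks:
        n = len(iv)
        a = max(nt_lo, offset + 1)
        b = min(nt_hi, offset + n)
        if a <= b:
            if iv.strand == FORWARD:
                out.append(GenomicInterval(iv.chrom, iv.start + (a - offset - 1),
                                           iv.start + (b - offset - 1), iv.strand))
            else:
                out.append(GenomicInterval(iv.chrom, iv.end - (b - offset - 1),
                                           iv.end - (a - offset - 1), iv.strand))
        offset += n
    return out


def coding_length(m: DomainGenomicMapping) -> int:
    """Coding nucleotides covered by the mapping: the sum of inclusive block
    lengths, always ``3 ×`` the amino-acid count."""
    return sum(len(b) for b in m.blocks)


def genomic_span(
    m: DomainGenomicMapping,
    convention: Literal["inclusive", "subtraction"] = "inclusive",
) -> int:
    """Genomic extent of the mapping, introns included.

    ``"inclusive"`` counts every base from the minimum to the maximum block
    coordinate (``max - min + 1``).  ``"subtraction"`` returns the plain
    endpoint difference ``|reported_end - reported_start|``, one base
    shorter — the convention sometimes used when quoting a span as the
    difference of two printed positions.  Both are exposed so either style
    of printed value can be cross-checked.
    """
    lo = min(b.start for b in m.blocks)
    hi = max(b.end for b in m.blocks)
    if convention == "inclusive":
        return hi - lo + 1
    if convention == "subtraction":
        return abs(m.reported_end - m.reported_start)
    raise ValueError(f"unknown convention {convention!r}")


def intron_gap_total(m: DomainGenomicMapping) -> int:
    """Total intronic nucleotides between the mapping's blocks."""
    return genomic_span(m, "inclusive") - coding_length(m)


def batch_convert(
    models: Iterable[TranscriptModel],
    hits: Iterable[DomainHit],
    coords: Literal["alignment", "envelope"] = "alignment",
) -> tuple[list[DomainGenomicMapping], list[tuple[DomainHit, str]]]:
    """Convert every Pfam hit whose transcript is known and whose amino-acid
    range is valid; all other hits are enumerated in the skipped report with
    a reason code (``transcript_not_found`` or ``aa_out_of_range``).

    ``coords`` selects which PfamScan coordinate pair defines the domain
    boundary: the confidently aligned region (default) or the wider
    envelope.
    """
    by_id = {t.transcript_id: t for t in models}
    mappings: list[DomainGenomicMapping] = []
    skipped: list[tuple[DomainHit, str]] = []
    for hit in hits:
        t = by_id.get(hit.seq_id)
        if t is None:
            skipped.append((hit, "transcript_not_found"))
            continue
        if coords == "alignment":
            aa_start, aa_end = hit.aln_start, hit.aln_end
        else:
            aa_start, aa_end = hit.env_start, hit.env_end
        try:
            mappings.append(peptide_to_genome(t, aa_start, aa_end, hit.hmm_acc))
        except CoordinateError:
            skipped.append((hit, "aa_out_of_range"))
    return mappings, skipped


# ---------------------------------------------------------------------------
# Writers

def write_mapping_table(mappings: Iterable[DomainGenomicMapping], path: str) -> None:
    """Tab-separated mapping table: transcript id, Pfam accession, amino-acid
    range and transcript-orientation genomic endpoints."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tpfam_acc\taa_start\taa_end\tchrom\tchr_start\tchr_end\tstrand\n")
        for m in mappings:
            fh.write(
                f"{m.transcript_id}\t{m.domain_acc}\t{m.aa_start}\t{m.aa_end}\t"
                f"{m.chrom}\t{m.reported_start}\t{m.reported_end}\t{m.strand}\n"
            )


def write_bed12(mappings: Iterable[DomainGenomicMapping], path: str) -> None:
    """Write mappings as BED12 (0-based, half-open on disk); block starts and
    sizes encode the exonic blocks in ascending genomic order."""
    with open(path, "w") as fh:
        for m in mappings:
            blocks = sorted(m.blocks, key=lambda b: b.start)
            chrom_start = blocks[0].start - 1  # BED is 0-based half-open
            chrom_end = blocks[-1].end
            sizes = ",".join(str(len(b)) for b in blocks)
            starts = ",".join(str(b.start - 1 - chrom_start) for b in blocks)
            name = f"{m.transcript_id}|{m.domain_acc}|{m.aa_start}-{m.aa_end}"
            fh.write(
                f"{m.chrom}\t{chrom_start}\t{chrom_end}\t{name}\t0\t{m.strand}\t"
                f"{chrom_start}\t{chrom_end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def write_skip_report(skipped: Iterable[tuple[DomainHit, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\thmm_acc\treason\n")
        for hit, reason in skipped:
            fh.write(f"{hit.seq_id}\t{hit.hmm_acc}\t{reason}\n")
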