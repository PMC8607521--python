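"""Transcript gene models: exon/CDS structure parsed from Ensembl-dialect GTF
or built programmatically as fixtures.

Coordinates are 1-based and fully inclusive at both ends (Ensembl
convention); every length in this package is computed as ``end - start + 1``.
Strand is ``"+"`` (forward) or ``"-"`` (reverse).  On the reverse strand the
5'→3' reading order runs in *descending* genomic coordinates, so ordered
interval lists for reverse-strand transcripts have descending coordinates.

The stop codon is treated as the final three CDS nucleotides and is excluded
from the peptide length, keeping the 3-nucleotides-per-amino-acid arithmetic
exact.  Fixtures may declare a CDS without a stop codon via ``has_stop``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"
_STRANDS = (FORWARD, REVERSE)


class GeneModelError(ValueError):
    """Raised when a gene-model invariant is violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval. ``start <= end`` always; orientation is
    carried by ``strand``, never by coordinate order."""

    chrom: str
    start: int
    end: int
    strand: str = FORWARD

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GeneModelError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise GeneModelError(
                f"start {self.start} > end {self.end}; intervals are stored "
                "with start <= end regardless of strand"
            )
        if self.strand not in _STRANDS:
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Exon:
    """One exon with its 1-based rank in transcript (5'→3') order."""

    interval: GenomicInterval
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise GeneModelError(f"exon rank must be >= 1, got {self.rank}")


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript: exon structure plus CDS intervals.

    ``cds_intervals`` are held in transcript (5'→3') order and include the
    stop codon when ``has_stop`` is true.  ``peptide_length`` counts amino
    acids, excluding the stop.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    cds_intervals: tuple[GenomicInterval, ...]
    has_stop: bool = True
    peptide_length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise GeneModelError(f"{self.transcript_id}: transcript has no exons")
        if not self.cds_intervals:
            raise GeneModelError(f"{self.transcript_id}: transcript has no CDS")
        self._check_exons()
        self._check_cds()
        cds_nt = sum(len(iv) for iv in self.cds_intervals)
        coding_nt = cds_nt - 3 if self.has_stop else cds_nt
        if coding_nt <= 0 or coding_nt % 3 != 0:
            raise GeneModelError(
                f"{self.transcript_id}: coding length {coding_nt} nt is not a "
                "positive multiple of 3"
            )
        object.__setattr__(self, "peptide_length", coding_nt // 3)

    def _check_exons(self) -> None:
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(ranks) + 1)):
            raise GeneModelError(
                f"{self.transcript_id}: exon ranks {ranks} are not consecutive from 1"
            )
        ivs = sorted((e.interval for e in self.exons), key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end >= b.start:
                raise GeneModelError(
                    f"{self.transcript_id}: exons {a.start}-{a.end} and "
                    f"{b.start}-{b.end} overlap"
                )
        starts = [e.interval.start for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == FORWARD else starts == sorted(starts, reverse=True)
        if not ordered:
            raise GeneModelError(
                f"{self.transcript_id}: exon ranks do not follow {self.strand} "
                "strand genomic order"
            )

    def _check_cds(self) -> None:
        for iv in self.cds_intervals:
            if not any(e.interval.contains_interval(iv) for e in self.exons):
                raise GeneModelError(
                    f"{self.transcript_id}: CDS {iv.start}-{iv.end} is not "
                    "contained in any exon"
                )

    @property
    def cds_nt_length(self) -> int:
        """Total CDS length in nucleotides, including the stop codon if present."""
        return sum(len(iv) for iv in self.cds_intervals)


def cds_blocks(t: TranscriptModel) -> list[GenomicInterval]:
    """Ordered coding blocks of ``t`` in transcript (5'→3') orientation.

    The stop codon is trimmed, so the concatenated blocks have length
    exactly ``3 * t.peptide_length``; UTRs and introns are excluded by
    construction.  On the reverse strand the first block has the numerically
    largest coordinates.
    """
    blocks = list(t.cds_intervals)
    if t.has_stop:
        blocks = _trim_3prime(blocks, 3, t.strand)
    return blocks


def _trim_3prime(
    blocks: list[GenomicInterval], n: int, strand: str
) -> list[GenomicInterval]:
    """Remove the final ``n`` nucleotides (transcript orientation) from an
    ordered block list."""
    out: list[GenomicInterval] = []
    remaining = n
    for iv in reversed(blocks):
        if remaining == 0:
            out.append(iv)
            continue
        take = min(len(iv), remaining)
        remaining -= take
        if take < len(iv):
            if strand == FORWARD:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end - take, iv.strand))
            else:
                out.append(GenomicInterval(iv.chrom, iv.start + take, iv.end, iv.strand))
    if remaining:
        raise GeneModelError("CDS shorter than the stop codon")
    return list(reversed(out))


def build_fixture(
    chrom: str,
    strand: str,
    exon_intervals: Sequence[tuple[int, int]],
    cds_span: tuple[int, int],
    *,
    has_stop: bool = True,
    transcript_id: str = "TX1",
    gene_id: str = "G1",
) -> TranscriptModel:
    """Construct a :class:`TranscriptModel` from exon intervals and a
    transcript-relative CDS span.

    Parameters
    ----------
    exon_intervals
        ``(start, end)`` genomic pairs, disjoint; given in any order.
    cds_span
        1-based inclusive nucleotide range in *transcript* coordinates
        (5'→3' over the concatenated exons), including the stop codon when
        ``has_stop`` is true.
    """
    if strand not in _STRANDS:
        raise GeneModelError(f"strand must be '+' or '-', got {strand!r}")
    ivs = sorted(
        (GenomicInterval(chrom, s, e, strand) for s, e in exon_intervals),
        key=lambda iv: iv.start,
        reverse=(strand == REVERSE),
    )
    for a, b in zip(sorted(ivs, key=lambda iv: iv.start), sorted(ivs, key=lambda iv: iv.start)[1:]):
        if a.end >= b.start:
            raise GeneModelError(
                f"exon intervals ({a.start},{a.end}) and ({b.start},{b.end}) overlap"
            )
    exons = tuple(Exon(iv, rank) for rank, iv in enumerate(ivs, start=1))
    total = sum(len(iv) for iv in ivs)
    lo, hi = cds_span
    if not (1 <= lo <= hi <= total):
        raise GeneModelError(
            f"cds_span {cds_span} outside the concatenated exon length {total}"
        )
    cds = _transcript_span_to_genomic(ivs, strand, lo, hi)
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_intervals=tuple(cds),
        has_stop=has_stop,
    )


def _transcript_span_to_genomic(
    ordered_exons: Sequence[GenomicInterval],
    strand: str,
    lo: int,
    hi: int,
) -> list[GenomicInterval]:
    """Map a 1-based transcript-coordinate span onto genomic intervals,
    split at exon boundaries and returned in transcript order."""
    out: list[GenomicInterval] = []
    offset = 0  # transcript nt consumed so far
    for iv in ordered_exons:
        n = len(iv)
        a = max(lo, offset + 1)
        b = min(hi, offset + n)
        if a <= b:
            if strand == FORWARD:
                out.append(
                    GenomicInterval(iv.chrom, iv.start + (a - offset - 1), iv.start + (b - offset - 1), strand)
                )
            else:
                out.append(
                    GenomicInterval(iv.chrom, iv.end - (b - offset - 1), iv.end - (a - offset - 1), strand)
                )
        offset += n
    return out


# ---------------------------------------------------------------------------
# GTF input / output (Ensembl dialect)

_GTF_FIELDS = 9
_USED_FEATURES = {"exon", "CDS", "five_prime_utr", "three_prime_utr"}


def parse_gtf(path: str, dialect: str = "ensembl") -> list[TranscriptModel]:
    """Read transcript models from an Ensembl-dialect GTF file.

    One model is returned per transcript that carries at least one CDS (or
    UTR-derivable coding) interval and satisfies all model invariants;
    transcripts failing an invariant are skipped with a logged warning, as
    are malformed lines (reported with their line number).
    """
    if dialect != "ensembl":
        raise ValueError(f"unsupported GTF dialect: {dialect!r}")
    good_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != _GTF_FIELDS:
                logger.warning("%s:%d: malformed GTF line skipped", path, lineno)
                continue
            good_lines.append(line)
    db = gffutils.create_db(
        "".join(good_lines),
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict[str, list]] = {}
    meta: dict[str, dict[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in _USED_FEATURES:
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            logger.warning("%s: %s feature without transcript_id skipped", path, feat.featuretype)
            continue
        bucket = per_tx.setdefault(tid, {ft: [] for ft in _USED_FEATURES})
        bucket[feat.featuretype].append(feat)
        meta.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", ["unknown"])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
            },
        )
    models: list[TranscriptModel] = []
    for tid, bucket in per_tx.items():
        try:
            model = _assemble_transcript(tid, bucket, meta[tid])
        except GeneModelError as exc:
            logger.warning("%s: transcript %s skipped: %s", path, tid, exc)
            continue
        if model is not None:
            models.append(model)
    return models


def _assemble_transcript(
    tid: str, bucket: dict[str, list], info: dict[str, str]
) -> TranscriptModel | None:
    strand = info["strand"]
    if strand not in _STRANDS:
        raise GeneModelError(f"unsupported strand {strand!r}")
    chrom = info["chrom"]
    exon_feats = bucket["exon"]
    if not exon_feats:
        raise GeneModelError("no exon features")
    exon_ivs = sorted(
        (GenomicInterval(chrom, f.start, f.end, strand) for f in exon_feats),
        key=lambda iv: iv.start,
        reverse=(strand == REVERSE),
    )
    exons = tuple(Exon(iv, rank) for rank, iv in enumerate(exon_ivs, start=1))

    cds_ivs = [GenomicInterval(chrom, f.start, f.end, strand) for f in bucket["CDS"]]
    if not cds_ivs:
        utrs = [
            GenomicInterval(chrom, f.start, f.end, strand)
            for ft in ("five_prime_utr", "three_prime_utr")
            for f in bucket[ft]
        ]
        if not utrs:
            raise GeneModelError("no CDS feature (and no UTRs to derive one)")
        cds_ivs = _subtract_intervals([e.interval for e in exons], utrs, chrom, strand)
        if not cds_ivs:
            raise GeneModelError("UTRs cover every exon; no coding sequence")
    cds_ivs.sort(key=lambda iv: iv.start, reverse=(strand == REVERSE))
    return TranscriptModel(
        transcript_id=tid,
        gene_id=info["gene_id"],
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_intervals=tuple(cds_ivs),
    )


def _subtract_intervals(
    exons: Iterable[GenomicInterval],
    utrs: list[GenomicInterval],
    chrom: str,
    strand: str,
) -> list[GenomicInterval]:
    """Exonic intervals minus UTR intervals (all closed coordinates)."""
    out: list[GenomicInterval] = []
    for exon in exons:
        pieces = [(exon.start, exon.end)]
        for utr in utrs:
            nxt: list[tuple[int, int]] = []
            for s, e in pieces:
                if utr.end < s or utr.start > e:
                    nxt.append((s, e))
                    continue
                if utr.start > s:
                    nxt.append((s, utr.start - 1))
                if utr.end < e:
                    nxt.append((utr.end + 1, e))
            pieces = nxt
        out.extend(GenomicInterval(chrom, s, e, strand) for s, e in pieces)
    return out


def write_gtf(models: Iterable[TranscriptModel], path: str) -> None:
    """Serialize models to Ensembl-dialect GTF (exon + CDS features).

    The CDS features cover the model's full ``cds_intervals`` (stop codon
    included when present), so :func:`parse_gtf` round-trips the model.
    """
    with open(path, "w") as fh:
        fh.write("#!genome-version synthetic\n")
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for exon in t.exons:
                fh.write(
                    _gtf_line(t.chrom, "exon", exon.interval.start, exon.interval.end,
                              t.strand, attrs + f' exon_number "{exon.rank}";')
                )
            for iv in sorted(t.cds_intervals, key=lambda iv: iv.start):
                fh.write(_gtf_line(t.chrom, "CDS", iv.start, iv.end, t.strand, attrs))


def _gtf_line(chrom: str, feature: str, start: int, end: int, strand: str, attrs: str) -> str:
    return "\t".join(
        [chrom, "smdtools", feature, str(start), str(end), ".", strand, ".", attrs]
    ) + "\n"


def transcripts_per_gene(n_transcripts: int, n_genes: int) -> float:
    """Mean transcripts per gene, truncated (not rounded) to two decimals.

    Truncation matches how ratio statistics are conventionally printed in
    annotation summaries (e.g. 73311 transcripts over 15096 genes → 4.85).
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return (100 * n_transcripts // n_genes) / 100
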