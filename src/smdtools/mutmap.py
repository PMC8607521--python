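"""Map COSMIC-style somatic mutations onto protein-domain genomic blocks.

A mutation "maps" to a domain when its genomic anchor position falls inside
one of the domain's exonic coding blocks — never in an intron gap between
blocks, consistent with the exclusion of intronic mutations from the input.
Counting is per (record, Pfam family): a mutation covered by several isoform
mappings of the same family counts once for that family, so isoform
redundancy does not inflate counts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from smdtools.coordmap import DomainGenomicMapping

logger = logging.getLogger(__name__)

#: Mutation classes retained for domain mapping.
INCLUDED_TYPES = frozenset({"nonsense", "missense", "coding_silent", "complex"})
#: Classes excluded: events outside coding domains or without usable detail.
EXCLUDED_TYPES = frozenset({"intronic", "unknown", "other"})

#: Regex patterns (case-insensitive) classifying COSMIC mutation
#: descriptions; first match wins, no match → "other".
DEFAULT_TYPE_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"nonsense", "nonsense"),
    (r"missense", "missense"),
    (r"coding silent|synonymous", "coding_silent"),
    (r"complex|insertion|deletion|frameshift", "complex"),
    (r"intronic", "intronic"),
    (r"unknown", "unknown"),
)

DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "gene": "Gene name",
    "transcript": "Accession Number",
    "site": "Primary site",
    "position": "Mutation genome position",
    "description": "Mutation Description",
    "sample": "ID_sample",
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation anchored at a single genomic base (for
    multi-base events, the first affected base)."""

    gene_name: str
    transcript_id: str
    primary_site: str
    chrom: str
    position: int
    mutation_type: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.primary_site:
            raise ValueError("primary_site must be non-empty")


@dataclass(frozen=True)
class DomainMutationCount:
    """Accumulated mutation count for one (Pfam family, cancer type) pair,
    with the family's cumulative amino-acid length across all occurrences
    (the normalisation denominator)."""

    domain_family: str
    primary_site: str
    accumulated_count: int
    cumulative_length_aa: int
    n_instances: int

    def __post_init__(self) -> None:
        if self.accumulated_count < 0:
            raise ValueError("accumulated_count must be >= 0")
        if self.cumulative_length_aa < self.n_instances:
            raise ValueError(
                "cumulative_length_aa must be >= n_instances (each occurrence "
                "spans at least one amino acid)"
            )


_POSITION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def classify_mutation_type(
    description: str,
    patterns: Iterable[tuple[str, str]] = DEFAULT_TYPE_PATTERNS,
) -> str:
    """Classify a COSMIC mutation description (e.g. ``Substitution -
    Missense``) into a mutation-type label; unmatched text → ``other``."""
    for pattern, label in patterns:
        if re.search(pattern, description, flags=re.IGNORECASE):
            return label
    return "other"


def parse_cosmic(
    path: str,
    column_map: Mapping[str, str] | None = None,
    type_patterns: Iterable[tuple[str, str]] = DEFAULT_TYPE_PATTERNS,
) -> list[MutationRecord]:
    """Read a tab-separated COSMIC-style mutation table.

    ``column_map`` names the table columns holding the gene, primary site,
    genomic position (``chrom:start-end``; the start is used as the anchor)
    and mutation description.  Rows without a parsable genomic position are
    excluded; their count is logged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for role in ("gene", "site", "position", "description"):
        if cmap[role] not in df.columns:
            raise KeyError(
                f"{path}: required column {cmap[role]!r} (role {role!r}) missing"
            )
    records: list[MutationRecord] = []
    n_unknown_position = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        match = _POSITION_RE.match(row_d[cmap["position"]].strip())
        if match is None:
            n_unknown_position += 1
            continue
        records.append(
            MutationRecord(
                gene_name=row_d[cmap["gene"]],
                transcript_id=row_d.get(cmap.get("transcript", ""), ""),
                primary_site=row_d[cmap["site"]],
                chrom=match["chrom"],
                position=int(match["start"]),
                mutation_type=classify_mutation_type(
                    row_d[cmap["description"]], type_patterns
                ),
                sample_id=row_d.get(cmap.get("sample", ""), ""),
            )
        )
    if n_unknown_position:
        logger.warning(
            "%s: %d row(s) without a parsable genomic position excluded",
            path, n_unknown_position,
        )
    return records


def filter_types(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Retain nonsense, missense, coding-silent and complex mutations; drop
    intronic, unknown and unclassifiable records."""
    return [r for r in records if r.mutation_type in INCLUDED_TYPES]


class DomainIndex:
    """Interval index over domain genomic blocks, replacing the quadratic
    every-mutation-against-every-domain scan with O(log n) stabbing queries."""

    def __init__(self, mappings: Iterable[DomainGenomicMapping]) -> None:
        self.mappings: list[DomainGenomicMapping] = list(mappings)
        self._trees: dict[str, IntervalTree] = {}
        for m in self.mappings:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            for b in m.blocks:
                tree.addi(b.start, b.end + 1, m)  # half-open internally

    def query(self, chrom: str, position: int) -> list[DomainGenomicMapping]:
        """All mappings with an exonic block containing ``position``
        (1-based); equivalent to a linear scan over every block."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(position)]

    def families(self) -> list[str]:
        return sorted({m.family for m in self.mappings})

    def family_lengths(self) -> dict[str, tuple[int, int]]:
        """Per family: (cumulative amino-acid length over all occurrences,
        number of occurrences)."""
        out: dict[str, list[int]] = {}
        for m in self.mappings:
            acc = out.setdefault(m.family, [0, 0])
            acc[0] += m.aa_length
            acc[1] += 1
        return {fam: (length, n) for fam, (length, n) in out.items()}


def build_domain_index(mappings: Iterable[DomainGenomicMapping]) -> DomainIndex:
    """Build a queryable interval index over the mappings' exonic blocks."""
    return DomainIndex(mappings)


@dataclass
class MappingResult:
    """Output of :func:`map_mutations`: the per-site mapping summary and the
    per-(family, site) accumulated counts."""

    summary: pd.DataFrame
    counts: list[DomainMutationCount] = field(default_factory=list)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.domain_family, c.primary_site, c.accumulated_count,
                 c.cumulative_length_aa, c.n_instances)
                for c in self.counts
            ],
            columns=["domain_family", "primary_site", "accumulated_count",
                     "cumulative_length_aa", "n_instances"],
        )


def map_mutations(
    records: Iterable[MutationRecord],
    index: DomainIndex,
    group_by_site: bool = True,
) -> MappingResult:
    """Count mutations inside domain blocks, per Pfam family and cancer type.

    A record is "mapped" when it falls inside at least one domain block; a
    record inside several families' blocks increments each family once, but
    the mapped total still counts the record once.  Zero-count (family,
    site) pairs are included in the output so the downstream score
    population covers unmutated families.  ``group_by_site=False`` pools all
    records under a single ``all`` label.
    """
    site_of = (lambda r: r.primary_site) if group_by_site else (lambda r: "all")
    totals: dict[str, int] = {}
    mapped: dict[str, int] = {}
    fam_counts: dict[tuple[str, str], int] = {}
    for rec in records:
        site = site_of(rec)
        totals[site] = totals.get(site, 0) + 1
        hits = index.query(rec.chrom, rec.position)
        if not hits:
            continue
        mapped[site] = mapped.get(site, 0) + 1
        for fam in {m.family for m in hits}:  # dedupe on (record, family)
            key = (fam, site)
            fam_counts[key] = fam_counts.get(key, 0) + 1

    summary = pd.DataFrame(
        [
            (site, total, mapped.get(site, 0), total - mapped.get(site, 0),
             percentage_mapped(total, mapped.get(site, 0)))
            for site, total in sorted(totals.items())
        ],
        columns=["primary_site", "total", "mapped", "unmapped", "percentage"],
    )
    lengths = index.family_lengths()
    counts = [
        DomainMutationCount(
            domain_family=fam,
            primary_site=site,
            accumulated_count=fam_counts.get((fam, site), 0),
            cumulative_length_aa=lengths[fam][0],
            n_instances=lengths[fam][1],
        )
        for site in sorted(totals)
        for fam in sorted(lengths)
    ]
    return MappingResult(summary=summary, counts=counts)


def percentage_mapped(total: int, mapped: int) -> float:
    """Percentage of mutations mapped to domains, truncated to two decimals.

    Truncation (not half-up rounding) reproduces how such percentage tables
    are conventionally printed: 1376/2085 → 65.99, not 66.00.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= mapped <= total:
        raise ValueError("mapped must lie in [0, total]")
    if isinstance(total, int) and isinstance(mapped, int):
        return (10000 * mapped // total) / 100
    return math.floor(10000 * mapped / total) / 100


def count_domains_per_chromosome(
    mappings: Iterable[DomainGenomicMapping],
) -> dict[str, int]:
    """Tally domain mappings per chromosome; counts sum to the number of
    mappings."""
    out: dict[str, int] = {}
    for m in mappings:
        out[m.chrom] = out.get(m.chrom, 0) + 1
    return out
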