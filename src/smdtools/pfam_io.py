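"""Read and write PfamScan domain-hit tables and apply the e-value filter.

PfamScan emits 15 whitespace-separated columns per hit: sequence id,
alignment start/end, envelope start/end, HMM accession, HMM name, hit type,
HMM start/end/length, bit score, e-value, significance flag and clan.  The
envelope is the wider region possibly belonging to the domain; it always
contains the alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

logger = logging.getLogger(__name__)

N_COLUMNS = 15


@dataclass(frozen=True)
class DomainHit:
    """One PfamScan hit on a protein sequence (coordinates in amino acids)."""

    seq_id: str
    aln_start: int
    aln_end: int
    env_start: int
    env_end: int
    hmm_acc: str
    hmm_name: str
    hit_type: str
    hmm_start: int
    hmm_end: int
    hmm_length: int
    bit_score: float
    e_value: float
    significance: int
    clan: str

    def __post_init__(self) -> None:
        if self.aln_start > self.aln_end:
            raise ValueError(
                f"{self.seq_id}/{self.hmm_acc}: alignment start {self.aln_start} "
                f"> end {self.aln_end}"
            )
        if self.env_start > self.aln_start or self.aln_end > self.env_end:
            raise ValueError(
                f"{self.seq_id}/{self.hmm_acc}: envelope "
                f"{self.env_start}-{self.env_end} does not contain alignment "
                f"{self.aln_start}-{self.aln_end}"
            )
        if self.e_value < 0:
            raise ValueError(f"{self.seq_id}/{self.hmm_acc}: negative e-value")

    @property
    def family(self) -> str:
        """Pfam accession without the version suffix (PF13927.1 → PF13927)."""
        return self.hmm_acc.split(".")[0]


def parse_pfamscan(path: str) -> list[DomainHit]:
    """Parse a PfamScan output file into :class:`DomainHit` records.

    Comment lines (``#``) and blank lines are ignored.  Rows with the wrong
    column count or unparsable numeric fields are skipped with a warning;
    everything else is preserved row for row, duplicates included.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split()
            if len(cols) != N_COLUMNS:
                logger.warning(
                    "%s:%d: expected %d columns, found %d; row skipped",
                    path, lineno, N_COLUMNS, len(cols),
                )
                continue
            try:
                hits.append(
                    DomainHit(
                        seq_id=cols[0],
                        aln_start=int(cols[1]),
                        aln_end=int(cols[2]),
                        env_start=int(cols[3]),
                        env_end=int(cols[4]),
                        hmm_acc=cols[5],
                        hmm_name=cols[6],
                        hit_type=cols[7],
                        hmm_start=int(cols[8]),
                        hmm_end=int(cols[9]),
                        hmm_length=int(cols[10]),
                        bit_score=float(cols[11]),
                        e_value=float(cols[12]),
                        significance=int(cols[13]),
                        clan=cols[14],
                    )
                )
            except ValueError as exc:
                logger.warning("%s:%d: unparsable row skipped (%s)", path, lineno, exc)
    return hits


def write_pfamscan(hits: Iterable[DomainHit], path: str) -> None:
    """Write hits in the standard 15-column PfamScan layout."""
    with open(path, "w") as fh:
        fh.write("# <seq id> <alignment start> <alignment end> <envelope start> "
                 "<envelope end> <hmm acc> <hmm name> <type> <hmm start> <hmm end> "
                 "<hmm length> <bit score> <E-value> <significance> <clan>\n")
        for h in hits:
            fh.write(
                f"{h.seq_id} {h.aln_start} {h.aln_end} {h.env_start} {h.env_end} "
                f"{h.hmm_acc} {h.hmm_name} {h.hit_type} {h.hmm_start} {h.hmm_end} "
                f"{h.hmm_length} {h.bit_score:g} {h.e_value:g} {h.significance} "
                f"{h.clan}\n"
            )


def filter_evalue(hits: Iterable[DomainHit], threshold: float = 0.01) -> list[DomainHit]:
    """Keep hits with ``e_value <= threshold`` (inclusive), order preserved.

    The filter is inclusive so a hit at exactly the threshold is retained,
    matching the convention that an e-value bound of 0.01 keeps hits
    reported as 0.01.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [h for h in hits if h.e_value <= threshold]
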