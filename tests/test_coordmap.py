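"""Peptide→genome conversion: worked examples, a per-base brute-force
oracle, and structural properties."""

import numpy as np
import pytest

from smdtools.coordmap import (
    CoordinateError,
    batch_convert,
    coding_length,
    genomic_span,
    intron_gap_total,
    peptide_to_genome,
    write_bed12,
)
from smdtools.genemodel import build_fixture, cds_blocks


def enumerate_codon_bases(t, aa_start, aa_end):
    """Independent oracle: walk every CDS nucleotide 5'→3', assign codon
    index ceil(i/3), and collect the genomic positions of codons in
    [aa_start, aa_end] in reading order."""
    positions = []
    for block in cds_blocks(t):
        if t.strand == "+":
            positions.extend(range(block.start, block.end + 1))
        else:
            positions.extend(range(block.end, block.start - 1, -1))
    return [
        pos
        for i, pos in enumerate(positions, start=1)
        if aa_start <= -(-i // 3) <= aa_end
    ]


def mapping_bases(m):
    """Genomic positions of a mapping's blocks in 5'→3' order."""
    out = []
    for b in m.blocks:
        if m.strand == "+":
            out.extend(range(b.start, b.end + 1))
        else:
            out.extend(range(b.end, b.start - 1, -1))
    return out


def random_fixture(rng):
    n_exons = int(rng.integers(1, 11))
    pos = int(rng.integers(1, 1_000_000))
    exons = []
    for _ in range(n_exons):
        ln = int(rng.integers(10, 300))
        exons.append((pos, pos + ln - 1))
        pos += ln + int(rng.integers(30, 2000))
    total = sum(e - s + 1 for s, e in exons)
    utr5 = int(rng.integers(0, 12))
    n_aa = (total - utr5 - 3) // 3
    strand = "+" if rng.random() < 0.5 else "-"
    if n_aa < 2:
        return None
    return build_fixture("7", strand, exons, (utr5 + 1, utr5 + 3 * n_aa + 3))


class TestWorkedExamples:
    def test_single_exon_reverse_strand_domain(self, worked_examples):
        (t1, _), _ = worked_examples
        m = peptide_to_genome(t1, 112, 194, "PF00583.28")
        assert m.reported_start == 73_700_972
        assert m.reported_end == 73_700_724
        assert len(m.blocks) == 1
        assert coding_length(m) == 249
        assert genomic_span(m) == 249  # no introns: span equals coding length

    def test_six_exon_forward_strand_domain(self, worked_examples):
        (_, t2), _ = worked_examples
        m = peptide_to_genome(t2, 10, 75, "PF02798.24")
        assert m.reported_start == 23_980_225
        assert m.reported_end == 23_982_652
        assert len(m.blocks) == 3
        assert coding_length(m) == 198 == 66 * 3
        assert genomic_span(m, "subtraction") == 2427
        assert genomic_span(m, "inclusive") == 2428
        assert intron_gap_total(m) == 2230

    def test_first_codon_is_three_bases_at_cds_start(self):
        t = build_fixture("1", "+", [(1000, 1999)], (1, 300), has_stop=False)
        m = peptide_to_genome(t, 1, 1)
        assert [(b.start, b.end) for b in m.blocks] == [(1000, 1002)]
        assert coding_length(m) == 3
        assert genomic_span(m) == 3

    def test_out_of_range_names_transcript(self, worked_examples):
        (t1, _), _ = worked_examples
        with pytest.raises(CoordinateError, match="ENST00000377712.3"):
            peptide_to_genome(t1, 1, t1.peptide_length + 1)


class TestOracleEquivalence:
    def test_base_for_base_agreement_on_random_fixtures(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 1000:
            t = random_fixture(rng)
            if t is None:
                continue
            aa_start = int(rng.integers(1, t.peptide_length + 1))
            aa_end = int(rng.integers(aa_start, t.peptide_length + 1))
            m = peptide_to_genome(t, aa_start, aa_end)
            assert mapping_bases(m) == enumerate_codon_bases(t, aa_start, aa_end)
            assert coding_length(m) == 3 * (aa_end - aa_start + 1)
            checked += 1


class TestProperties:
    def test_strand_mirror_symmetry(self):
        rng = np.random.default_rng(5)
        mirror_origin = 10_000_000
        for _ in range(50):
            t = random_fixture(rng)
            if t is None:
                continue
            mirrored_exons = [
                (mirror_origin - e.interval.end, mirror_origin - e.interval.start)
                for e in t.exons
            ]
            lo = min(e.interval.start for e in t.exons)
            hi = max(e.interval.end for e in t.exons)
            total = sum(len(e.interval) for e in t.exons)
            # recover the transcript-relative CDS span of t
            span = _cds_span_of(t, total)
            flipped = build_fixture(
                "7", "-" if t.strand == "+" else "+", mirrored_exons, span,
            )
            aa_start = 1 + (t.peptide_length // 3)
            aa_end = min(t.peptide_length, aa_start + 5)
            m = peptide_to_genome(t, aa_start, aa_end)
            fm = peptide_to_genome(flipped, aa_start, aa_end)
            got = sorted((b.start, b.end) for b in fm.blocks)
            expected = sorted(
                (mirror_origin - b.end, mirror_origin - b.start) for b in m.blocks
            )
            assert got == expected
            assert lo >= 1 and hi < mirror_origin

    def test_adjacent_domains_tile_the_cds(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            t = random_fixture(rng)
            if t is None or t.peptide_length < 3:
                continue
            k = int(rng.integers(1, t.peptide_length))
            left = peptide_to_genome(t, 1, k)
            right = peptide_to_genome(t, k + 1, t.peptide_length)
            assert mapping_bases(left) + mapping_bases(right) == mapping_bases(
                peptide_to_genome(t, 1, t.peptide_length)
            )


def _cds_span_of(t, total_exon_nt):
    """Transcript-relative CDS span of a model (helper for mirroring)."""
    offset = 0
    lo = hi = None
    cds = set()
    for iv in t.cds_intervals:
        cds.update(range(iv.start, iv.end + 1))
    for exon in t.exons:
        iv = exon.interval
        rng_ = range(iv.start, iv.end + 1) if t.strand == "+" else range(iv.end, iv.start - 1, -1)
        for pos in rng_:
            offset += 1
            if pos in cds:
                if lo is None:
                    lo = offset
                hi = offset
    assert lo is not None and offset == total_exon_nt
    return (lo, hi)


class TestBatchConvert:
    def _models_for_table(self, ids):
        return [
            build_fixture("11", "+", [(1000, 1999)], (1, 900), has_stop=False,
                          transcript_id=tid, gene_id=f"G{i}")
            for i, tid in enumerate(ids)
        ]

    def test_all_hits_convert_when_transcripts_present(self, pfamscan_file):
        from smdtools.pfam_io import parse_pfamscan

        hits = parse_pfamscan(pfamscan_file)
        models = self._models_for_table(sorted({h.seq_id for h in hits}))
        mappings, skipped = batch_convert(models, hits)
        assert len(mappings) == 8
        assert skipped == []

    def test_missing_transcript_reported(self, pfamscan_file):
        from smdtools.pfam_io import parse_pfamscan

        hits = parse_pfamscan(pfamscan_file)[:1]
        mappings, skipped = batch_convert([], hits)
        assert mappings == []
        assert [(h.seq_id, reason) for h, reason in skipped] == [
            ("ENST00000615270.1", "transcript_not_found")
        ]

    def test_aa_out_of_range_reported(self):
        t = build_fixture("1", "+", [(100, 399)], (1, 300), has_stop=False,
                          transcript_id="T1")
        from smdtools.pfam_io import DomainHit

        hit = DomainHit("T1", 90, 150, 90, 150, "PF1.1", "F", "Domain",
                        1, 61, 61, 20.0, 1e-4, 1, "No_clan")
        mappings, skipped = batch_convert([t], [hit])
        assert mappings == []
        assert skipped[0][1] == "aa_out_of_range"

    def test_envelope_coordinates_switch(self):
        t = build_fixture("1", "+", [(100, 999)], (1, 900), has_stop=False,
                          transcript_id="T1")
        from smdtools.pfam_io import DomainHit

        hit = DomainHit("T1", 10, 20, 5, 25, "PF1.1", "F", "Domain",
                        1, 11, 11, 20.0, 1e-4, 1, "No_clan")
        (m_aln,), _ = batch_convert([t], [hit], coords="alignment")
        (m_env,), _ = batch_convert([t], [hit], coords="envelope")
        assert (m_aln.aa_start, m_aln.aa_end) == (10, 20)
        assert (m_env.aa_start, m_env.aa_end) == (5, 25)


def test_bed12_blocks_are_ascending_and_sized(tmp_path, worked_examples):
    (_, t2), _ = worked_examples
    m = peptide_to_genome(t2, 10, 75, "PF02798.24")
    out = tmp_path / "m.bed"
    write_bed12([m], str(out))
    fields = out.read_text().strip().split("\t")
    assert fields[0] == "22"
    assert int(fields[1]) == 23_980_225 - 1  # 0-based start
    assert int(fields[2]) == 23_982_652
    sizes = [int(x) for x in fields[10].split(",")]
    starts = [int(x) for x in fields[11].split(",")]
    assert sum(sizes) == 198
    assert starts == sorted(starts) and starts[0] == 0
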