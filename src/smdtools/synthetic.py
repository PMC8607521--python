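"""Seeded generators for self-contained test worlds.

:func:`simulate_world` writes a matched trio of input files — an
Ensembl-dialect GTF of transcript models, a PfamScan hit table, and a
COSMIC-style mutation table — plus a ground-truth table of planted
significantly mutated families.  Mutations are drawn per coding base as
independent Bernoulli events at a uniform background rate, multiplied
inside the blocks of planted families; this emulates the statistical
structure the analysis assumes (uniform background substitution with
elevated rates inside driver domains) while remaining fully known.

:func:`worked_example_fixtures` builds two reference transcripts whose
domain conversions have hand-checkable printed coordinates: a single-exon
reverse-strand acetyltransferase domain (83 aa, 249 nt, no introns) and a
six-exon forward-strand glutathione-S-transferase N-terminal domain (66 aa,
198 coding nt spread over three exons separated by 638 + 1592 = 2230
intronic nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from smdtools.coordmap import peptide_to_genome
from smdtools.genemodel import TranscriptModel, build_fixture, write_gtf
from smdtools.pfam_io import DomainHit, write_pfamscan

#: COSMIC-style primary-site labels used for simulated cancer types.
SITE_LABELS = (
    "adrenal_gland", "biliary_tract", "bone", "breast", "central_nervous_system",
    "cervix", "endometrium", "eye", "kidney", "large_intestine", "liver",
    "lung", "oesophagus", "ovary", "pancreas", "prostate", "skin", "stomach",
    "testis", "thyroid", "urinary_tract",
)

_TYPE_MIX = (
    ("Substitution - Missense", 0.70),
    ("Substitution - Nonsense", 0.10),
    ("Substitution - coding silent", 0.10),
    ("Complex - deletion inframe", 0.10),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic world.

    ``mutations_per_site`` is the number of independent per-base Bernoulli
    sweeps (simulated tumour samples) per cancer type; the expected mutation
    count at a base is therefore ``mutations_per_site × background_rate ×
    multiplier``.  ``planted_families`` lists (Pfam accession, rate
    multiplier) pairs; each planted family is placed on
    ``planted_instances`` distinct genes.
    """

    seed: int = 0
    n_genes: int = 300
    transcripts_per_gene: float = 1.2
    exons_per_transcript: tuple[int, int] = (1, 6)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (200, 2000)
    domains_per_transcript: tuple[int, int] = (1, 3)
    domain_length_aa: tuple[int, int] = (25, 60)
    background_rate: float = 2e-4
    planted_families: tuple[tuple[str, float], ...] = ()
    n_sites: int = 4
    mutations_per_site: int = 100
    planted_instances: int = 8
    intronic_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_sites", "mutations_per_site", "planted_instances"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.transcripts_per_gene < 1:
            raise ValueError("transcripts_per_gene must be >= 1")
        for name in ("exons_per_transcript", "exon_length", "intron_length",
                     "domains_per_transcript", "domain_length_aa"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range {lo}-{hi} is invalid")
        if not 0.0 < self.background_rate < 1.0:
            raise ValueError("background_rate must lie in (0, 1)")
        for fam, mult in self.planted_families:
            if mult < 1:
                raise ValueError(f"planted multiplier for {fam} must be >= 1")
        if not 0.0 <= self.intronic_fraction < 1.0:
            raise ValueError("intronic_fraction must lie in [0, 1)")


@dataclass
class SimWorld:
    """Paths of one simulated world plus its ground truth."""

    gtf_path: Path
    pfam_path: Path
    mutation_path: Path
    truth_path: Path
    ground_truth: pd.DataFrame
    models: list[TranscriptModel] = field(default_factory=list)
    hits: list[DomainHit] = field(default_factory=list)


def simulate_world(cfg: SimConfig, out_dir: str | Path) -> SimWorld:
    """Generate one synthetic world under ``out_dir``; deterministic for a
    given config (same seed → byte-identical files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    models, primary = _simulate_transcripts(cfg, rng)
    hits, domain_truth = _simulate_domains(cfg, rng, primary)
    # Duplicate each primary transcript's hits onto its isoforms, as PfamScan
    # does when isoforms share the domain-bearing peptide.
    iso_hits: list[DomainHit] = []
    primary_of = {}
    for t in models:
        primary_of.setdefault(t.gene_id, t.transcript_id)
    hits_by_tx: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_tx.setdefault(h.seq_id, []).append(h)
    for t in models:
        src = primary_of[t.gene_id]
        if t.transcript_id != src:
            for h in hits_by_tx.get(src, []):
                iso_hits.append(DomainHit(**{**h.__dict__, "seq_id": t.transcript_id}))
    all_hits = hits + iso_hits

    mutations = _simulate_mutations(cfg, rng, primary, domain_truth)

    gtf_path = out / "genes.gtf"
    pfam_path = out / "domains.pfamscan"
    mut_path = out / "mutations.tsv"
    truth_path = out / "ground_truth.tsv"
    write_gtf(models, str(gtf_path))
    write_pfamscan(all_hits, str(pfam_path))
    mutations.to_csv(mut_path, sep="\t", index=False)
    truth = pd.DataFrame(
        [
            (fam, mult, len(blocks),
             ";".join(f"{c}:{s}-{e}" for c, s, e in blocks))
            for fam, (mult, blocks) in sorted(domain_truth.items())
            if mult > 1.0
        ],
        columns=["domain_family", "multiplier", "n_instances", "blocks"],
    )
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimWorld(gtf_path, pfam_path, mut_path, truth_path, truth,
                    models=models, hits=all_hits)


def _simulate_transcripts(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Lay genes end to end along chromosomes; extra isoforms are identical
    copies of the primary transcript (distinct versioned ids)."""
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    cursors = {c: 10_000 for c in chroms}
    models: list[TranscriptModel] = []
    primary: list[TranscriptModel] = []
    tx_serial = 0
    for g in range(cfg.n_genes):
        chrom = chroms[g % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(cfg.exons_per_transcript[0],
                                   cfg.exons_per_transcript[1] + 1))
        exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1,
                                 size=n_exons)
        intron_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1,
                                   size=max(n_exons - 1, 0))
        start = cursors[chrom]
        exons = []
        pos = start
        for i, ln in enumerate(exon_lens):
            exons.append((pos, pos + int(ln) - 1))
            pos += int(ln)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        cursors[chrom] = pos + 10_000
        total = int(exon_lens.sum())
        utr5 = int(rng.integers(0, 21))
        n_aa = (total - utr5 - 3 - 20) // 3  # leave >= 20 nt headroom for 3'UTR
        if n_aa < 40:  # stretch the last exon so short transcripts still code
            deficit = (40 - n_aa) * 3
            s, e = exons[-1]
            exons[-1] = (s, e + deficit)
            cursors[chrom] += deficit
            total += deficit
            n_aa = (total - utr5 - 3 - 20) // 3
        cds_span = (utr5 + 1, utr5 + 3 * n_aa + 3)
        tx_serial += 1
        gene_id = f"SGENE{g + 1:05d}"
        base = build_fixture(
            chrom, strand, exons, cds_span,
            transcript_id=f"STX{tx_serial:08d}.1", gene_id=gene_id,
        )
        models.append(base)
        primary.append(base)
        n_iso = int(rng.poisson(cfg.transcripts_per_gene - 1.0))
        for _ in range(min(n_iso, 3)):
            tx_serial += 1
            models.append(
                build_fixture(chrom, strand, exons, cds_span,
                              transcript_id=f"STX{tx_serial:08d}.1",
                              gene_id=gene_id)
            )
    return models, primary


def _simulate_domains(
    cfg: SimConfig, rng: np.random.Generator, primary: list[TranscriptModel]
) -> tuple[list[DomainHit], dict[str, tuple[float, list[tuple[str, int, int]]]]]:
    """Place non-overlapping domains on primary transcripts and assign
    families: planted families first (on distinct genes), then a pool of
    recurring background families (about two occurrences each, as Pfam
    families recur across genes)."""
    len_lo, len_hi = cfg.domain_length_aa
    slots: list[tuple[TranscriptModel, int, int]] = []
    for t in primary:
        n_dom = int(rng.integers(cfg.domains_per_transcript[0],
                                 cfg.domains_per_transcript[1] + 1))
        seg = t.peptide_length // n_dom
        for d in range(n_dom):
            seg_lo = d * seg + 1
            max_len = min(len_hi, seg - 2)
            if max_len < len_lo:
                continue
            length = int(rng.integers(len_lo, max_len + 1))
            offset = int(rng.integers(0, seg - length))
            slots.append((t, seg_lo + offset, seg_lo + offset + length - 1))
    order = rng.permutation(len(slots))

    hits: list[DomainHit] = []
    truth: dict[str, tuple[float, list[tuple[str, int, int]]]] = {}
    assigned: list[str] = [""] * len(slots)
    used_genes: dict[str, set[str]] = {}
    slot_iter = iter(order)
    for fam, mult in cfg.planted_families:
        placed = 0
        used = used_genes.setdefault(fam, set())
        for idx in order:
            if placed >= cfg.planted_instances:
                break
            if assigned[idx]:
                continue
            t = slots[idx][0]
            if t.gene_id in used:
                continue
            assigned[idx] = fam
            used.add(t.gene_id)
            truth.setdefault(fam, (mult, []))
            placed += 1
    n_free = sum(1 for a in assigned if not a)
    pool_size = max(1, n_free // 2)
    for idx in range(len(slots)):
        if not assigned[idx]:
            assigned[idx] = f"PF8{int(rng.integers(pool_size)) + 1:04d}"
    for idx, (t, aa_lo, aa_hi) in enumerate(slots):
        fam = assigned[idx]
        acc = f"{fam}.1"
        mult = dict(cfg.planted_families).get(fam, 1.0)
        mapping = peptide_to_genome(t, aa_lo, aa_hi, acc)
        entry = truth.setdefault(fam, (mult, []))
        for b in mapping.blocks:
            entry[1].append((b.chrom, b.start, b.end))
        e_value = float(10 ** rng.uniform(-8, -2.2))
        hits.append(
            DomainHit(
                seq_id=t.transcript_id,
                aln_start=aa_lo, aln_end=aa_hi,
                env_start=max(1, aa_lo - int(rng.integers(0, 4))),
                env_end=min(t.peptide_length, aa_hi + int(rng.integers(0, 4))),
                hmm_acc=acc, hmm_name=fam, hit_type="Domain",
                hmm_start=1, hmm_end=aa_hi - aa_lo + 1,
                hmm_length=aa_hi - aa_lo + 1,
                bit_score=float(np.round(rng.uniform(15, 200), 1)),
                e_value=e_value, significance=1, clan="No_clan",
            )
        )
        if rng.random() < 0.05:  # decoy hit failing the e-value filter
            hits.append(
                DomainHit(
                    seq_id=t.transcript_id,
                    aln_start=aa_lo, aln_end=aa_hi,
                    env_start=aa_lo, env_end=aa_hi,
                    hmm_acc="PF99999.9", hmm_name="Decoy", hit_type="Family",
                    hmm_start=1, hmm_end=aa_hi - aa_lo + 1,
                    hmm_length=aa_hi - aa_lo + 1,
                    bit_score=9.9, e_value=float(np.round(rng.uniform(0.02, 0.5), 3)),
                    significance=0, clan="No_clan",
                )
            )
    return hits, truth


def _simulate_mutations(
    cfg: SimConfig,
    rng: np.random.Generator,
    primary: list[TranscriptModel],
    truth: dict[str, tuple[float, list[tuple[str, int, int]]]],
) -> pd.DataFrame:
    """Per-base Bernoulli mutation draws over all coding bases, with planted
    multipliers inside planted family blocks, plus a fraction of intronic
    and unknown records to exercise the type filter."""
    from smdtools.genemodel import cds_blocks

    chroms: list[str] = []
    positions: list[int] = []
    genes: list[str] = []
    txs: list[str] = []
    intron_pool: list[tuple[str, int, str, str]] = []
    for t in primary:
        blocks = cds_blocks(t)
        for b in blocks:
            for pos in range(b.start, b.end + 1):
                chroms.append(t.chrom)
                positions.append(pos)
                genes.append(t.gene_id)
                txs.append(t.transcript_id)
        span_lo = min(b.start for b in blocks)
        span_hi = max(b.end for b in blocks)
        covered = {p for b in blocks for p in range(b.start, b.end + 1)}
        introns = [p for p in range(span_lo, span_hi + 1) if p not in covered]
        intron_pool.extend((t.chrom, p, t.gene_id, t.transcript_id)
                           for p in introns[:50])

    chrom_arr = np.array(chroms)
    pos_arr = np.array(positions)
    mult = np.ones(len(positions))
    for fam, (m, blocks) in truth.items():
        if m <= 1.0:
            continue
        for c, s, e in blocks:
            inside = (chrom_arr == c) & (pos_arr >= s) & (pos_arr <= e)
            mult[inside] = np.maximum(mult[inside], m)

    rate = np.clip(cfg.background_rate * mult, 0, 1)
    site_names = [SITE_LABELS[i] if i < len(SITE_LABELS) else f"site_{i + 1}"
                  for i in range(cfg.n_sites)]
    type_names = [t for t, _ in _TYPE_MIX]
    type_probs = np.array([w for _, w in _TYPE_MIX])

    rows: list[tuple[str, str, str, str, str, str]] = []
    sample_serial = 0
    for site in site_names:
        counts = rng.binomial(cfg.mutations_per_site, rate)
        idx = np.nonzero(counts)[0]
        n_coding = 0
        for i in idx:
            for _ in range(int(counts[i])):
                sample_serial += 1
                desc = type_names[rng.choice(len(type_names), p=type_probs)]
                rows.append(
                    (genes[i], txs[i], site,
                     f"{chrom_arr[i]}:{pos_arr[i]}-{pos_arr[i]}",
                     desc, f"S{sample_serial}")
                )
                n_coding += 1
        frac = cfg.intronic_fraction
        n_extra = int(round(n_coding * frac / (1.0 - frac))) if frac else 0
        for j in range(n_extra):
            sample_serial += 1
            if j % 2 == 0 and intron_pool:
                c, p, g, tx = intron_pool[int(rng.integers(0, len(intron_pool)))]
                rows.append((g, tx, site, f"{c}:{p}-{p}", "Intronic",
                             f"S{sample_serial}"))
            else:
                i = int(rng.integers(0, len(pos_arr)))
                rows.append((genes[i], txs[i], site,
                             f"{chrom_arr[i]}:{pos_arr[i]}-{pos_arr[i]}",
                             "Unknown", f"S{sample_serial}"))
    return pd.DataFrame(
        rows,
        columns=["Gene name", "Accession Number", "Primary site",
                 "Mutation genome position", "Mutation Description", "ID_sample"],
    )


def worked_example_fixtures() -> tuple[tuple[TranscriptModel, TranscriptModel],
                                       tuple[DomainHit, DomainHit]]:
    """The two reference transcripts with hand-checkable conversions.

    Fixture 1 emulates ENST00000377712.3: one exon on the reverse strand of
    chromosome 2; the Acetyltransf_1 domain (aa 112–194, 83 aa) occupies
    genomic 73,700,724–73,700,972, read 73,700,972 → 73,700,724 in
    transcript orientation — 249 bases with no introns.

    Fixture 2 emulates ENST00000621118.4: six exons on the forward strand
    of chromosome 22; the GST_N domain (aa 10–75, 66 aa) starts in exon 1
    at 23,980,225 and ends in exon 3 at 23,982,652, its 198 coding bases
    interrupted by introns of 638 and 1592 nt.  Exons 4–6 (which carry no
    domain bases) have fixed arbitrary sizes.
    """
    t1 = build_fixture(
        "2", "-", [(73_700_476, 73_701_400)], (96, 698),
        transcript_id="ENST00000377712.3", gene_id="ENSG00000143797",
    )
    t2 = build_fixture(
        "22", "+",
        [
            (23_980_178, 23_980_297),
            (23_980_936, 23_981_035),
            (23_982_628, 23_982_707),
            (23_982_908, 23_982_947),
            (23_983_098, 23_983_127),
            (23_983_228, 23_983_260),
        ],
        (21, 383),
        transcript_id="ENST00000621118.4", gene_id="ENSG00000099984",
    )
    h1 = DomainHit(
        seq_id="ENST00000377712.3", aln_start=112, aln_end=194,
        env_start=110, env_end=198, hmm_acc="PF00583.28",
        hmm_name="Acetyltransf_1", hit_type="Family", hmm_start=1, hmm_end=83,
        hmm_length=83, bit_score=55.0, e_value=1e-12, significance=1,
        clan="CL0257",
    )
    h2 = DomainHit(
        seq_id="ENST00000621118.4", aln_start=10, aln_end=75,
        env_start=9, env_end=78, hmm_acc="PF02798.24", hmm_name="GST_N",
        hit_type="Domain", hmm_start=1, hmm_end=66, hmm_length=66,
        bit_score=48.2, e_value=3e-10, significance=1, clan="CL0172",
    )
    return (t1, t2), (h1, h2)
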