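"""Shared fixtures: reference transcripts, a PfamScan table with printed
values, and a small simulated world."""

import pytest

from smdtools.synthetic import SimConfig, simulate_world, worked_example_fixtures

# An eight-row PfamScan result table (Ig_3 hits across isoforms of one
# locus); the third row sits exactly at the 0.01 e-value threshold.
PFAMSCAN_TABLE = """\
# seq_id aln_start aln_end env_start env_end hmm_acc hmm_name type hmm_start hmm_end hmm_length bit_score e_value significance clan
ENST00000615270.1 128 181 128 222 PF13927.1 Ig_3 Domain 1 36 75 17.7 0.0037 1 CL0011
ENST00000616914.1 128 181 128 222 PF13927.1 Ig_3 Domain 1 36 75 17.7 0.0037 1 CL0011
ENST00000615996.1 128 155 128 224 PF13927.1 Ig_3 Domain 1 28 75 16.3 0.01 1 CL0011
ENST00000611873.1 128 181 128 222 PF13927.1 Ig_3 Domain 1 36 75 17.7 0.0037 1 CL0011
ENST00000339924.12 128 181 128 222 PF13927.1 Ig_3 Domain 1 36 75 17.7 0.0037 1 CL0011
ENST00000391729.1 128 181 128 211 PF13927.1 Ig_3 Domain 1 36 75 17.8 0.0034 1 CL0011
ENST00000621713.1 128 181 128 222 PF13927.1 Ig_3 Domain 1 36 75 17.7 0.0037 1 CL0011
ENST00000610808.1 128 181 128 222 PF13927.1 Ig_3 Domain 1 36 75 17.7 0.0037 1 CL0011
"""


@pytest.fixture(scope="session")
def worked_examples():
    """((single-exon reverse transcript, six-exon forward transcript),
    (their Pfam hits))."""
    return worked_example_fixtures()


@pytest.fixture()
def pfamscan_file(tmp_path):
    path = tmp_path / "hits.pfamscan"
    path.write_text(PFAMSCAN_TABLE)
    return str(path)


@pytest.fixture(scope="session")
def planted_world(tmp_path_factory):
    """One simulated world with two planted families (10x and 6x the
    background mutation rate)."""
    out = tmp_path_factory.mktemp("world")
    cfg = SimConfig(seed=42, planted_families=(("PF90001", 10.0), ("PF90002", 6.0)))
    return cfg, simulate_world(cfg, out)
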