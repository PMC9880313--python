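import random

import pytest

from stopfate.fixtures import btk_like, dmd_like, make_transcript


@pytest.fixture(scope="session")
def dmd_model():
    return dmd_like()


@pytest.fixture(scope="session")
def btk_model():
    return btk_like()


@pytest.fixture(scope="session")
def three_exon_model():
    """Exons [100,100,100], CDS 1..270, 30 nt 3'UTR."""
    return make_transcript([100, 100, 100], (1, 270), seed=3)


@pytest.fixture
def small_model():
    return make_transcript([60, 90, 120, 90, 90], (1, 420), seed=5)


# ---------------------------------------------------------------------------
# toy genome + GTF for the load_gtf / VCF path


def _write_fasta(path, name, seq, width=60):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """1 kb contig with a 2-exon plus-strand gene TX1.

    Exon1 genomic 51..110 (tx 1..60), exon2 201..290 (tx 61..150); CDS
    genomic 61..110 + 201..270 → tx 11..130 (ATG + 38 codons + TAA,
    120 nt, stop included in the CDS features).
    """
    rng = random.Random(42)
    genome = ["".join(rng.choice("ACGT") for _ in range(1000))]

    # plant a clean CDS: exon1 51..110 (60 nt), exon2 201..290 (90 nt)
    # CDS tx 11..130: ATG + 38 sense codons + TAA = 120 nt
    sense = [c for c in
             (a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
             if c not in ("TAA", "TAG", "TGA")]
    body = "".join(rng.choice(sense) for _ in range(38))
    cds = "ATG" + body + "TAA"
    assert len(cds) == 120
    g = list(genome[0])
    # exon1 genomic 51..110 → tx 1..60; CDS starts at tx 11 → genomic 61
    g[60:110] = cds[:50]
    g[200:270] = cds[50:]
    # keep intron boundaries canonical-ish (GT..AG), irrelevant to loading
    g[110:112] = "GT"
    g[198:200] = "AG"
    genome = "".join(g)

    d = tmp_path_factory.mktemp("toygenome")
    fa = d / "toy.fa"
    _write_fasta(fa, "chr1", genome)

    gtf = d / "toy.gtf"
    attr_p = 'gene_id "G1"; transcript_id "TX1";'
    rows = [
        ("chr1", "test", "exon", 51, 110, ".", "+", ".", attr_p),
        ("chr1", "test", "exon", 201, 290, ".", "+", ".", attr_p),
        ("chr1", "test", "CDS", 61, 110, ".", "+", ".", attr_p),
        ("chr1", "test", "CDS", 201, 270, ".", "+", ".", attr_p),
    ]
    with open(gtf, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return {"fasta": fa, "gtf": gtf, "genome": genome, "dir": d, "cds": cds}
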