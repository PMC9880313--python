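"""Transcript model, coordinate mapping, and loaders."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopfate.errors import (
    DomainError,
    FixtureError,
    NotFoundError,
    ValidationError,
)
from stopfate.fixtures import make_transcript
from stopfate.transcript import (
    cds_pos_to_codon,
    exon_offset_to_cds,
    fixture_to_dict,
    load_fixture,
    load_gtf,
    locate_cds_pos,
    reverse_complement,
)


class TestCdsPosToCodon:
    @pytest.mark.parametrize(
        "cds_pos,codon",
        [
            (72, 24),   # dystrophin Trp24 stop: r.72g>a sits in codon 24
            (595, 199), # last deleted nt of the BTK delins → residue 199
            (1, 1), (3, 1), (4, 2),
        ],
    )
    def test_examples(self, cds_pos, codon):
        assert cds_pos_to_codon(cds_pos) == codon

    @given(st.integers(min_value=1, max_value=10_000))
    def test_codon_boundaries(self, k):
        """Codon k spans CDS positions 3k-2 .. 3k."""
        assert cds_pos_to_codon(3 * k) == k
        assert cds_pos_to_codon(3 * k - 2) == k

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            cds_pos_to_codon(0)


class TestLocate:
    def test_mid_penultimate_exon(self, three_exon_model):
        # cds 150 = tx 150, exon 2 (101..200); junction at tx 200
        loc = locate_cds_pos(three_exon_model, 150)
        assert loc.exon_rank == 2
        assert loc.dist_to_last_junction == 51
        assert not loc.is_last_exon

    def test_last_exon(self, three_exon_model):
        loc = locate_cds_pos(three_exon_model, 250)
        assert loc.exon_rank == 3 and loc.is_last_exon
        assert loc.dist_to_last_junction < 0

    def test_single_exon(self):
        m = make_transcript([300], (1, 270), seed=1)
        loc = locate_cds_pos(m, 100)
        assert loc.exon_rank == 1 and loc.is_last_exon
        assert loc.dist_to_last_junction is None

    def test_out_of_range(self, three_exon_model):
        with pytest.raises(DomainError):
            locate_cds_pos(three_exon_model, 271)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data(), seed=st.integers(0, 10_000))
    def test_round_trip(self, data, seed):
        """locate then (exon_rank, offset) inversion reproduces cds_pos."""
        n_exons = data.draw(st.integers(1, 6))
        lengths = data.draw(
            st.lists(st.integers(30, 200), min_size=n_exons, max_size=n_exons)
        )
        total = sum(lengths)
        cds_start = data.draw(st.integers(1, min(20, total - 9)))
        max_len = (total - cds_start + 1) // 3 * 3
        if max_len < 9:
            return
        model = make_transcript(
            lengths, (cds_start, cds_start + max_len - 1), seed=seed
        )
        cds_pos = data.draw(st.integers(1, model.cds_len))
        loc = locate_cds_pos(model, cds_pos)
        assert exon_offset_to_cds(model, loc.exon_rank, loc.offset_in_exon) == cds_pos


class TestFixtureLoader:
    def test_basic_fixture(self, tmp_path, three_exon_model):
        p = tmp_path / "m.json"
        p.write_text(json.dumps(fixture_to_dict(three_exon_model)))
        m = load_fixture(p)
        assert m.n_exons == 3 and len(m.spliced_seq) == 300
        assert m == three_exon_model or m.spliced_seq == three_exon_model.spliced_seq

    def test_dmd_like_shape(self, dmd_model):
        """Dystrophin isoform-1 geometry: 79 exons, 3,685 residues."""
        assert dmd_model.n_exons == 79
        assert dmd_model.cds_len == 11058
        assert dmd_model.protein_length == 3685

    def test_cds_not_divisible_by_three(self, tmp_path, three_exon_model):
        d = fixture_to_dict(three_exon_model)
        d["cds_end_tx"] = 271
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(d))
        with pytest.raises(ValidationError):
            load_fixture(p)

    def test_malformed_json_names_problem(self, tmp_path):
        p = tmp_path / "broken.json"
        p.write_text("{not json")
        with pytest.raises(FixtureError):
            load_fixture(p)

    def test_missing_field(self, tmp_path, three_exon_model):
        d = fixture_to_dict(three_exon_model)
        del d["exon_lengths"]
        p = tmp_path / "m.json"
        p.write_text(json.dumps(d))
        with pytest.raises(FixtureError, match="exon_lengths"):
            load_fixture(p)

    def test_non_atg_start_rejected_unless_permissive(self, tmp_path, three_exon_model):
        d = fixture_to_dict(three_exon_model)
        d["spliced_seq"] = "CCC" + d["spliced_seq"][3:]
        p = tmp_path / "m.json"
        p.write_text(json.dumps(d))
        with pytest.raises(ValidationError):
            load_fixture(p)
        assert load_fixture(p, permissive_start=True).n_exons == 3


class TestGtfLoader:
    def test_plus_strand_concatenation(self, toy_genome):
        model = load_gtf(toy_genome["gtf"], toy_genome["fasta"], "TX1")
        genome = toy_genome["genome"]
        expected = genome[50:110] + genome[200:290]  # manual concatenation
        assert model.spliced_seq == expected
        assert (model.cds_start_tx, model.cds_end_tx) == (11, 130)
        assert model.cds_seq == toy_genome["cds"]

    def test_minus_strand_equals_revcomp_oracle(self, toy_genome, tmp_path):
        """Loading the reverse-complemented genome with mirrored minus-strand
        coordinates must reproduce the same mRNA."""
        genome = toy_genome["genome"]
        L = len(genome)
        rc = reverse_complement(genome)
        fa = tmp_path / "rc.fa"
        with open(fa, "w") as fh:
            fh.write(">chr1\n")
            for i in range(0, L, 60):
                fh.write(rc[i : i + 60] + "\n")

        def mirror(a, b):
            return L - b + 1, L - a + 1

        attr = 'gene_id "G1"; transcript_id "TX1";'
        gtf = tmp_path / "rc.gtf"
        with open(gtf, "w") as fh:
            for feat, (a, b) in [
                ("exon", (51, 110)), ("exon", (201, 290)),
                ("CDS", (61, 110)), ("CDS", (201, 270)),
            ]:
                ma, mb = mirror(a, b)
                fh.write(
                    f"chr1\ttest\t{feat}\t{ma}\t{mb}\t.\t-\t.\t{attr}\n"
                )
        plus = load_gtf(toy_genome["gtf"], toy_genome["fasta"], "TX1")
        minus = load_gtf(gtf, fa, "TX1")
        assert minus.strand == "-"
        assert minus.spliced_seq == plus.spliced_seq
        assert (minus.cds_start_tx, minus.cds_end_tx) == (
            plus.cds_start_tx, plus.cds_end_tx,
        )

    def test_missing_transcript(self, toy_genome):
        with pytest.raises(NotFoundError):
            load_gtf(toy_genome["gtf"], toy_genome["fasta"], "NO_SUCH_TX")


class TestGenomicMapping:
    def test_exonic_and_intronic_offsets(self, toy_genome):
        model = load_gtf(toy_genome["gtf"], toy_genome["fasta"], "TX1")
        assert model.genomic_to_tx(51) == (1, None)
        assert model.genomic_to_tx(110) == (60, None)
        assert model.genomic_to_tx(201) == (61, None)
        # first/second intronic nt past the donor
        assert model.genomic_to_tx(111) == (None, 1)
        assert model.genomic_to_tx(112) == (None, 2)
        # last intronic nt before the acceptor
        assert model.genomic_to_tx(200) == (None, -1)
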