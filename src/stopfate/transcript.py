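"""Transcript models and coordinate arithmetic.

All downstream computation runs in 1-based, inclusive transcript/CDS
coordinates — the frame of reference of HGVS ``c.`` descriptions and of the
NMD escape rules (which are all measured on the spliced mRNA). Genomic
coordinates are converted once at ingestion (`load_gtf`) and never used
afterwards.

Coordinate systems
------------------
mRNA (tx) position
    1-based offset into the spliced transcript sequence, 5'→3'.
CDS position
    1-based offset into the coding sequence; ``tx = cds_start_tx + cds - 1``.
codon index
    1-based; codon ``k`` occupies CDS positions ``3k-2 .. 3k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

from .errors import DomainError, FixtureError, NotFoundError, ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Exon:
    """One exon of a spliced transcript, in transcript (5'→3') order.

    Genomic coordinates are optional: fixture-dialect transcripts carry
    only exon lengths.
    """

    rank: int
    length: int
    genomic_start: int | None = None
    genomic_end: int | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValidationError(f"exon rank {self.rank}: length must be >= 1")
        if (self.genomic_start is None) != (self.genomic_end is None):
            raise ValidationError(
                f"exon rank {self.rank}: genomic_start/genomic_end must be set together"
            )
        if self.genomic_start is not None:
            if self.genomic_end - self.genomic_start + 1 != self.length:
                raise ValidationError(
                    f"exon rank {self.rank}: genomic span does not match length"
                )


@dataclass(frozen=True)
class NmdRuleConfig:
    """Thresholds of the NMD escape/attenuation rules.

    penultimate_window_nt
        PTCs in the penultimate exon within this many nt of its 3' end
        escape NMD (the "50 nt rule").
    start_proximal_nt
        PTCs whose stop codon starts within this many nt of the start codon
        may escape degradation (hedged in the literature; mapped to an
        INTERMEDIATE fate, see the classifier).
    long_exon_nt
        A PTC-bearing exon longer than this reduces NMD efficiency.
    """

    penultimate_window_nt: int = 50
    start_proximal_nt: int = 150
    long_exon_nt: int = 400

    def __post_init__(self):
        for name in ("penultimate_window_nt", "start_proximal_nt", "long_exon_nt"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")


@dataclass(frozen=True)
class ExonLocation:
    """Where a CDS position falls on the exon scaffold.

    dist_to_last_junction counts nucleotides from the position to the 3'
    end of the penultimate exon, inclusive of the position itself (a
    position at the very last nt of the penultimate exon has distance 1).
    Negative once the position is downstream of that junction (in the last
    exon); None for single-exon transcripts, which have no junction.
    """

    exon_rank: int
    offset_in_exon: int
    dist_to_last_junction: int | None
    exon_length: int
    is_last_exon: bool


@dataclass
class TranscriptModel:
    transcript_id: str
    strand: str
    exons: list[Exon]
    cds_start_tx: int
    cds_end_tx: int
    spliced_seq: str
    permissive_start: bool = False
    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self):
        self.spliced_seq = self.spliced_seq.upper()
        tid = self.transcript_id
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{tid}: strand must be '+' or '-'")
        if [e.rank for e in self.exons] != list(range(1, len(self.exons) + 1)):
            raise ValidationError(f"{tid}: exon ranks must be consecutive from 1")
        total = sum(e.length for e in self.exons)
        if len(self.spliced_seq) != total:
            raise ValidationError(
                f"{tid}: spliced_seq length {len(self.spliced_seq)} != "
                f"sum of exon lengths {total}"
            )
        if set(self.spliced_seq) - set("ACGTN"):
            raise ValidationError(f"{tid}: spliced_seq contains non-ACGTN characters")
        if not (1 <= self.cds_start_tx < self.cds_end_tx <= total):
            raise ValidationError(f"{tid}: CDS span outside transcript")
        if self.cds_len % 3 != 0:
            raise ValidationError(
                f"{tid}: CDS length {self.cds_len} not divisible by 3"
            )
        start_codon = self.spliced_seq[self.cds_start_tx - 1 : self.cds_start_tx + 2]
        if start_codon != "ATG" and not self.permissive_start:
            raise ValidationError(f"{tid}: CDS does not start with ATG ({start_codon})")
        # cumulative exon lengths; _cum[i] = total length through exon rank i
        cum, acc = [0], 0
        for e in self.exons:
            acc += e.length
            cum.append(acc)
        self._cum = cum

    # -- derived quantities -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_len(self) -> int:
        return self.cds_end_tx - self.cds_start_tx + 1

    @property
    def n_codons(self) -> int:
        """Codon count including the stop codon."""
        return self.cds_len // 3

    @property
    def protein_length(self) -> int:
        """Residue count excluding the stop."""
        return self.n_codons - 1

    @property
    def cds_seq(self) -> str:
        return self.spliced_seq[self.cds_start_tx - 1 : self.cds_end_tx]

    @property
    def utr3_seq(self) -> str:
        return self.spliced_seq[self.cds_end_tx :]

    # -- coordinate mapping -------------------------------------------------

    def cds_to_tx(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.cds_len:
            raise DomainError(f"CDS position {cds_pos} outside 1..{self.cds_len}")
        return self.cds_start_tx + cds_pos - 1

    def tx_to_exon_rank(self, tx_pos: int) -> int:
        if not 1 <= tx_pos <= self._cum[-1]:
            raise DomainError(f"mRNA position {tx_pos} outside transcript")
        lo, hi = 1, self.n_exons
        while lo < hi:
            mid = (lo + hi) // 2
            if tx_pos <= self._cum[mid]:
                hi = mid
            else:
                lo = mid + 1
        return lo

    def exon_junction_dists(self, tx_pos: int) -> tuple[int | None, int | None]:
        """Distances (nt, inclusive of the position) to the 5' and 3'
        boundaries of the containing exon, or None where the boundary is a
        transcript end rather than a splice junction."""
        rank = self.tx_to_exon_rank(tx_pos)
        d5 = tx_pos - self._cum[rank - 1]
        d3 = self._cum[rank] - tx_pos + 1
        return (None if rank == 1 else d5, None if rank == self.n_exons else d3)

    def genomic_to_tx(self, gpos: int) -> tuple[int | None, int | None]:
        """Map a genomic position onto the spliced transcript.

        Returns ``(tx_pos, None)`` for exonic positions and
        ``(None, offset)`` for intronic positions, where offset is the
        signed HGVS-style distance from the nearest exon edge in transcript
        orientation (+1 = first intronic nt after a donor site, -1 = last
        intronic nt before an acceptor). Positions outside the transcript
        span raise DomainError.
        """
        if any(e.genomic_start is None for e in self.exons):
            raise DomainError("transcript has no genomic coordinates (fixture mode)")
        exs = self.exons
        span_lo = min(e.genomic_start for e in exs)
        span_hi = max(e.genomic_end for e in exs)
        if not span_lo <= gpos <= span_hi:
            raise DomainError(f"genomic position {gpos} outside transcript span")
        for e in exs:
            if e.genomic_start <= gpos <= e.genomic_end:
                if self.strand == "+":
                    return self._cum[e.rank - 1] + (gpos - e.genomic_start + 1), None
                return self._cum[e.rank - 1] + (e.genomic_end - gpos + 1), None
        # intronic: signed offset from the nearest exon edge, tx orientation
        best: tuple[int, int] | None = None  # (abs distance, signed offset)
        for e in exs:
            if gpos < e.genomic_start:
                d = e.genomic_start - gpos
                off = -d if self.strand == "+" else d
            elif gpos > e.genomic_end:
                d = gpos - e.genomic_end
                off = d if self.strand == "+" else -d
            else:
                continue
            if best is None or d < best[0]:
                best = (d, off)
        assert best is not None
        return None, best[1]


def cds_pos_to_codon(cds_pos: int) -> int:
    """Codon index (1-based) containing a 1-based CDS nucleotide position."""
    if cds_pos < 1:
        raise DomainError(f"CDS position must be >= 1, got {cds_pos}")
    return ceil(cds_pos / 3)


def locate_cds_pos(model: TranscriptModel, cds_pos: int) -> ExonLocation:
    """Place a CDS position on the exon scaffold of its transcript."""
    tx_pos = model.cds_to_tx(cds_pos)
    rank = model.tx_to_exon_rank(tx_pos)
    exon = model.exons[rank - 1]
    offset = tx_pos - model._cum[rank - 1]
    if model.n_exons == 1:
        dist = None
    else:
        dist = model._cum[model.n_exons - 1] - tx_pos + 1
    return ExonLocation(
        exon_rank=rank,
        offset_in_exon=offset,
        dist_to_last_junction=dist,
        exon_length=exon.length,
        is_last_exon=rank == model.n_exons,
    )


def exon_offset_to_cds(model: TranscriptModel, exon_rank: int, offset: int) -> int:
    """Inverse of `locate_cds_pos` for round-trip checks."""
    if not 1 <= exon_rank <= model.n_exons:
        raise DomainError(f"exon rank {exon_rank} outside transcript")
    tx_pos = model._cum[exon_rank - 1] + offset
    cds_pos = tx_pos - model.cds_start_tx + 1
    if not 1 <= cds_pos <= model.cds_len:
        raise DomainError("position outside CDS")
    return cds_pos


# ---------------------------------------------------------------------------
# loaders


def load_fixture(path: str | Path, permissive_start: bool = False) -> TranscriptModel:
    """Load the self-contained JSON transcript dialect.

    Schema: {"transcript_id": str, "exon_lengths": [int, ...],
    "cds_start_tx": int, "cds_end_tx": int, "spliced_seq": str}.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FixtureError(f"{path}: invalid JSON: {exc}") from exc
    return fixture_from_dict(payload, permissive_start=permissive_start)


def fixture_from_dict(payload: dict, permissive_start: bool = False) -> TranscriptModel:
    required = {
        "transcript_id": str,
        "exon_lengths": list,
        "cds_start_tx": int,
        "cds_end_tx": int,
        "spliced_seq": str,
    }
    for key, typ in required.items():
        if key not in payload:
            raise FixtureError(f"fixture missing field '{key}'")
        if not isinstance(payload[key], typ):
            raise FixtureError(f"fixture field '{key}' must be {typ.__name__}")
    lengths = payload["exon_lengths"]
    if not all(isinstance(x, int) and x >= 1 for x in lengths):
        raise FixtureError("fixture field 'exon_lengths' must be positive integers")
    exons = [Exon(rank=i + 1, length=n) for i, n in enumerate(lengths)]
    return TranscriptModel(
        transcript_id=payload["transcript_id"],
        strand="+",
        exons=exons,
        cds_start_tx=payload["cds_start_tx"],
        cds_end_tx=payload["cds_end_tx"],
        spliced_seq=payload["spliced_seq"],
        permissive_start=permissive_start,
    )


def fixture_to_dict(model: TranscriptModel) -> dict:
    return {
        "transcript_id": model.transcript_id,
        "exon_lengths": [e.length for e in model.exons],
        "cds_start_tx": model.cds_start_tx,
        "cds_end_tx": model.cds_end_tx,
        "spliced_seq": model.spliced_seq,
    }


def load_gtf(
    gtf_path: str | Path,
    fasta_path: str | Path,
    transcript_id: str,
    permissive_start: bool = False,
) -> TranscriptModel:
    """Build a TranscriptModel from GTF/GFF3 exon+CDS features and a genome
    FASTA.

    Exons are ordered 5'→3' in transcript orientation; on the minus strand
    each exon sequence is reverse-complemented so spliced_seq is always the
    sense-strand mRNA.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def _features(ftype):
        out = []
        for feat in db.features_of_type(ftype):
            tids = feat.attributes.get("transcript_id") or feat.attributes.get(
                "Parent", []
            )
            if transcript_id in tids:
                out.append(feat)
        return out

    exon_feats = _features("exon")
    cds_feats = _features("CDS")
    if not exon_feats:
        raise NotFoundError(f"transcript '{transcript_id}' not found in {gtf_path}")
    if not cds_feats:
        raise NotFoundError(f"transcript '{transcript_id}' has no CDS features")

    strand = exon_feats[0].strand
    if strand not in {"+", "-"}:
        raise ValidationError(f"{transcript_id}: unstranded feature in GTF")
    minus = strand == "-"
    exon_feats.sort(key=lambda f: f.start, reverse=minus)
    fasta = Fasta(str(fasta_path), rebuild=False)

    exons, chunks = [], []
    for i, feat in enumerate(exon_feats):
        seq = fasta[feat.seqid][feat.start - 1 : feat.end].seq.upper()
        if minus:
            seq = reverse_complement(seq)
        chunks.append(seq)
        exons.append(
            Exon(
                rank=i + 1,
                length=feat.end - feat.start + 1,
                genomic_start=feat.start,
                genomic_end=feat.end,
            )
        )
    spliced = "".join(chunks)

    # CDS span in transcript coordinates from the genomic CDS extremes.
    # Ensembl GTFs keep the stop codon in separate stop_codon features;
    # fold those in so the CDS always includes its terminal stop.
    stop_feats = _features("stop_codon")
    cds_glo = min(f.start for f in cds_feats + stop_feats)
    cds_ghi = max(f.end for f in cds_feats + stop_feats)
    cum = [0]
    for e in exons:
        cum.append(cum[-1] + e.length)

    def g2t(gpos: int) -> int:
        for e in exons:
            if e.genomic_start <= gpos <= e.genomic_end:
                if minus:
                    return cum[e.rank - 1] + (e.genomic_end - gpos + 1)
                return cum[e.rank - 1] + (gpos - e.genomic_start + 1)
        raise ValidationError(f"{transcript_id}: CDS boundary {gpos} not exonic")

    t1, t2 = g2t(cds_glo), g2t(cds_ghi)
    cds_start_tx, cds_end_tx = min(t1, t2), max(t1, t2)

    return TranscriptModel(
        transcript_id=transcript_id,
        strand=strand,
        exons=exons,
        cds_start_tx=cds_start_tx,
        cds_end_tx=cds_end_tx,
        spliced_seq=spliced,
        permissive_start=permissive_start,
    )
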