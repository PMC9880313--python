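"""mRNA-level consequence calculation.

Applies a coding edit to a transcript's CDS, translates reference and
mutant, and locates any premature termination codon (PTC) — including the
scan for the first stop in a shifted reading frame, which continues past
the reference stop into the 3'UTR (a shifted frame does not see the old
stop).

PTC position convention: ``ptc_cds_pos`` is the first nucleotide of the new
stop codon in *reference*-CDS coordinates. For frameshifts the stop is
found in mutant coordinates and mapped back through the edit: positions
before the edit are shared, positions after it are shifted by the net
length change, and positions inside an inserted segment collapse onto the
first edited reference position. The NMD rules need a position on the
reference exon scaffold, which this mapping provides.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .errors import (
    ReferenceMismatchError,
    ScanAbortedError,
    UnsupportedRegionError,
    ValidationError,
)
from .hgvs import CodingVariant
from .transcript import TranscriptModel

_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

PLOF_CAVEAT = (
    "plof is a prediction of variant type, not of functional effect; "
    "loss of function requires experimental confirmation"
)


def translate_codon(codon: str) -> str:
    if "N" in codon:
        raise ScanAbortedError(f"codon '{codon}' contains N; translation ambiguous")
    try:
        return _CODON_TABLE[codon]
    except KeyError:
        raise ScanAbortedError(f"cannot translate codon '{codon}'") from None


def translate(seq: str, to_stop: bool = False) -> str:
    """Translate a nucleotide string codon by codon (trailing partial codon
    ignored); with to_stop, stop at and include the first '*'."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = translate_codon(seq[i : i + 3])
        out.append(aa)
        if to_stop and aa == "*":
            break
    return "".join(out)


@dataclass(frozen=True)
class MrnaConsequence:
    consequence_class: str
    net_length_change: int
    frame_offset: int
    ptc_cds_pos: int | None = None  # reference-scaffold coordinate, stop 1st nt
    ptc_codon: int | None = None  # codon index in the reading frame of the stop
    first_affected_codon: int | None = None
    ter_offset: int | None = None
    ref_residue: str | None = None  # at first_affected_codon, 1-letter
    new_residue: str | None = None

    _CLASSES = {
        "nonsense", "frameshift_with_ptc", "frameshift_no_ptc", "inframe_indel",
        "missense", "synonymous", "stop_lost", "no_change",
    }

    def __post_init__(self):
        if self.consequence_class not in self._CLASSES:
            raise ValidationError(
                f"unknown consequence class '{self.consequence_class}'"
            )
        if self.frame_offset != self.net_length_change % 3:
            raise ValidationError("frame_offset must equal net_length_change mod 3")
        if self.consequence_class in {"nonsense", "frameshift_with_ptc"}:
            if self.ptc_cds_pos is None:
                raise ValidationError(f"{self.consequence_class} requires ptc_cds_pos")

    @property
    def has_ptc(self) -> bool:
        return self.consequence_class in {"nonsense", "frameshift_with_ptc"}


@dataclass(frozen=True)
class PlofTag:
    """Predicted loss-of-function *type* label.

    Assigned from the variant type alone (stop-gained, frameshift, or a
    change to the two essential splice-site nucleotides flanking an exon) —
    never from the NMD outcome, and never a claim about function."""

    tag: str  # stop_gained | frameshift | essential_splice | none
    caveat: str = PLOF_CAVEAT

    def __post_init__(self):
        if self.tag not in {"stop_gained", "frameshift", "essential_splice", "none"}:
            raise ValidationError(f"unknown plof tag '{self.tag}'")


@dataclass(frozen=True)
class _Edit:
    """Positional bookkeeping of one applied edit, for coordinate mapping."""

    prefix_len: int  # reference nt untouched before the edit
    removed: int
    added: int

    @property
    def net(self) -> int:
        return self.added - self.removed

    def map_mut_to_ref(self, mut_pos: int) -> int:
        """Project a mutant-CDS coordinate onto the reference scaffold."""
        if mut_pos <= self.prefix_len:
            return mut_pos
        if mut_pos > self.prefix_len + self.added:
            return mut_pos - self.net
        # inside the inserted segment: collapse onto the edit locus
        return self.prefix_len + 1


def _edit_geometry(v: CodingVariant) -> _Edit:
    span = v.end - v.start + 1
    if v.kind == "substitution":
        return _Edit(v.start - 1, 1, 1)
    if v.kind == "deletion":
        return _Edit(v.start - 1, span, 0)
    if v.kind == "delins":
        return _Edit(v.start - 1, span, len(v.alt_seq))
    if v.kind == "insertion":
        return _Edit(v.start, 0, len(v.alt_seq))
    # duplication: the copy is inserted after the span
    return _Edit(v.end, 0, span)


def apply_variant(model: TranscriptModel, v: CodingVariant) -> str:
    """Apply a coding edit to the reference CDS; returns the mutated CDS.

    The variant's span must lie within the CDS; stated reference bases are
    checked against the transcript."""
    ref = model.cds_seq
    if not (1 <= v.start and v.end <= len(ref)):
        raise UnsupportedRegionError(
            f"{v.raw or v.kind}: span {v.start}_{v.end} outside CDS "
            f"1..{len(ref)} of {model.transcript_id}"
        )
    found = ref[v.start - 1 : v.end]
    if v.kind == "substitution" and found != v.ref_seq:
        raise ReferenceMismatchError(
            f"{v.raw or 'substitution'}: expected '{v.ref_seq}' at c.{v.start}, "
            f"transcript has '{found}'",
            expected=v.ref_seq,
            found=found,
        )
    if v.kind in {"deletion", "delins", "duplication"} and v.ref_seq:
        if found != v.ref_seq:
            raise ReferenceMismatchError(
                f"{v.raw or v.kind}: expected '{v.ref_seq}' at "
                f"c.{v.start}_{v.end}, transcript has '{found}'",
                expected=v.ref_seq,
                found=found,
            )

    if v.kind == "substitution":
        mutated = ref[: v.start - 1] + v.alt_seq + ref[v.start :]
    elif v.kind == "deletion":
        mutated = ref[: v.start - 1] + ref[v.end :]
    elif v.kind == "delins":
        mutated = ref[: v.start - 1] + v.alt_seq + ref[v.end :]
    elif v.kind == "insertion":
        mutated = ref[: v.start] + v.alt_seq + ref[v.start :]
    else:  # duplication
        mutated = ref[: v.end] + found + ref[v.end :]
    assert len(mutated) == len(ref) + v.net_length_change
    return mutated


def translate_and_scan(
    ref_cds: str,
    mut_cds: str,
    v: CodingVariant,
    utr3: str = "",
) -> MrnaConsequence:
    """Compare reference and mutant translations and locate any PTC.

    utr3 is the transcript sequence downstream of the reference stop; a
    shifted reading frame continues into it when hunting for the new stop.
    Raises ScanAbortedError on any N-containing codon and ValidationError
    if the reference CDS itself is malformed (internal stop / missing
    terminal stop), which catches fixture bugs early.
    """
    if not ref_cds or not mut_cds:
        raise ValidationError("empty sequence passed to translate_and_scan")
    ref_prot = translate(ref_cds)
    if "*" in ref_prot[:-1]:
        raise ValidationError("reference CDS contains an internal stop codon")
    if not ref_prot.endswith("*"):
        raise ValidationError("reference CDS does not end with a stop codon")

    edit = _edit_geometry(v)
    net = v.net_length_change
    frame_offset = net % 3
    ref_stop_first_nt = len(ref_cds) - 2
    ref_stop_codon = len(ref_cds) // 3

    if mut_cds == ref_cds:
        return MrnaConsequence("no_change", 0, 0)

    mut_prot = translate(mut_cds + utr3, to_stop=True)

    # first residue differing from reference (None if proteins agree over
    # the compared overlap — e.g. a synonymous substitution)
    first_affected = None
    for i in range(min(len(ref_prot), len(mut_prot))):
        if ref_prot[i] != mut_prot[i]:
            first_affected = i + 1
            break

    # stop codon of the mutant, mapped onto the reference scaffold; a stop
    # is premature iff its mapped first nt lies upstream of the reference
    # stop's first nt
    stop_idx = len(mut_prot) if mut_prot.endswith("*") else None  # codon index
    mapped_stop = edit.map_mut_to_ref(3 * stop_idx - 2) if stop_idx else None
    premature = mapped_stop is not None and mapped_stop < ref_stop_first_nt

    def _residues(codon: int | None) -> dict:
        if codon is None:
            return {}
        return dict(
            ref_residue=ref_prot[codon - 1] if codon <= len(ref_prot) else None,
            new_residue=mut_prot[codon - 1] if codon <= len(mut_prot) else None,
        )

    if frame_offset == 0:
        if premature:
            if first_affected is None:
                first_affected = stop_idx
            return MrnaConsequence(
                "nonsense", net, 0,
                ptc_cds_pos=mapped_stop,
                ptc_codon=stop_idx,
                first_affected_codon=first_affected,
                **_residues(first_affected),
            )
        if stop_idx is None or mapped_stop > ref_stop_first_nt:
            # reference stop destroyed; translation runs on (or off the end)
            fa = first_affected or ref_stop_codon
            return MrnaConsequence(
                "stop_lost", net, 0, first_affected_codon=fa, **_residues(fa)
            )
        # terminates at the reference stop locus
        if first_affected is None:
            if net == 0:
                return MrnaConsequence("synonymous", net, 0)
            return MrnaConsequence(
                "inframe_indel", net, 0,
                first_affected_codon=edit.prefix_len // 3 + 1,
            )
        cls = "missense" if net == 0 else "inframe_indel"
        return MrnaConsequence(
            cls, net, 0,
            first_affected_codon=first_affected,
            **_residues(first_affected),
        )

    # ----- shifted frame ---------------------------------------------------
    if first_affected is None:
        # shifted residues happen to match the reference up to the stop (or
        # the edit sits in the terminal codon): anchor on the edit locus
        first_affected = edit.prefix_len // 3 + 1
    if stop_idx is None:
        return MrnaConsequence(
            "frameshift_no_ptc", net, frame_offset,
            first_affected_codon=first_affected,
            **_residues(first_affected),
        )
    ter_offset = stop_idx - first_affected + 1
    common = dict(
        first_affected_codon=first_affected,
        ter_offset=ter_offset if ter_offset >= 1 else None,
        **_residues(first_affected),
    )
    if premature:
        return MrnaConsequence(
            "frameshift_with_ptc", net, frame_offset,
            ptc_cds_pos=mapped_stop, ptc_codon=stop_idx, **common,
        )
    # stop found, but at/after the reference stop locus: no premature stop
    return MrnaConsequence("frameshift_no_ptc", net, frame_offset, **common)


def plof_tag(
    v: CodingVariant | None,
    consequence: MrnaConsequence | None = None,
    splice_offset: int | None = None,
) -> PlofTag:
    """Type-level predicted-LoF label.

    splice_offset is the intronic offset of a genomic variant (VCF path);
    |offset| ≤ 2 marks the essential splice-site dinucleotides."""
    if splice_offset is not None and abs(splice_offset) <= 2:
        return PlofTag("essential_splice")
    if consequence is not None:
        if consequence.consequence_class == "nonsense":
            return PlofTag("stop_gained")
        if consequence.frame_offset != 0:
            return PlofTag("frameshift")
    return PlofTag("none")
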