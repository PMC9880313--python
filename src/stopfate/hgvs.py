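"""A deliberately small HGVS dialect.

Parses coding-DNA (``c.``) substitutions, deletions, insertions,
duplications and delins, and emits RNA (``r.``) and protein (``p.``)
descriptions including the no-product forms ``r.0``/``r.(0)`` and
``p.0``/``p.(0)``.

Everything outside that subset — intronic offsets (c.100+2), UTR positions
(c.-14, c.*6), inversions, repeats, alleles — is rejected with a typed
error so the caller reports the variant instead of misannotating it.

Because every annotation this tool produces is a computational prediction,
emitted r./p. strings are parenthesised by default; ``predicted=False``
(evidence-backed records) drops the parentheses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import HgvsParseError, UnsupportedRegionError, ValidationError

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}
_AA1 = {v: k for k, v in AA3.items()}


def aa3(residue: str) -> str:
    """1-letter → 3-letter amino acid code ('*' → 'Ter')."""
    try:
        return AA3[residue]
    except KeyError:
        raise ValidationError(f"unknown residue '{residue}'") from None


@dataclass(frozen=True)
class CodingVariant:
    """A parsed HGVS c. edit.

    start/end are 1-based CDS positions; start == end for single-nt edits
    and insertions use the flanking pair (start, end = start + 1).
    ref_seq may be empty when the description omitted the reference bases
    (validated later against the transcript, not at parse time).
    """

    kind: str  # substitution | deletion | insertion | duplication | delins
    start: int
    end: int
    ref_seq: str = ""
    alt_seq: str = ""
    raw: str = field(default="", compare=False)
    reference: str = field(default="", compare=False)  # e.g. "NM_000…" prefix

    def __post_init__(self):
        if self.kind not in {
            "substitution", "deletion", "insertion", "duplication", "delins"
        }:
            raise ValidationError(f"unknown variant kind '{self.kind}'")
        if self.start > self.end:
            raise ValidationError(f"start {self.start} > end {self.end}")
        for name in ("ref_seq", "alt_seq"):
            if set(getattr(self, name)) - set("ACGT"):
                raise ValidationError(f"{name} contains non-ACGT characters")
        if self.kind == "substitution" and not (
            len(self.ref_seq) == len(self.alt_seq) == 1 and self.start == self.end
        ):
            raise ValidationError("substitution must be a single-nt change")
        if self.kind == "insertion":
            if self.end != self.start + 1:
                raise ValidationError("insertion span must be a flanking pair")
            if not self.alt_seq:
                raise ValidationError("insertion requires inserted bases")
        if self.kind == "delins" and not self.alt_seq:
            raise ValidationError("delins requires inserted bases")
        if self.kind == "deletion" and self.alt_seq:
            raise ValidationError("deletion carries no inserted bases")

    @property
    def net_length_change(self) -> int:
        span = self.end - self.start + 1
        if self.kind == "substitution":
            return 0
        if self.kind == "deletion":
            return -span
        if self.kind == "insertion":
            return len(self.alt_seq)
        if self.kind == "duplication":
            return span
        return len(self.alt_seq) - span  # delins


@dataclass(frozen=True)
class ProteinAnnotation:
    """Inputs for a protein-level HGVS string.

    forms: no_protein_predicted (p.(0)), substitution_ter (p.Trp24*),
    frameshift_ter (p.Lys199Thrfs*3), missense (p.Lys199Thr),
    full_deletion (p.0 of an asserted absent protein), unchanged (p.(=)).
    """

    form: str
    first_affected_codon: int | None = None
    ref_residue: str | None = None  # 1-letter
    new_residue: str | None = None  # 1-letter
    ter_offset: int | None = None
    predicted: bool = True

    def __post_init__(self):
        forms = {
            "no_protein_predicted", "substitution_ter", "frameshift_ter",
            "missense", "full_deletion", "unchanged",
        }
        if self.form not in forms:
            raise ValidationError(f"unknown protein form '{self.form}'")
        if self.form in {"no_protein_predicted", "full_deletion", "unchanged"}:
            if any(
                x is not None
                for x in (self.first_affected_codon, self.ref_residue,
                          self.new_residue, self.ter_offset)
            ):
                raise ValidationError(f"{self.form} admits no residue fields")
        if self.form in {"substitution_ter", "frameshift_ter", "missense"}:
            if self.first_affected_codon is None or self.ref_residue is None:
                raise ValidationError(f"{self.form} needs codon and residue")
        if self.form == "frameshift_ter":
            if self.ter_offset is None or self.ter_offset < 1:
                raise ValidationError("frameshift_ter needs ter_offset >= 1")
            if self.new_residue is None:
                raise ValidationError("frameshift_ter needs the new residue")
        if self.form == "missense" and self.new_residue is None:
            raise ValidationError("missense needs the new residue")


# ---------------------------------------------------------------------------
# parsing

_PREFIX_RE = re.compile(r"^([A-Za-z][\w.]*):\s*(.*)$")
_UNSUPPORTED_POS_RE = re.compile(r"(?:^|[._])(?:\*|-)?\d+[+-]\d+|[._]\*\d+|\.\s*-\d+")
_SUB_RE = re.compile(r"^(\d+)([ACGT])>([ACGT])$")
_DELINS_RE = re.compile(r"^(\d+)(?:_(\d+))?del(?:([ACGT]+))?ins([ACGT]+)$")
_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]*)$")
_DUP_RE = re.compile(r"^(\d+)(?:_(\d+))?dup([ACGT]*)$")
_INS_RE = re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$")


def parse_c(hgvs_string: str) -> CodingVariant:
    """Parse an HGVS coding-DNA description.

    An optional reference prefix ("NM_0001:", "LRG_199t1:") is split off
    and retained. Intronic/UTR positions raise UnsupportedRegionError;
    anything else that fails the grammar raises HgvsParseError with the
    character offset of the failure.
    """
    raw = hgvs_string.strip()
    reference = ""
    body = raw
    m = _PREFIX_RE.match(body)
    if m and m.group(2).startswith(("c.", "c .")):
        reference, body = m.group(1), m.group(2)
    if not body.startswith("c."):
        raise HgvsParseError(f"expected 'c.' description, got '{raw}'", offset=0)
    expr = body[2:].replace(" ", "")
    if _UNSUPPORTED_POS_RE.search(body):
        raise UnsupportedRegionError(
            f"'{raw}': intronic/UTR positions are outside the supported c. subset"
        )

    def _span(g1: str, g2: str | None) -> tuple[int, int]:
        start = int(g1)
        end = int(g2) if g2 else start
        if start < 1 or end < start:
            raise HgvsParseError(f"bad span {g1}_{g2} in '{raw}'", offset=2)
        return start, end

    if m := _SUB_RE.match(expr):
        start = int(m.group(1))
        if start < 1:
            raise HgvsParseError(f"bad position in '{raw}'", offset=2)
        return CodingVariant(
            "substitution", start, start,
            ref_seq=m.group(2), alt_seq=m.group(3), raw=raw, reference=reference,
        )
    if m := _DELINS_RE.match(expr):
        start, end = _span(m.group(1), m.group(2))
        ref = m.group(3) or ""
        if ref and len(ref) != end - start + 1:
            raise HgvsParseError(
                f"'{raw}': stated deleted bases do not match span length", offset=2
            )
        return CodingVariant(
            "delins", start, end, ref_seq=ref, alt_seq=m.group(4),
            raw=raw, reference=reference,
        )
    if m := _DEL_RE.match(expr):
        start, end = _span(m.group(1), m.group(2))
        ref = m.group(3)
        if ref and len(ref) != end - start + 1:
            raise HgvsParseError(
                f"'{raw}': stated deleted bases do not match span length", offset=2
            )
        return CodingVariant(
            "deletion", start, end, ref_seq=ref, raw=raw, reference=reference
        )
    if m := _DUP_RE.match(expr):
        start, end = _span(m.group(1), m.group(2))
        ref = m.group(3)
        if ref and len(ref) != end - start + 1:
            raise HgvsParseError(
                f"'{raw}': stated duplicated bases do not match span length", offset=2
            )
        return CodingVariant(
            "duplication", start, end, ref_seq=ref, raw=raw, reference=reference
        )
    if m := _INS_RE.match(expr):
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise HgvsParseError(
                f"'{raw}': insertion span must be two flanking positions", offset=2
            )
        return CodingVariant(
            "insertion", start, end, alt_seq=m.group(3), raw=raw, reference=reference
        )

    # locate the first character that breaks the grammar, for the message
    offset = 2
    for i, ch in enumerate(expr):
        if not (ch.isdigit() or ch in "_ACGT>delinsup"):
            offset = 2 + i
            break
    raise HgvsParseError(f"cannot parse '{raw}'", offset=offset)


# ---------------------------------------------------------------------------
# formatting


def format_c(v: CodingVariant) -> str:
    """Canonical c. string for a CodingVariant (ref-less del/dup forms)."""
    span = f"{v.start}" if v.start == v.end else f"{v.start}_{v.end}"
    if v.kind == "substitution":
        return f"c.{v.start}{v.ref_seq}>{v.alt_seq}"
    if v.kind == "deletion":
        return f"c.{span}del"
    if v.kind == "duplication":
        return f"c.{span}dup"
    if v.kind == "insertion":
        return f"c.{v.start}_{v.end}ins{v.alt_seq}"
    return f"c.{span}delins{v.alt_seq}"


def _rna_payload(v: CodingVariant) -> str:
    def rna(seq: str) -> str:
        return seq.lower().replace("t", "u")

    span = f"{v.start}" if v.start == v.end else f"{v.start}_{v.end}"
    if v.kind == "substitution":
        return f"{v.start}{rna(v.ref_seq)}>{rna(v.alt_seq)}"
    if v.kind == "deletion":
        return f"{span}del"
    if v.kind == "duplication":
        return f"{span}dup"
    if v.kind == "insertion":
        return f"{v.start}_{v.end}ins{rna(v.alt_seq)}"
    return f"{span}delins{rna(v.alt_seq)}"


def format_r(
    variant: CodingVariant | None = None,
    degraded: bool = False,
    predicted: bool = True,
) -> str:
    """RNA-level description.

    degraded=True emits the no-transcript form r.0 / r.(0); otherwise the
    RNA image of the coding edit. predicted wraps the payload in
    parentheses (theoretical construction, no RNA evidence).
    """
    if degraded:
        payload = "0"
    elif variant is not None:
        payload = _rna_payload(variant)
    else:
        payload = "="
    return f"r.({payload})" if predicted else f"r.{payload}"


def format_p(ann: ProteinAnnotation, one_letter: bool = False) -> str:
    """Protein-level description from a ProteinAnnotation.

    Three-letter residue codes by default; one_letter switches the whole
    string to 1-letter codes (never mixed)."""

    def res(r: str) -> str:
        return r if one_letter else aa3(r)

    if ann.form in {"no_protein_predicted", "full_deletion"}:
        payload = "0"
    elif ann.form == "unchanged":
        payload = "="
    elif ann.form == "substitution_ter":
        payload = f"{res(ann.ref_residue)}{ann.first_affected_codon}*"
    elif ann.form == "missense":
        payload = (
            f"{res(ann.ref_residue)}{ann.first_affected_codon}{res(ann.new_residue)}"
        )
    else:  # frameshift_ter
        if ann.ter_offset == 1:
            # the first shifted codon is itself the stop
            payload = f"{res(ann.ref_residue)}{ann.first_affected_codon}*"
        else:
            payload = (
                f"{res(ann.ref_residue)}{ann.first_affected_codon}"
                f"{res(ann.new_residue)}fs*{ann.ter_offset}"
            )
    return f"p.({payload})" if ann.predicted else f"p.{payload}"
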