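"""Candidate "unsense" screening (VariO:0514).

A substitution that leaves the codon table unchanged can still destroy or
create a splice signal when it sits at the exonic edge of a junction, so an
apparently-synonymous change there may abolish the transcript or protein
altogether. Only junction proximity is computable here — exonic
splice-enhancer/silencer motifs and miRNA seed sites are not modelled — so
the flag is a *candidate* label, never a classification, and every
synonymous call carries the reminder that synonymy is a codon-table
statement only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consequence import MrnaConsequence
from .errors import ValidationError
from .hgvs import CodingVariant
from .transcript import TranscriptModel

VARIO_UNSENSE = "VariO:0514 unsense variant"

SYNONYMY_CAVEAT = (
    "synonymous by codon table only; splicing, splicing-regulatory and "
    "miRNA-binding effects are not excluded"
)


@dataclass(frozen=True)
class UnsenseFlag:
    flagged: bool
    reason: str  # exonic_splice_site_proximal | none | not_applicable
    dist_to_nearest_junction: int | None = None
    vario: str | None = None

    def __post_init__(self):
        if self.reason not in {"exonic_splice_site_proximal", "none", "not_applicable"}:
            raise ValidationError(f"unknown unsense reason '{self.reason}'")
        if self.flagged and self.vario != VARIO_UNSENSE:
            raise ValidationError("flagged records must carry VariO:0514")


def screen(
    v: CodingVariant,
    consequence: MrnaConsequence,
    model: TranscriptModel,
    window_nt: int = 3,
) -> UnsenseFlag:
    """Flag a synonymous substitution whose position lies within
    ``window_nt`` exonic nucleotides of a splice junction.

    Distance counts the position itself: the last nt of an internal exon is
    at distance 1 from the downstream junction. Transcript ends are not
    junctions. Non-substitutions and non-synonymous substitutions return a
    not-applicable flag (no error)."""
    if window_nt < 1:
        raise ValidationError("window_nt must be >= 1")
    if v.kind != "substitution" or consequence.consequence_class != "synonymous":
        return UnsenseFlag(False, "not_applicable")
    tx_pos = model.cds_to_tx(v.start)
    d5, d3 = model.exon_junction_dists(tx_pos)
    dists = [d for d in (d5, d3) if d is not None]
    nearest = min(dists) if dists else None
    if nearest is not None and nearest <= window_nt:
        return UnsenseFlag(
            True, "exonic_splice_site_proximal", nearest, VARIO_UNSENSE
        )
    return UnsenseFlag(False, "none", nearest)
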