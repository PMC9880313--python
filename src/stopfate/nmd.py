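"""NMD fate classification of a located premature termination codon.

The classifier applies the transcript-geometry escape rules from the NMD
literature in a fixed precedence:

1. single-exon transcript            → ESCAPE   (no exon junction complex)
2. PTC in the last exon              → ESCAPE   (last-exon rule)
3. PTC in the penultimate exon within
   the last `penultimate_window_nt`  → ESCAPE   (the 50 nt rule)
4. stop codon starting within
   `start_proximal_nt` of the start  → INTERMEDIATE (start-proximal rule)
5. PTC-bearing exon longer than
   `long_exon_nt`                    → INTERMEDIATE (long-exon rule)
6. otherwise                         → TRIGGER  (efficient degradation)

Escape rules dominate the attenuation rules: they describe where
degradation does not occur at all, while the start-proximal and long-exon
rules only reduce NMD efficiency (hence the hedged INTERMEDIATE fate rather
than ESCAPE). All applicable rules of the winning class are listed.

Distances: the 50 nt window is measured from the first nucleotide of the
stop codon to the 3' end of the penultimate exon, inclusive. A stop codon
straddling an exon junction is assigned to the exon containing its first
nucleotide, with a note in confidence_note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NoBoundaryError, ValidationError
from .transcript import (
    ExonLocation,
    NmdRuleConfig,
    TranscriptModel,
    cds_pos_to_codon,
    locate_cds_pos,
)

ESCAPE_RULES = ("single_exon", "last_exon", "penultimate_50nt")
ATTENUATION_RULES = ("start_proximal", "long_exon")

# modifiers the literature names but does not quantify; surfaced verbatim in
# confidence_note where relevant, never computed
_UNQUANTIFIED = "last exon size, re-initiation of transcription, splice site rescue"


@dataclass(frozen=True)
class NmdVerdict:
    fate: str  # TRIGGER | INTERMEDIATE | ESCAPE
    rules_fired: tuple[str, ...]
    measurements: dict = field(compare=False)
    confidence_note: str = field(default="", compare=False)

    def __post_init__(self):
        if self.fate not in {"TRIGGER", "INTERMEDIATE", "ESCAPE"}:
            raise ValidationError(f"unknown NMD fate '{self.fate}'")
        if self.fate == "ESCAPE" and not set(self.rules_fired) & set(ESCAPE_RULES):
            raise ValidationError("ESCAPE requires an escape rule")
        if self.fate == "TRIGGER" and tuple(self.rules_fired) != ("none",):
            raise ValidationError("TRIGGER must fire no rule")
        if self.fate == "INTERMEDIATE" and not (
            set(self.rules_fired) & set(ATTENUATION_RULES)
        ):
            raise ValidationError("INTERMEDIATE requires an attenuation rule")


def classify_nmd(
    loc: ExonLocation,
    ptc_cds_pos: int,
    model: TranscriptModel,
    cfg: NmdRuleConfig | None = None,
) -> NmdVerdict:
    """Classify the NMD fate of a PTC whose stop codon starts at
    ``ptc_cds_pos`` (reference-CDS coordinate) and sits at ``loc``.

    ``loc`` must have been derived from the same model/position; this is
    re-checked and an inconsistency raises ValidationError.
    """
    cfg = cfg or NmdRuleConfig()
    check = locate_cds_pos(model, ptc_cds_pos)
    if check != loc:
        raise ValidationError(
            f"ExonLocation does not match cds_pos {ptc_cds_pos} on "
            f"{model.transcript_id}"
        )

    notes: list[str] = []
    # stop codon straddling a junction: assigned to the first-nt exon
    last_nt = min(ptc_cds_pos + 2, model.cds_len)
    if locate_cds_pos(model, last_nt).exon_rank != loc.exon_rank:
        notes.append(
            "stop codon straddles an exon junction; assigned to the exon "
            "containing its first nucleotide"
        )

    escape = []
    if model.n_exons == 1:
        escape.append("single_exon")
    if loc.is_last_exon and model.n_exons > 1:
        escape.append("last_exon")
    if (
        model.n_exons > 1
        and loc.exon_rank == model.n_exons - 1
        and loc.dist_to_last_junction is not None
        and loc.dist_to_last_junction <= cfg.penultimate_window_nt
    ):
        escape.append("penultimate_50nt")
    if escape:
        notes.append(
            f"escape prediction from transcript geometry; other modifiers "
            f"({_UNQUANTIFIED}) are not modelled"
        )
        return NmdVerdict(
            "ESCAPE", tuple(escape), _measure(loc, ptc_cds_pos), "; ".join(notes)
        )

    attenuation = []
    if ptc_cds_pos <= cfg.start_proximal_nt:
        attenuation.append("start_proximal")
        notes.append(
            "start-proximal stop codons may not cause degradation; "
            "re-initiation of translation can rescue expression — possible escape"
        )
    if loc.exon_length > cfg.long_exon_nt:
        attenuation.append("long_exon")
        notes.append(
            f"PTC exon length {loc.exon_length} nt exceeds "
            f"{cfg.long_exon_nt} nt; reduced NMD efficiency"
        )
    if attenuation:
        return NmdVerdict(
            "INTERMEDIATE",
            tuple(attenuation),
            _measure(loc, ptc_cds_pos),
            "; ".join(notes),
        )

    return NmdVerdict("TRIGGER", ("none",), _measure(loc, ptc_cds_pos), "; ".join(notes))


def _measure(loc: ExonLocation, ptc_cds_pos: int) -> dict:
    return {
        "ptc_exon_rank": loc.exon_rank,
        "ptc_exon_length": loc.exon_length,
        "dist_to_last_junction": loc.dist_to_last_junction,
        "cds_pos_of_ptc": ptc_cds_pos,
        "ptc_codon": cds_pos_to_codon(ptc_cds_pos),
    }


# ---------------------------------------------------------------------------
# boundary sweeps


@dataclass(frozen=True)
class SweepResult:
    """Empirical flip point of one rule.

    boundary is the last measured value on the rule's "active" side and
    first_beyond the first value observed past it:
    penultimate_50nt — max distance-to-last-junction still ESCAPE (50);
    long_exon — max exon length at which the rule does NOT fire (400);
    start_proximal — max variant CDS position at which the rule fires (150).
    """

    rule: str
    boundary: int
    first_beyond: int
    n_classified: int


def sweep_boundary(
    rule: str,
    cfg: NmdRuleConfig | None = None,
) -> SweepResult:
    """Exhaustively place nonsense PTCs on synthetic transcripts and find
    where the named rule's behaviour flips.

    The stop codon's first nucleotide is frame-locked to CDS positions
    ≡ 1 (mod 3), so the penultimate-exon sweep uses three templates whose
    last junction is shifted by 0/1/2 nt — across them every distance value
    lands on a codon start. The start-proximal sweep is indexed by the
    swept *variant* position (a 3rd-position change at c.150 creates a stop
    starting at 148, inside the window), which is the only coordinate on
    which the flip is observable at 1-nt resolution.
    """
    from .consequence import apply_variant, translate_and_scan
    from .hgvs import CodingVariant
    from .fixtures import (
        STOP_REACHABLE_CODONS as STOP_REACHABLE,
        make_transcript,
        ptc_sweep,
    )

    cfg = cfg or NmdRuleConfig()

    def classify_variant(model, v):
        mut = apply_variant(model, v)
        cons = translate_and_scan(model.cds_seq, mut, v, utr3=model.utr3_seq)
        assert cons.consequence_class == "nonsense"
        loc = locate_cds_pos(model, cons.ptc_cds_pos)
        return cons, classify_nmd(loc, cons.ptc_cds_pos, model, cfg)

    if rule == "penultimate_50nt":
        fired: dict[int, bool] = {}  # dist_to_last_junction -> rule fired
        n = 0
        w = cfg.penultimate_window_nt
        for phase in range(3):
            # long penultimate exon so distances both sides of the window
            # are reachable; phase shifts the junction against the codon grid
            model = make_transcript(
                [120, max(3 * w + 60, 120) + phase, 210],
                seed=11 + phase,
                codon_pool=STOP_REACHABLE,
            )
            for _cds_pos, v in ptc_sweep(model):
                cons, verdict = classify_variant(model, v)
                loc = locate_cds_pos(model, cons.ptc_cds_pos)
                if loc.exon_rank != model.n_exons - 1:
                    continue
                d = loc.dist_to_last_junction
                fired[d] = "penultimate_50nt" in verdict.rules_fired
                n += 1
        hits = [d for d, f in fired.items() if f]
        if not hits:
            raise NoBoundaryError("penultimate_50nt never fired on templates")
        boundary = max(hits)
        beyond = [d for d in fired if d > boundary]
        if not beyond:
            raise NoBoundaryError("no observation beyond the penultimate window")
        return SweepResult(rule, boundary, min(beyond), n)

    if rule == "long_exon":
        t = cfg.long_exon_nt
        fired: dict[int, bool] = {}  # exon length -> rule fired
        n = 0
        for length in range(max(t - 9, 30), t + 12):
            # PTC mid exon 2; exon 1 long enough to defeat start-proximal
            mid_codon = (cfg.start_proximal_nt + 210 + length // 2) // 3
            model = make_transcript(
                [cfg.start_proximal_nt + 210, length, 240, 240, 240],
                seed=23,
                codon_constraints={mid_codon: "TAC"},
            )
            v_pos = 3 * mid_codon  # 3rd-position TAC>TAA change
            v = CodingVariant("substitution", v_pos, v_pos, ref_seq="C", alt_seq="A")
            cons, verdict = classify_variant(model, v)
            loc = locate_cds_pos(model, cons.ptc_cds_pos)
            assert loc.exon_rank == 2 and loc.exon_length == length
            fired[length] = "long_exon" in verdict.rules_fired
            n += 1
        quiet = [x for x, f in fired.items() if not f]
        active = [x for x, f in fired.items() if f]
        if not active:
            raise NoBoundaryError("long_exon never fired on templates")
        boundary = max(q for q in quiet if q < min(active))
        return SweepResult(rule, boundary, min(active), n)

    if rule == "start_proximal":
        # codon at the window edge gets a 3rd-position-reachable stop so the
        # flip is observable at exactly the configured threshold
        s = cfg.start_proximal_nt
        edge_codon = s // 3 if s % 3 == 0 else s // 3 + 1
        constraints = {edge_codon: "TAC", edge_codon + 1: "CAA"}
        model = make_transcript(
            [90, 90, 120, 120, 150],
            seed=31,
            codon_constraints=constraints,
            codon_pool=STOP_REACHABLE,
        )
        fired: dict[int, bool] = {}  # variant CDS position -> rule fired
        n = 0
        for cds_pos, v in ptc_sweep(model):
            _cons, verdict = classify_variant(model, v)
            fired[cds_pos] = "start_proximal" in verdict.rules_fired
            n += 1
        hits = [p for p, f in fired.items() if f]
        if not hits:
            raise NoBoundaryError("start_proximal never fired on template")
        boundary = max(hits)
        beyond = [p for p in fired if p > boundary]
        if not beyond:
            raise NoBoundaryError("no observation beyond the start-proximal window")
        return SweepResult(rule, boundary, min(beyond), n)

    raise ValidationError(f"unknown sweep rule '{rule}'")
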