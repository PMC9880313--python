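"""Corrected annotation records and their serializations.

The point of the whole tool lives here: a PTC variant on a transcript that
NMD degrades is not a truncated protein but an absent one, so the record
carries VariO:0240 *missing protein* / VariO:0245 *missing RNA* with
``r.(0)``/``p.(0)``, while an NMD-escaping PTC keeps a truncation
annotation (VariO:0015, a Ter/fs-Ter protein string). A record never
carries both 0240 and 0015 — the two claims are mutually exclusive.

INTERMEDIATE (attenuated-NMD) records keep the truncation-form HGVS plus a
warning caveat rather than claiming p.(0): partial degradation means some
protein may exist, so the less destructive claim is emitted. VariO has no
term for a partially degraded transcript, so vario_rna stays unset there
with an explanatory caveat.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .consequence import MrnaConsequence, plof_tag
from .errors import StopfateError, ValidationError
from .hgvs import CodingVariant, ProteinAnnotation, format_p, format_r
from .nmd import NmdVerdict
from .transcript import TranscriptModel
from .unsense import SYNONYMY_CAVEAT, UnsenseFlag

VARIO_MISSING_PROTEIN = "VariO:0240 missing protein"
VARIO_MISSING_RNA = "VariO:0245 missing RNA"
VARIO_TRUNCATION = "VariO:0015 protein truncation"

PREDICTION_CAVEAT = (
    "annotation is a computational prediction from transcript geometry, "
    "not experimental evidence; RNA/protein confirmation is required"
)
INTERMEDIATE_CAVEAT = "partial NMD predicted; residual expression possible"
NO_PARTIAL_RNA_TERM_CAVEAT = (
    "VariO has no term for a partially degraded transcript; RNA-level "
    "annotation left unset"
)

TSV_COLUMNS = [
    "variant", "transcript", "consequence", "nmd_fate", "rules",
    "vario_rna", "vario_protein", "hgvs_r", "hgvs_p", "plof",
    "unsense_candidate", "caveats", "error",
]


@dataclass(frozen=True)
class AnnotationRecord:
    variant_raw: str
    transcript_id: str
    consequence_class: str = ""
    nmd_fate: str = ""
    rules_fired: tuple[str, ...] = ()
    vario_rna: str | None = None
    vario_protein: str | None = None
    hgvs_r: str = ""
    hgvs_p: str = ""
    plof: str = "none"
    unsense_candidate: bool = False
    caveats: tuple[str, ...] = ()
    error: str = ""

    def __post_init__(self):
        both = {VARIO_MISSING_PROTEIN, VARIO_TRUNCATION}
        carried = {self.vario_rna, self.vario_protein}
        if both <= carried:
            raise ValidationError(
                "a record cannot claim both missing protein (0240) and "
                "truncation (0015)"
            )


def error_record(variant_raw: str, transcript_id: str, error: str) -> AnnotationRecord:
    """Row for a variant that could not be annotated (never dropped)."""
    return AnnotationRecord(variant_raw, transcript_id, error=error)


def _truncation_protein(consequence: MrnaConsequence, predicted: bool) -> str:
    if consequence.consequence_class == "nonsense":
        ann = ProteinAnnotation(
            "substitution_ter",
            first_affected_codon=consequence.first_affected_codon,
            ref_residue=consequence.ref_residue,
            predicted=predicted,
        )
    else:
        ann = ProteinAnnotation(
            "frameshift_ter",
            first_affected_codon=consequence.first_affected_codon,
            ref_residue=consequence.ref_residue,
            new_residue=consequence.new_residue,
            ter_offset=consequence.ter_offset,
            predicted=predicted,
        )
    return format_p(ann)


def emit(
    consequence: MrnaConsequence,
    verdict: NmdVerdict | None,
    model: TranscriptModel,
    v: CodingVariant,
    unsense: UnsenseFlag | None = None,
    asserted: bool = False,
    splice_offset: int | None = None,
) -> AnnotationRecord:
    """Fold consequence + NMD verdict (+ optional unsense flag) into one
    corrected annotation record.

    ``verdict`` must be present exactly when the consequence carries a PTC.
    ``asserted`` switches r./p. strings from the predicted (parenthesised)
    forms to the evidence-backed ones.
    """
    if consequence.has_ptc and verdict is None:
        raise ValidationError("PTC consequence requires an NMD verdict")
    if not consequence.has_ptc and verdict is not None:
        raise ValidationError("NMD verdict supplied for a PTC-free consequence")

    predicted = not asserted
    caveats: list[str] = []
    vario_rna = vario_protein = None
    tag = plof_tag(v, consequence, splice_offset=splice_offset)
    cls = consequence.consequence_class

    if consequence.has_ptc:
        caveats.append(PREDICTION_CAVEAT)
        if verdict.confidence_note:
            caveats.append(verdict.confidence_note)
        if verdict.fate == "TRIGGER":
            vario_rna = VARIO_MISSING_RNA
            vario_protein = VARIO_MISSING_PROTEIN
            hgvs_r = format_r(degraded=True, predicted=predicted)
            hgvs_p = format_p(
                ProteinAnnotation("no_protein_predicted", predicted=predicted)
            )
        elif verdict.fate == "ESCAPE":
            vario_protein = VARIO_TRUNCATION
            hgvs_r = format_r(variant=v, predicted=predicted)
            hgvs_p = _truncation_protein(consequence, predicted)
        else:  # INTERMEDIATE
            vario_protein = VARIO_TRUNCATION
            hgvs_r = format_r(variant=v, predicted=predicted)
            hgvs_p = _truncation_protein(consequence, predicted)
            caveats.append(INTERMEDIATE_CAVEAT)
            caveats.append(NO_PARTIAL_RNA_TERM_CAVEAT)
        fate = verdict.fate
        rules = tuple(verdict.rules_fired)
    else:
        fate, rules = "", ()
        hgvs_r = format_r(variant=v if cls != "no_change" else None,
                          predicted=predicted)
        if cls in {"synonymous", "no_change"}:
            hgvs_p = format_p(ProteinAnnotation("unchanged", predicted=predicted))
            if cls == "synonymous":
                caveats.append(SYNONYMY_CAVEAT)
        elif cls == "missense":
            hgvs_p = format_p(
                ProteinAnnotation(
                    "missense",
                    first_affected_codon=consequence.first_affected_codon,
                    ref_residue=consequence.ref_residue,
                    new_residue=consequence.new_residue,
                    predicted=predicted,
                )
            )
        else:
            # inframe_indel / stop_lost / frameshift_no_ptc: no validated
            # protein-level description is generated
            hgvs_p = "p.?"
            if cls == "stop_lost":
                caveats.append(
                    "reference stop codon lost; extension not modelled and "
                    "not fed to NMD rules"
                )
            elif cls == "frameshift_no_ptc":
                caveats.append(
                    "shifted reading frame reaches the transcript 3' end "
                    "without a stop codon (non-stop transcript)"
                )
            else:
                caveats.append(
                    "in-frame indel; protein-level description not generated"
                )

    unsense_candidate = False
    if unsense is not None and unsense.flagged:
        unsense_candidate = True
        caveats.append(
            f"candidate unsense variant ({unsense.vario}): synonymous "
            f"substitution {unsense.dist_to_nearest_junction} nt from an "
            f"exon junction; splicing effect possible"
        )

    if tag.tag != "none":
        caveats.append(tag.caveat)

    return AnnotationRecord(
        variant_raw=v.raw or v.kind,
        transcript_id=model.transcript_id,
        consequence_class=cls,
        nmd_fate=fate,
        rules_fired=rules,
        vario_rna=vario_rna,
        vario_protein=vario_protein,
        hgvs_r=hgvs_r,
        hgvs_p=hgvs_p,
        plof=tag.tag,
        unsense_candidate=unsense_candidate,
        caveats=tuple(caveats),
    )


# ---------------------------------------------------------------------------
# serialization


def _to_row(r: AnnotationRecord) -> dict:
    return {
        "variant": r.variant_raw,
        "transcript": r.transcript_id,
        "consequence": r.consequence_class,
        "nmd_fate": r.nmd_fate,
        "rules": ",".join(r.rules_fired),
        "vario_rna": r.vario_rna or "",
        "vario_protein": r.vario_protein or "",
        "hgvs_r": r.hgvs_r,
        "hgvs_p": r.hgvs_p,
        "plof": r.plof,
        "unsense_candidate": "yes" if r.unsense_candidate else "no",
        "caveats": " | ".join(r.caveats),
        "error": r.error,
    }


def _from_row(row: dict) -> AnnotationRecord:
    return AnnotationRecord(
        variant_raw=row["variant"],
        transcript_id=row["transcript"],
        consequence_class=row["consequence"],
        nmd_fate=row["nmd_fate"],
        rules_fired=tuple(x for x in row["rules"].split(",") if x),
        vario_rna=row["vario_rna"] or None,
        vario_protein=row["vario_protein"] or None,
        hgvs_r=row["hgvs_r"],
        hgvs_p=row["hgvs_p"],
        plof=row["plof"],
        unsense_candidate=row["unsense_candidate"] == "yes",
        caveats=tuple(x for x in row["caveats"].split(" | ") if x),
        error=row["error"],
    )


def write_tsv(records: list[AnnotationRecord], path: str | Path) -> None:
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=TSV_COLUMNS, delimiter="\t", lineterminator="\n"
            )
            writer.writeheader()
            for r in records:
                writer.writerow(_to_row(r))
    except OSError as exc:
        raise StopfateError(f"cannot write TSV to {path}: {exc}") from exc


def read_tsv(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    try:
        with path.open(newline="") as fh:
            return [_from_row(row) for row in csv.DictReader(fh, delimiter="\t")]
    except OSError as exc:
        raise StopfateError(f"cannot read TSV from {path}: {exc}") from exc


def _info_value(r: AnnotationRecord) -> str:
    def acc(term: str | None) -> str:
        return term.split(" ", 1)[0] if term else "."

    fields = [
        r.consequence_class or ".",
        r.nmd_fate or ".",
        ",".join(r.rules_fired) or ".",
        acc(r.vario_rna),
        acc(r.vario_protein),
        r.hgvs_r or ".",
        r.hgvs_p or ".",
        r.plof or ".",
    ]
    return "|".join(f.replace(" ", "_").replace(";", ",") for f in fields)


STOPFATE_HEADER = (
    '##INFO=<ID=STOPFATE,Number=1,Type=String,Description="NMD-aware '
    "re-annotation: consequence|nmd_fate|rules|vario_rna|vario_protein|"
    'hgvs_r|hgvs_p|plof">'
)


def write_vcf_info(
    records: list[AnnotationRecord], in_vcf: str | Path, out_vcf: str | Path
) -> None:
    """Copy a VCF, adding one STOPFATE INFO key per record.

    ``records`` must be ordered like the VCF body rows (the VCF annotation
    pipeline produces them that way)."""
    import pysam

    try:
        vin = pysam.VariantFile(str(in_vcf))
    except (OSError, ValueError) as exc:
        raise StopfateError(f"cannot read VCF {in_vcf}: {exc}") from exc
    header = vin.header.copy()
    header.add_line(STOPFATE_HEADER)
    rows = list(vin)
    vin.close()
    if len(rows) != len(records):
        raise ValidationError(
            f"{len(records)} records for {len(rows)} VCF rows in {in_vcf}"
        )
    try:
        with pysam.VariantFile(str(out_vcf), "w", header=header) as vout:
            for row, rec in zip(rows, records):
                row.translate(header)
                row.info["STOPFATE"] = _info_value(rec)
                vout.write(row)
    except OSError as exc:
        raise StopfateError(f"cannot write VCF to {out_vcf}: {exc}") from exc
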