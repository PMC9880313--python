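"""End-to-end annotation: HGVS/VCF input → corrected AnnotationRecords.

The CLI is a thin shell over these functions; library users call them
directly."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from . import unsense
from .consequence import apply_variant, plof_tag, translate_and_scan
from .emit import AnnotationRecord, emit, error_record
from .errors import StopfateError
from .hgvs import CodingVariant, parse_c
from .nmd import classify_nmd
from .transcript import NmdRuleConfig, TranscriptModel, locate_cds_pos, reverse_complement


def annotate_variant(
    model: TranscriptModel,
    variant: CodingVariant | str,
    cfg: NmdRuleConfig | None = None,
    unsense_window_nt: int = 3,
    asserted: bool = False,
) -> AnnotationRecord:
    """Annotate one coding variant on one transcript.

    Accepts a parsed CodingVariant or a raw HGVS c. string. Any failure
    (parse error, unsupported region, reference mismatch, N in a codon)
    comes back as an error record rather than an exception, so batch runs
    never silently drop a variant.
    """
    raw = variant if isinstance(variant, str) else (variant.raw or "")
    try:
        v = parse_c(variant) if isinstance(variant, str) else variant
        mutated = apply_variant(model, v)
        consequence = translate_and_scan(
            model.cds_seq, mutated, v, utr3=model.utr3_seq
        )
        verdict = None
        if consequence.has_ptc:
            loc = locate_cds_pos(model, consequence.ptc_cds_pos)
            verdict = classify_nmd(loc, consequence.ptc_cds_pos, model, cfg)
        flag = unsense.screen(v, consequence, model, window_nt=unsense_window_nt)
        return emit(
            consequence, verdict, model, v, unsense=flag, asserted=asserted
        )
    except StopfateError as exc:
        return error_record(raw or str(variant), model.transcript_id, f"{type(exc).__name__}: {exc}")


def annotate_lines(
    model: TranscriptModel,
    lines: list[str],
    models_by_id: dict[str, TranscriptModel] | None = None,
    **kwargs,
) -> list[AnnotationRecord]:
    """Annotate a plain-text variant list.

    Each non-empty, non-comment line is either an HGVS c. expression or the
    two-column form ``transcript_id<TAB>hgvs`` (resolved against
    models_by_id when given)."""
    records = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        target = model
        expr = line
        if "\t" in line:
            tid, expr = line.split("\t", 1)
            if models_by_id and tid in models_by_id:
                target = models_by_id[tid]
            elif tid != model.transcript_id:
                records.append(
                    error_record(line, tid, f"NotFoundError: unknown transcript '{tid}'")
                )
                continue
        records.append(annotate_variant(target, expr, **kwargs))
    return records


# ---------------------------------------------------------------------------
# VCF input


def vcf_site_to_coding_variant(
    model: TranscriptModel, pos: int, ref: str, alt: str
) -> tuple[CodingVariant | None, int | None, str | None]:
    """Convert one genomic REF/ALT to a CDS variant on ``model``.

    Returns (variant, splice_offset, error): exactly one of the three is
    meaningful. SNVs work on both strands (alleles reverse-complemented on
    minus-strand transcripts); indels are converted on plus-strand
    transcripts only. Positions at intronic offsets ±1/±2 return a
    splice_offset for essential-splice tagging.
    """
    raw = f"g.{pos}{ref}>{alt}"
    if len(ref) == 1 and len(alt) == 1:
        tx, off = model.genomic_to_tx(pos)
        if tx is None:
            if abs(off) <= 2:
                return None, off, None
            return None, None, f"intronic position (offset {off:+d}); not annotated"
        cds = tx - model.cds_start_tx + 1
        if not 1 <= cds <= model.cds_len:
            return None, None, "position in UTR; outside the supported c. subset"
        r, a = (ref, alt) if model.strand == "+" else (
            reverse_complement(ref), reverse_complement(alt)
        )
        return (
            CodingVariant("substitution", cds, cds, ref_seq=r, alt_seq=a, raw=raw),
            None,
            None,
        )

    if model.strand != "+":
        return None, None, "indel on a minus-strand transcript; not converted"
    # left-anchored VCF indel: strip the shared leading base
    if ref[0] != alt[0]:
        # multi-nt substitution block: treat as delins over the span
        start_g = pos
        del_len = len(ref)
        ins = alt
    else:
        start_g = pos + 1
        del_len = len(ref) - 1
        ins = alt[1:]
    if del_len == 0 and not ins:
        return None, None, "REF == ALT; nothing to annotate"
    tx_start, off = model.genomic_to_tx(start_g if del_len else pos)
    if tx_start is None:
        if abs(off) <= 2:
            return None, off, None
        return None, None, f"intronic indel (offset {off:+d}); not annotated"
    cds_start = tx_start - model.cds_start_tx + 1
    if del_len:
        end_g = start_g + del_len - 1
        tx_end, off_end = model.genomic_to_tx(end_g)
        if tx_end is None:
            if off_end is not None and abs(off_end) <= 2:
                return None, off_end, None
            return None, None, "indel crosses an exon boundary; not converted"
        cds_end = tx_end - model.cds_start_tx + 1
        if not (1 <= cds_start and cds_end <= model.cds_len):
            return None, None, "indel extends outside the CDS; not annotated"
        if ins:
            kind, alt_seq = "delins", ins
        else:
            kind, alt_seq = "deletion", ""
        return (
            CodingVariant(kind, cds_start, cds_end, alt_seq=alt_seq, raw=raw),
            None,
            None,
        )
    # pure insertion after `pos`
    if not 1 <= cds_start < model.cds_len:
        return None, None, "insertion outside the CDS; not annotated"
    return (
        CodingVariant(
            "insertion", cds_start, cds_start + 1, alt_seq=ins, raw=raw
        ),
        None,
        None,
    )


def annotate_vcf(
    model: TranscriptModel,
    in_vcf: str | Path,
    cfg: NmdRuleConfig | None = None,
    unsense_window_nt: int = 3,
    asserted: bool = False,
) -> list[AnnotationRecord]:
    """Annotate every row of a VCF against one transcript model (GTF-loaded,
    so genomic coordinates are available). One record per row, in row order,
    multi-allelic rows annotated on their first ALT only (with a caveat)."""
    import pysam

    records = []
    with pysam.VariantFile(str(in_vcf)) as vcf:
        for row in vcf:
            raw = f"{row.chrom}:{row.pos}:{row.ref}>{','.join(row.alts or ['.'])}"
            if not row.alts:
                records.append(error_record(raw, model.transcript_id, "no ALT allele"))
                continue
            try:
                v, splice_off, err = vcf_site_to_coding_variant(
                    model, row.pos, row.ref, row.alts[0]
                )
            except StopfateError as exc:
                records.append(
                    error_record(raw, model.transcript_id, f"{type(exc).__name__}: {exc}")
                )
                continue
            if err:
                records.append(error_record(raw, model.transcript_id, err))
                continue
            if splice_off is not None:
                tag = plof_tag(None, None, splice_offset=splice_off)
                records.append(
                    AnnotationRecord(
                        variant_raw=raw,
                        transcript_id=model.transcript_id,
                        consequence_class="essential_splice_site",
                        plof=tag.tag,
                        caveats=(
                            f"essential splice-site nucleotide (intronic "
                            f"offset {splice_off:+d}); transcript-level effect "
                            f"not computed",
                            tag.caveat,
                        ),
                    )
                )
                continue
            rec = annotate_variant(
                model, v, cfg=cfg, unsense_window_nt=unsense_window_nt,
                asserted=asserted,
            )
            if len(row.alts) > 1:
                rec = replace(
                    rec,
                    caveats=rec.caveats
                    + ("multi-allelic site: first ALT annotated only",),
                )
            records.append(rec)
    return records
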