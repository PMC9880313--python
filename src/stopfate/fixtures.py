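"""Synthetic transcript fixtures.

Everything downstream of this module is testable with no downloads: a
seeded generator produces multi-exon protein-coding transcripts with
controllable exon counts/lengths and CDS placement, and two bundled
fixtures encode the shapes of the worked examples used throughout the
docs — a dystrophin-like transcript (79 exons, 3,685 residues, CDS
11,058 nt including the stop) and a Bruton-tyrosine-kinase-like transcript
(19 exons, variant locus in exon 8).

Both bundled fixtures are synthetic stand-ins: exon sizes and sequence are
generated, with only the codons the worked examples constrain pinned
(Trp24/TGG on the DMD-like model; Leu198/CTA + Lys199/AAA on the BTK-like
model so that c.592_595delinsCTAACTACATA yields Thr at 199 and a stop three
codons into the shifted frame).
"""

from __future__ import annotations

import json
import random
from importlib import resources
from pathlib import Path
from typing import Iterator

from .errors import ValidationError
from .hgvs import CodingVariant
from .transcript import (
    STOP_CODONS,
    Exon,
    TranscriptModel,
    fixture_from_dict,
    fixture_to_dict,
)

SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS
)

def _single_subs(codon: str) -> list[str]:
    out = []
    for i in range(3):
        for alt in "ACGT":
            if alt != codon[i]:
                out.append(codon[:i] + alt + codon[i + 1 :])
    return out


#: sense codons one substitution away from a stop; sweep templates fill
#: with these so every codon of the fill admits a nonsense variant
STOP_REACHABLE_CODONS = sorted(
    c for c in SENSE_CODONS if any(s in STOP_CODONS for s in _single_subs(c))
)


def make_transcript(
    exon_lengths: list[int],
    cds_span: tuple[int, int] | None = None,
    seed: int = 0,
    *,
    codon_constraints: dict[int, str] | None = None,
    codon_pool: list[str] | None = None,
    transcript_id: str | None = None,
) -> TranscriptModel:
    """Generate a deterministic synthetic transcript.

    The CDS starts with ATG, ends with a single stop codon, and contains no
    internal stop; interior codons are drawn from ``codon_pool`` (default:
    all 61 sense codons) by a generator seeded with ``seed``, so the same
    arguments always rebuild the identical model. ``codon_constraints``
    pins specific interior codons ({index: codon}), which is how the worked
    examples place their mutable sites.

    cds_span defaults to (1, largest multiple of 3 ≤ transcript length),
    leaving any remainder as 3'UTR.
    """
    total = sum(exon_lengths)
    if any(n < 1 for n in exon_lengths):
        raise ValidationError("exon lengths must be positive")
    if cds_span is None:
        cds_span = (1, total - total % 3)
    cds_start, cds_end = cds_span
    cds_len = cds_end - cds_start + 1
    if not (1 <= cds_start < cds_end <= total):
        raise ValidationError(f"CDS span {cds_span} impossible for length {total}")
    if cds_len % 3:
        raise ValidationError(f"CDS length {cds_len} not divisible by 3")
    n_codons = cds_len // 3
    if n_codons < 3:
        raise ValidationError("CDS must hold at least start, one codon, and stop")

    rng = random.Random(seed)
    pool = codon_pool or SENSE_CODONS
    if set(pool) & STOP_CODONS:
        raise ValidationError("codon_pool must not contain stop codons")
    constraints = dict(codon_constraints or {})
    for idx, codon in constraints.items():
        if not 2 <= idx <= n_codons - 1:
            raise ValidationError(
                f"constraint codon {idx} outside interior 2..{n_codons - 1}"
            )
        if len(codon) != 3 or set(codon) - set("ACGT") or codon in STOP_CODONS:
            raise ValidationError(f"constraint {idx}: '{codon}' is not a sense codon")

    codons = ["ATG"]
    for i in range(2, n_codons):
        codons.append(constraints.get(i) or rng.choice(pool))
    codons.append("TAA")
    cds = "".join(codons)

    utr5 = "".join(rng.choice("ACGT") for _ in range(cds_start - 1))
    utr3 = "".join(rng.choice("ACGT") for _ in range(total - cds_end))
    tid = transcript_id or f"SYN_{len(exon_lengths)}x_{total}_s{seed}"
    return TranscriptModel(
        transcript_id=tid,
        strand="+",
        exons=[Exon(rank=i + 1, length=n) for i, n in enumerate(exon_lengths)],
        cds_start_tx=cds_start,
        cds_end_tx=cds_end,
        spliced_seq=utr5 + cds + utr3,
    )


# ---------------------------------------------------------------------------
# worked-example fixtures

#: dystrophin isoform 1 shape: 3,685 residues + stop = 3,686 codons,
#: CDS 11,058 nt, 79 exons; codon 24 pinned to TGG so c.72G>A creates TGA
DMD_LIKE_EXONS = [200] + [140] * 77 + [178]
DMD_LIKE_SEED = 199


def dmd_like() -> TranscriptModel:
    return make_transcript(
        DMD_LIKE_EXONS,
        (1, 11058),
        seed=DMD_LIKE_SEED,
        codon_constraints={24: "TGG"},
        transcript_id="DMD_LIKE",
    )


#: Bruton tyrosine kinase shape: 659 residues + stop = 660 codons,
#: CDS 1,980 nt, 19 exons, c.592_595 inside exon 8 (tx 561..680); codons
#: 198/199 pinned so the delins reads ...CTA|ACT|ACA|TAA... (Thr199, fs*3)
BTK_LIKE_EXONS = [80] * 7 + [120] + [120] * 10 + [160]
BTK_LIKE_SEED = 593


def btk_like() -> TranscriptModel:
    return make_transcript(
        BTK_LIKE_EXONS,
        (1, 1980),
        seed=BTK_LIKE_SEED,
        codon_constraints={198: "CTA", 199: "AAA"},
        transcript_id="BTK_LIKE",
    )


_BUNDLED = {"dmd_like": dmd_like, "btk_like": btk_like}


def load_bundled(name: str) -> TranscriptModel:
    """Load a committed worked-example fixture ('dmd_like' or 'btk_like')."""
    if name not in _BUNDLED:
        raise ValidationError(f"no bundled fixture '{name}'")
    ref = resources.files("stopfate") / "data" / f"{name}.json"
    return fixture_from_dict(json.loads(ref.read_text()))


def write_bundled(outdir: str | Path) -> list[Path]:
    """Regenerate the bundled fixture JSONs (tamper-evidence: tests check
    the committed files equal the generator output bit for bit)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, builder in _BUNDLED.items():
        path = outdir / f"{name}.json"
        path.write_text(
            json.dumps(fixture_to_dict(builder()), indent=0) + "\n"
        )
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# nonsense sweeps


def stop_substitutions(codon: str, codon_index: int) -> list[CodingVariant]:
    """All single-nt substitutions turning ``codon`` (1-based index within
    the CDS) into a stop codon."""
    out = []
    for i in range(3):
        for alt in "ACGT":
            if alt == codon[i]:
                continue
            mutant = codon[:i] + alt + codon[i + 1 :]
            if mutant in STOP_CODONS:
                pos = 3 * (codon_index - 1) + i + 1
                out.append(
                    CodingVariant(
                        "substitution", pos, pos, ref_seq=codon[i], alt_seq=alt
                    )
                )
    return out


def ptc_sweep(model: TranscriptModel) -> Iterator[tuple[int, CodingVariant]]:
    """Yield every single-nt substitution that converts an interior codon
    of ``model`` into a stop, as (variant CDS position, variant).

    The start codon and the reference stop codon are excluded. Codons with
    no reachable stop are skipped (count them with `ptc_sweep_skipped`).
    """
    cds = model.cds_seq
    for k in range(2, model.n_codons):
        codon = cds[3 * (k - 1) : 3 * k]
        for v in stop_substitutions(codon, k):
            yield v.start, v


def ptc_sweep_skipped(model: TranscriptModel) -> int:
    """Interior codons from which no single-nt substitution reaches a stop."""
    cds = model.cds_seq
    skipped = 0
    for k in range(2, model.n_codons):
        codon = cds[3 * (k - 1) : 3 * k]
        if not stop_substitutions(codon, k):
            skipped += 1
    return skipped
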