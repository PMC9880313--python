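# stopfate

NMD-aware re-annotation of premature-termination-codon (PTC) variants.

## The problem

Standard variant annotation pipelines describe a nonsense or frameshift
variant by the protein it *would* produce — `p.Trp24*`, `p.Lys199Thrfs*3` —
as if a truncated polypeptide were the outcome. For most PTC variants it is
not: nonsense-mediated decay (NMD) recognises the premature stop through
the exon-junction complexes left on the spliced mRNA and degrades the
transcript, so the real outcome is *no* RNA and *no* protein. Calling such
a variant a "truncation" misleads downstream interpretation; clinically it
is a knock-out-type allele.

`stopfate` re-annotates coding variants accordingly. For each
PTC-introducing variant it decides, from transcript geometry, whether the
predicted fate is degradation (missing RNA/missing protein) or escape (a
genuinely truncated protein), and emits corrected HGVS (`r.(0)`/`p.(0)` vs
Ter/fs-Ter forms) and Variation Ontology terms (VariO:0245 *missing RNA*,
VariO:0240 *missing protein*, VariO:0015 *protein truncation*). It also
flags apparently-synonymous substitutions at splice-critical exonic
positions as candidate *unsense* variants (VariO:0514), and tags
predicted-loss-of-function variant types (stop-gained, frameshift,
essential splice site) with an explicit type-not-effect caveat.

## The rules

A PTC located at CDS position *p*, in exon *e* of *n*, is classified by a
fixed precedence:

1. single-exon transcript → **ESCAPE** (no exon-junction complex);
2. PTC in the last exon → **ESCAPE** (last-exon rule);
3. PTC in the penultimate exon within 50 nt of its 3' end → **ESCAPE**
   (the 50 nt rule);
4. stop codon starting within 150 nt of the start codon → **INTERMEDIATE**
   (start-proximal rule; degradation uncertain, translation re-initiation
   possible);
5. PTC-bearing exon longer than 400 bp → **INTERMEDIATE** (long-exon rule,
   reduced NMD efficiency);
6. otherwise → **TRIGGER** (efficient degradation).

All thresholds are configurable (`--penultimate-window`,
`--start-proximal`, `--long-exon`, or a YAML config). TRIGGER yields
`r.(0)`/`p.(0)` + VariO:0240/0245; ESCAPE keeps the truncation form +
VariO:0015; INTERMEDIATE keeps the truncation form with a
partial-degradation caveat. Parentheses mark predictions; `--asserted`
switches to the evidence-backed `r.0`/`p.0` forms.

## Worked example

Two bundled synthetic fixtures reproduce the canonical cases: a
dystrophin-like transcript (79 exons, 3,685 residues) and a BTK-like
transcript (19 exons, variant locus in exon 8).

```python
from stopfate import annotate_variant, load_bundled

dmd = load_bundled("dmd_like")
print(annotate_variant(dmd, "c.72G>A").nmd_fate)      # INTERMEDIATE
print(annotate_variant(dmd, "c.72G>A").hgvs_p)        # p.(Trp24*)

btk = load_bundled("btk_like")
rec = annotate_variant(btk, "c.592_595delinsCTAACTACATA")
print(rec.consequence_class, rec.nmd_fate)  # frameshift_with_ptc TRIGGER
print(rec.hgvs_r, rec.hgvs_p)               # r.(0) p.(0)
print(rec.vario_protein)                    # VariO:0240 missing protein
```

The first variant creates a stop at codon 24 within 150 nt of the start
codon, so the start-proximal rule fires and the fate is hedged
(INTERMEDIATE): the truncation form is kept but a caveat warns that
expression may be rescued or absent. The second shifts the frame (+7 nt)
mid-transcript, the new stop three codons in is far from every escape
region, and NMD is predicted to destroy the transcript — the naive
`p.(Lys199Thrfs*3)` is replaced by `r.(0)`/`p.(0)`.

From the shell:

```sh
stopfate annotate --transcripts src/stopfate/data/btk_like.json \
    --variants variants.txt --out annotated.tsv
stopfate sweep --out boundaries.json     # empirical 50/400/150 boundaries
stopfate fixtures --outdir fixtures/     # regenerate bundled fixtures
```

VCF input (with a GTF + FASTA transcript source) adds a `STOPFATE` INFO
key to the output VCF.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, by running the package end to end: the stop-codon index of the
dystrophin-like worked example, the first-affected codon of the BTK-like
delins, and the three empirical rule boundaries recovered by exhaustive
nonsense-PTC sweeps on synthetic transcripts (penultimate-exon escape
window, long-exon activation length, start-proximal cutoff). Results are
written as JSON, one entry per quantity.
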