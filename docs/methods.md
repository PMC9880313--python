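# Methods

## Model

`stopfate` treats a protein-coding transcript as a list of exon lengths,
a CDS span in spliced-mRNA coordinates, and the spliced sense-strand
sequence. All computation is done in 1-based, inclusive transcript/CDS
coordinates — the frame of HGVS `c.` descriptions and of every NMD rule,
which are all transcript-relative. Genomic coordinates exist only at
ingestion (GTF/GFF3 + FASTA, or VCF positions) and are converted once;
minus-strand transcripts are reverse-complemented so downstream code never
sees strand.

A coding variant is applied to the CDS as a pure string edit. Reference
and mutant are translated codon-by-codon with the standard genetic code;
the first residue at which the proteins differ is the first affected
codon. For frame-shifting edits the scan for the new stop continues past
the reference stop into the 3'UTR, because a shifted frame does not read
the old stop; if no stop appears before the transcript end the consequence
is `frameshift_no_ptc` (a non-stop transcript) rather than an invented
`fs*N`.

A stop is premature iff its first nucleotide, mapped onto the reference
exon scaffold, lies strictly upstream of the reference stop's first
nucleotide. The mutant→reference mapping shares positions before the edit,
shifts positions after it by the net length change, and collapses
positions inside an inserted segment onto the first edited reference
position. That mapped coordinate is what the NMD rules measure, since the
exon-junction complexes sit on the *reference* exon scaffold.

## NMD classification

Precedence (escape > attenuation > default):

| step | condition | fate | rule name |
|---|---|---|---|
| 1 | single-exon transcript | ESCAPE | `single_exon` |
| 2 | PTC in last exon | ESCAPE | `last_exon` |
| 3 | penultimate exon, ≤ `penultimate_window_nt` from its 3' end | ESCAPE | `penultimate_50nt` |
| 4 | stop starts ≤ `start_proximal_nt` into the CDS | INTERMEDIATE | `start_proximal` |
| 5 | PTC exon longer than `long_exon_nt` | INTERMEDIATE | `long_exon` |
| 6 | otherwise | TRIGGER | `none` |

Defaults: 50 nt, 150 nt, 400 bp. Design choices made where the literature
leaves the procedure open:

- **Precedence order.** The escape rules describe where degradation does
  not occur; the start-proximal and long-exon observations only modulate
  its efficiency. Escape therefore dominates, and attenuation dominates
  the default TRIGGER. All applicable rules of the winning class are
  listed in `rules_fired`.
- **Start-proximal maps to INTERMEDIATE, not ESCAPE.** The rule is hedged
  in the literature ("may not cause degradation"); the verdict says so
  rather than overstating it, and both the threshold and the mapping are
  configurable.
- **Measurement convention for the 50 nt window**: from the *first*
  nucleotide of the stop codon to the 3' end of the penultimate exon,
  inclusive (the last nt of the exon is at distance 1). No standard fixes
  the measurement point; one convention is declared and used everywhere.
- **Junction-straddling stops** are assigned to the exon containing the
  stop's first nucleotide, with a note in `confidence_note`.
- **Single-exon transcripts escape** — without an exon junction downstream
  of the stop there is no EJC-dependent NMD signal.
- Unquantified modifiers (last exon size, re-initiation of transcription,
  splice site rescue) are not modelled; their names appear in
  `confidence_note` so the reader knows what the verdict ignores.

## Annotation semantics

- TRIGGER → `r.(0)`, `p.(0)`, VariO:0245 *missing RNA*, VariO:0240
  *missing protein*. ESCAPE → truncation form (`p.(Trp24*)`,
  `p.(Lys199Thrfs*3)`) with VariO:0015 *protein truncation*. A record
  never carries both 0240 and 0015 (enforced at construction).
- INTERMEDIATE keeps the truncation-form HGVS plus the caveat "partial NMD
  predicted; residual expression possible": partial degradation means some
  protein may exist, so the less destructive claim is made, flagged.
  VariO has no term for a partially degraded transcript, so `vario_rna`
  stays unset there with an explanatory caveat.
- Parenthesised (predicted) forms are the default everywhere; all outputs
  are computational predictions. `--asserted` drops the parentheses for
  evidence-backed records.
- The plof tag (stop-gained / frameshift / essential-splice) is assigned
  from variant *type* only, never from the NMD outcome, and always carries
  the caveat that type is not functional effect.
- Non-PTC consequences pass through: `p.(=)` for synonymous/no-change, a
  simple substitution form for missense, and `p.?` plus an explanatory
  caveat for in-frame indels, stop-loss and non-stop frameshifts, for
  which no validated protein description is generated. Stop-loss is
  classified but not fed to the NMD rules.
- Unsense screening flags synonymous substitutions within 3 exonic nt
  (default) of a splice junction as *candidates* (VariO:0514). Junction
  proximity is the only computable signal here — exonic splice
  enhancer/silencer motifs and miRNA seed sites have no published
  parameters to implement — so the flag never claims an effect, and every
  synonymous call carries the caveat that synonymy is a codon-table
  statement only. Intronic ±1/±2 changes route through the essential-splice
  plof tag (VCF path), not through this screen.

## Synthetic fixtures

The generator builds transcripts with arbitrary exon lengths and CDS
placement: ATG start, a single terminal stop, no internal stop, interior
codons drawn deterministically from a seeded generator. Two bundled
fixtures encode the worked examples at their published geometry:

- **DMD-like**: 79 exons, 3,685 residues (CDS 11,058 nt with stop),
  codon 24 pinned to TGG so `c.72G>A` creates TGA. Exon sizes (200 nt
  first exon, 140 nt internals) are synthetic; only the counts and the
  mutable codon are constrained by the example.
- **BTK-like**: 19 exons, 659 residues, `c.592_595` inside exon 8;
  codons 198/199 pinned to CTA/AAA so the delins reads
  `…CTA|ACT|ACA|TAA…` — Thr at 199, stop three codons into the new frame.

Both are committed as JSON and must match the generator bit-for-bit
(tamper evidence, checked in the tests). They emulate exon/CDS geometry
and single-transcript annotation; they do not emulate real splice-site
sequences, UTR regulation, alternative isoforms or expression level, so a
green test establishes correct rule arithmetic on the stated geometry, not
biological validity on the real genes.

Boundary sweeps place a nonsense substitution at every reachable codon of
synthetic templates and read off where each rule flips. Because a stop
codon's first nucleotide is frame-locked to CDS positions ≡ 1 (mod 3),
the penultimate-window sweep uses three templates whose last junction is
shifted by 0/1/2 nt (every distance lands on a codon start in one of
them), and the start-proximal sweep reports the swept *variant* position —
a 3rd-position change at c.150 creates a stop starting at c.148, inside
the window — which is the only coordinate on which the 150/151 flip is
observable at 1-nt resolution; its template pins the window-edge codon to
TAC to make that change available.

## Numerical/degenerate-input choices

- N bases are allowed in sequence but any codon containing N aborts the
  scan with a typed error — fail loudly rather than guess.
- Intronic offsets (`c.100+2`) and UTR positions parse to a distinct
  unsupported-region error so batch runs report rather than misannotate;
  the CLI emits them as error rows and still exits 0 with a warning count.
- Reference-allele mismatches report expected vs found and never proceed.
- Everything is deterministic: no randomness anywhere in parsing,
  scanning, classification or emission; end-to-end reruns are
  byte-identical (tested).

## Known limitations

- No probabilistic or tissue-specific NMD efficiency; the three-tier fate
  is a geometry rule set, not a learned score.
- One transcript per run; no canonical-transcript selection across a
  multi-transcript annotation set.
- VCF indels are converted on plus-strand transcripts only (minus-strand
  indels are reported as unsupported rather than risk a misconversion);
  HGVS `c.` input, the primary path, is strand-agnostic.
- Alternative translation initiation is surfaced only as a caveat when the
  start-proximal rule fires; it is never modelled.
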