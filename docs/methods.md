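# Methods

This note documents the models behind `txlogic`: what the simulators
emulate, how the analysis chain is defined, which parameters matter, and
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The regulatory model

A unit operation is one transcription factor (TF) paired with one DNA
operator at one position relative to a promoter. TF binding follows the
allosteric phenotype:

| phenotype | binds operator when…       | logic   |
|-----------|----------------------------|---------|
| X⁺        | ligand absent              | BUFFER  |
| Xᴬ        | ligand present             | NOT     |
| Xˢ        | always                     | off     |
| X⁻        | never                      | on      |

Ligand inputs are strictly binary (present/absent at a fixed working
concentration of 10 mM recorded as metadata); no dose–response model is
included.

Positions differ mechanistically. A **core** operator sits between the
−35/−10 promoter hexamers, so a bound TF competes directly with RNA
polymerase; a **proximal** operator sits downstream of −10 and blocks
transcription without that competition. Core units therefore reach tighter
anti-induced states, which the default expression profiles encode (see
below).

### Composition semantics

- An operator is **occupied** iff any TF whose DNA-binding domain (DBD) is
  cognate to it is bound *and* effective at that position. Several TFs with
  a shared DBD exchange on one operator (series-parallel); any bound one
  silences it.
- A **channel** (one promoter, ≤ 1 core + ≤ 1 proximal operator, one gene)
  transmits iff *all* of its operators are free — series conjunction.
- A **circuit** (1–2 channels sharing an output gene) is on iff *any*
  channel transmits — parallel disjunction.

Core-position RNAP competition is not modeled thermodynamically. It is a
per-(TF, operator, position) **effectiveness table**: every entry defaults
to effective except the one empirically grounded failure — a
wild-type-expression LacI repressor (X⁺, YQR DBD, IPTG ligand) at an O¹
core operator — with its two rescues (the higher-affinity O^SYM operator,
or ≥ 10× expression from the LacI^q promoter) emerging naturally from the
rule's conditions. Anything beyond these observations would be invented
physics; users can override any entry per circuit.

The quantitative layer assigns each (TF, operator, position) an expression
profile — fractional output in the two ligand states. A node transmits at
the minimum level over its cognate effective TFs (tightest repression wins
on a shared operator), or 1 with no TF; a channel multiplies its nodes'
transmissions; parallel channels couple through the **maximum**, not the
sum, keeping outputs in [0, 1] and reproducing the ON plateau that
per-gate normalization anchors to. The boolean and quantitative layers
agree through a 0.5 threshold on every catalog circuit (tested).

### Default cognate map

YQR → {O¹, O^SYM}, HQN → O^ttg, KSL → O^agg, NAR → O^gta are the pairings
the gate circuits use. TAN and the wild-type RbsR/FruR DBDs are given
placeholder cognates (O^tan, rbsDACBK, fruBKA); the map is plain data and
overridable. Non-cognate pairs are treated as non-binding — the lone
documented weak non-cognate interaction is not modeled.

## Synthetic data

The simulators generate what the analysis consumes, with the controls it
requires; they are first-class, tested code.

**Plate model.** A culture well's raw fluorescence is
`blank + level · (max_output − blank) · (net_OD / nominal_OD) · ε`, with
multiplicative log-normal noise ε (mean exactly 1) on both fluorescence
and OD. Because the signal scales with the *realized* culture density,
OD-normalization cancels the density draw exactly: with all CVs at zero the
pipeline returns the configured levels to machine precision (tested), and
fold changes are recovered without OD-noise inflation. Culture net OD is
drawn around a fixed mean independent of genotype; metabolic-burden
effects are ignored. Defaults: CV 0.05 on both channels, blank 500 r.f.u. /
0.04 OD, maximum output 75,000 r.f.u., nominal net OD 0.5.

Characterization plates carry 6 replicates per (unit, ligand state), gate
plates 12 per ligand-subset condition (2^k conditions for k inputs); every
(operator, position) stratum gets its own `lac_null` control wells (a
plasmid producing no TF, defining that stratum's maximum output) and every
plate carries blanks. Identical seeds give bit-identical plates.

**Default expression profiles.** ON level 0.9; anti-induced leak 0.09
proximal / 0.03 core (fold 10 and 30); super-repressed 0.03; null and
non-cognate 0.95. The source assays report standardized heatmaps rather
than per-unit numbers, so these are package defaults chosen to be
phenotype-consistent and position-consistent (core ≥ proximal dynamic
range); every analysis function takes measured or overridden profiles.

**Cytometry model.** Single-cell FITC is log-normal with geometric mean
`autofluor + level · fitc_scale` (150 + level · 55,000 r.f.u.) and shape
σ = 0.3 ln-units (~30% CV, a realistic bacterial GFP population width);
these constants place the anti-induced and ON populations on opposite
sides of the 10⁴ FITC-A sort threshold with a ~1% crossing tail. Scatter
is a 5% debris / 90% singlet / 5% doublet mixture: debris falls below the
5,000 side-scatter threshold, doublets double the area channels at
unchanged height (area/height ≈ 2, cut at 1.5). Samples default to 25,000
events. What the model omits: instrument spillover/compensation, FCS
binary format, cell-cycle structure, and any correlation between scatter
and expression.

## Analysis chain

1. **Normalize**: subtract mean blank fluorescence and OD, divide by net
   OD; negative numerators clip to 0; wells at or below blank OD are
   excluded and logged.
2. **Standardize**: divide by the stratum's mean normalized `lac_null`
   output; `lac_null` wells then average to 1 by construction, and all raw
   scale factors cancel (scale invariance is tested).
3. **Classify**: Welch two-tailed t-test between ligand states at
   α = 0.001 per unit (no multiple-testing correction across matrix cells;
   the convention is per-cell significance stars). Significant: X⁺ if
   induction raises output, Xᴬ if it lowers it. Nonsignificant: pooled
   mean ≥ 50% of maximum → X⁻, below → Xˢ. Design choices where the rule
   was open: the 50% rule uses the pooled mean over both states; an exact
   50% tie is called X⁻ (conservative — avoids claiming super-repression);
   the test runs on standardized vectors (per-stratum constant scaling, so
   the t statistic is unchanged). Zero-variance degenerate inputs resolve
   by comparing means (p = 1 or 0) with a relative tolerance of 1e-9
   absorbing float roundoff.
4. **Metrology**: the ON state is the phenotype's high state. Dynamic
   range = s_on / max(s_off, 0.005); the 0.005 fraction-of-maximum floor
   (~detection limit) is flagged on the card whenever applied. Raw
   anti-induction/induction units (AIU/IU) are the fold change itself; raw
   repression units RU = 1 / s_no-ligand. These raw-unit formulas are this
   package's definitions — no standardized expressions exist for these
   units — chosen so that RU approaches AIU exactly as
   a NOT unit's ON state degrades toward super-repression, which is what
   the compatibility proximity rule (|AIU − RU| < 1.5 with DR ≥ 5) probes;
   the rule applies raw units, not traceability ratios. Traceability is
   the plain metric ratio against the reference card (I⁺_YQR | O¹,
   proximal), anchored by the reference scoring exactly 1.0 against
   itself. Pairings with ≥ 10-fold RU difference are incompatible.
   Plate-vs-cytometry concordance fits OLS between standardized plate
   means and singlet-gated FITC geometric means (the natural summary of a
   log-normal population).
5. **Gate evaluation**: condition means are scaled to the maximum
   condition (normalized output units), tested by one-way ANOVA at
   α = 0.01, then partitioned by Tukey HSD: conditions indistinguishable
   from the maximum read 1, from the minimum read 0, and conditions
   separable from both (or from neither) stay indeterminate rather than
   being forced to a bit. A nonsignificant ANOVA reads "constant". A
   consequence worth knowing: series gates whose OFF conditions leak at
   different levels (core vs proximal leak) can binarize as indeterminate
   at low noise precisely *because* the assay resolves the difference —
   the evaluator reports "unclassified" instead of guessing.

## Screening math

NNS codons are enumerated against the standard genetic code (32 codons, 20
amino acids, amber the only stop). Coverage treats codons as equiprobable
(synthesis bias ignored). Two quantities are deliberately both exposed:
the **per-codon** probability 1 − (31/32)^n (the conventional "95% at 96
picks" number) and the **all-codon** coupon-collector probability by
inclusion–exclusion, which at 96 picks is only ~0.2 — the conventional
figure is the per-codon one, and the discrepancy is visible rather than
hidden. EP-PCR is a substitution-only Binomial(region length, error rate)
model — no indels, no transition/transversion spectrum, positions
uniform — matching the aggregate error-frequency description; defaults
(815 bp, 0.7%) give 5–7 substitutions per clone.

**Sort simulator.** Each pass draws a labeled sample from the current
library composition, applies the scatter gate then the step's FITC
threshold gate, and updates the composition by each genotype's
*conditional survival rate* in the drawn sample (rather than raw survivor
counts, so resampling noise alone cannot shuffle the composition). An
empty surviving population is reported as a screen failure, not an
exception. The default discovery plan sorts low-FITC with ligand
(keeping Xˢ and Xᴬ), then high-FITC without (keeping Xᴬ), each step run
twice. Enrichment of the target phenotype is monotone *up to the target's
own gate-failure tail*: at the default proximal profiles an anti-induced
cell crosses the 10⁴ threshold with probability ~1.2% (log-normal tail),
so during a repeated low-bin pass the Xᴬ fraction can dip by up to that
rate relative to a co-surviving Xˢ population; the monotonicity tests
allow a 2% relative decrease (tail + counting noise at 25k events) and
verify final enrichment from 0.25 to > 0.9.

## Constructs

Cassette builders enforce the layout constants: core operators are exactly
17 bp and sit contiguously between the −35 (`TTGACA`) and −10 hexamers
(`TATAAT` for trc, `GATACT` for pL, `GACTAT` for the mutated pL);
proximal operators start 15 bp after the −10 box (the original
single-operator reporter's unstated spacer is treated identically);
parallel records concatenate two complete cassettes that must carry
distinct ribozyme insulator labels (RiboJ / RiboJ10). All coordinates are
0-based half-open. Operator, insulator, gene, and terminator sequences are
synthetic placeholders — symbolic labels are authoritative, and layout
validation measures annotated features, not sequence motifs, so real
sequences can be dropped in via configuration without touching the
validator. Out of scope: primer design, assembly simulation, restriction
analysis.

## Problem sizes and what passing tests show

The statistical suites run at the assay's own design points: 6 replicates
for unit classification (500 seeded plates, ≥ 99% recovery), 12 for gates
(200 seeds per gate, ≥ 95% name recovery for NAND/NOR/XNOR), 100 seeded
sort runs, 50 Welch-vs-permutation fixtures at n = 8–12 per group (the
smallest sizes at which a permutation test can resolve p < 0.001 at all),
and exact coverage checks against an independent absorbing-Markov-chain
enumeration for k ≤ 6. Passing these shows the pipeline is self-consistent
under its own noise model — multiplicative log-normal error, binary
induction, genotype-independent growth. Real plate data add effects the
generator deliberately omits (growth differences, edge effects, reader
drift, partial induction), so recovery rates here are an upper bound on,
not a prediction of, real-assay performance.
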