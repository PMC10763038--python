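# Methods

## The screening model

The screen assumes a transcription factor whose binding specificity is
summarized by a short degenerate motif, and asks which genes it could
plausibly regulate. Three decisions define a candidate:

**Matching.** A genomic base matches a motif letter when the base's own
IUPAC set is contained in the letter's set. For plain A/C/G/T genomes this
is ordinary degenerate matching; for assemblies containing ambiguity codes
it is deliberately conservative — `N` in the genome matches only `N` in the
motif — so unresolved assembly regions can never inflate hit counts.
Overlapping occurrences are all reported; no masking rule is applied.

**Strand collapse.** A DNA palindrome (a sequence equal to its own reverse
complement under IUPAC complementation) matches both strands over the same
interval at every occurrence. Such duplicate hits are collapsed into one
record with strand `.`, because the biological object being counted is a
double-stranded binding site. Non-palindromic motifs report `+` and `-`
hits separately. Palindromicity is computed, not declared.

**Promoter eligibility.** A hit becomes a candidate only when it lies
*wholly* inside the regulatory window of a gene that owns a promoter. The
window runs from `upstream` bases 5′ of the translational start site (TRSS)
to `downstream` bases into the coding sequence (defaults 600 and 100),
oriented by gene strand and truncated at the ends of linear contigs.
Promoter ownership comes from a standard prokaryotic operon heuristic:
co-directional adjacent genes with intergenic gaps of at most
`max_intergenic_gap` (default 50 bp, a common prokaryotic threshold) form
one operon, a strand flip always breaks the run, and only the operon's
5′-most gene (or a monocistronic gene) carries an eligible window. The
gap threshold and the whole-containment rule are this package's own
conventions — the biology constrains neither uniquely — and both are
configurable. A hit inside two genes' windows (a divergent promoter)
yields one candidate per gene.

Positions are reported relative to the TRSS with no position zero: −1 is
the base immediately 5′ of the start codon, +1 the first base of the start
codon. For a plus-strand gene with TRSS at S, a genomic coordinate p maps
to p−S+1 when p ≥ S and p−S otherwise; minus-strand genes mirror this
around the gene's end coordinate, and intervals are reported 5′→3′ along
the gene.

Product-category tagging is a keyword aid only ("transcriptional
regulator", "transporter"/"permease"/"substrate-binding", "sigma factor",
else other); the biological triage of which candidates matter for a given
pathway is knowledge-driven and out of scope.

## qPCR fold changes

Relative expression uses the 2^−ΔΔCT estimator. Per replicate,
ΔCt = Ct_target − Ct_reference within a strain; ΔΔCt is the difference of
strain means, and the fold change is 2^−ΔΔCt with the control strain at
1.0 by construction. Statistics stay on the ΔCt scale, where cycle noise
is approximately normal: the two strains' replicate SDs are pooled in
quadrature and propagated into an asymmetric range 2^−(ΔΔCt±SD), and the
p-value is a two-sided Welch t-test on the two ΔCt replicate sets (the
test is this package's choice; star thresholds are the conventional
0.05/0.01/0.001). No amplification-efficiency correction is attempted, and
no multiple-testing correction is applied by default. Genes with missing
Ct values (undetectably low transcription) are skipped with a warning in
batch reports. With zero-variance (synthetic noiseless) inputs the t-test
is undefined; the p-value degenerates to 0 or 1 by whether ΔΔCt is zero.

## Reporter kinetics

XylE (catechol 2,3-dioxygenase) activity is the ordinary-least-squares
slope of A375 against time divided by the protein mass of the extract, in
ΔA375·min⁻¹·mg⁻¹. All supplied points are fit by default — no automatic
linear-phase detection — with an optional time window to restrict the fit.
The estimate is invariant to constant absorbance baselines and exactly
inversely proportional to mass. A perfectly flat trace gets activity 0
with r² defined as 1 (the zero-slope line has zero residual); a negative
slope is reported with a warning rather than clamped, since it indicates
assay failure, not enzyme activity. Strain ratios are reported with a
direction label and a magnitude (a ratio of 1/19 is a 19-fold decrease).

## Network assembly

Evidence rows are grouped by (regulator, target). Binding evidence (e.g.
gel shift) sets the `direct` flag but carries no sign. Directional
evidence comes from perturbation: a significant target fold > 1+ε in the
regulator-deletion strain means repression by the regulator, < 1−ε means
activation (ε = 0.5 on the fold scale, requiring the significance flag —
near-1 or non-significant folds are treated as uninformative). Reporter
comparisons between deletion strain and wild type use the same logic.
Disagreeing directional rows mark the edge `conflict`; conflicts are
surfaced, never averaged. Removing binding rows can therefore change only
directness, never signs.

## What the generators emulate — and what a green test shows

`simulate_genome` produces a high-GC (default 70%, matching a
streptomycete) chromosome with genes laid out in operons (sizes
min(Geometric(0.5), 5), intra-operon gaps 5–50 bp, intergenic gaps
150–1200 bp, strand random per operon) and motif instances planted at
known positions: inside eligible windows, upstream of operon-internal
genes, or intergenic. The background is rejection-sampled — any
spontaneous motif occurrence is re-drawn, preserving GC composition — so
the planted truth table is exact, and planted sites keep a full
motif-length margin from one another so they cannot compound into extra
occurrences. Defaults (200 kb, 150 genes, 6+3+4 planted sites) are large
enough for operon structure while scanning in milliseconds.

The generator does **not** emulate codon structure, repeats, skewed
oligonucleotide composition beyond GC, or annotation errors. A green
recovery test therefore establishes that the scan and the window logic are
exact on their own terms — not that the funnel's counts on a real genome
are robust to assembly or annotation quality, which is why the real-genome
head counts are kept as a separate check requiring the actual assembly.

`simulate_ct` writes Ct = baseline − log2(expression) + N(0, SD), with the
reference gene at expression 1 in every strain and default SD 0.2 cycles
(typical technical-replicate spread) in triplicate; it models neither
efficiency differences between amplicons nor between-run batch effects.
`simulate_reporter` writes linear traces A(t) = baseline + activity·mass·t
+ N(0, SD) with default read noise 0.002 absorbance units over 10
one-minute points; it does not model substrate depletion or lag phases.

## Numerical and degenerate-input choices

- Internal coordinates are 1-based inclusive everywhere; BED export
  converts to 0-based half-open at the I/O boundary only.
- Circular contigs are supported in the scanner (windows spanning the
  origin are found by extending the sequence by motif length − 1);
  regulatory windows on circular contigs are not origin-wrapped — a known
  limitation, irrelevant for linear streptomycete chromosomes.
- A motif longer than a contig yields an empty hit list, not an error.
- Site placement and background cleanup are bounded rejection loops (500
  placement attempts per site, 60 cleanup rounds) that raise a specific
  error rather than looping forever on infeasible specs.
- All generators are pure functions of their spec, which carries the seed;
  identical specs give byte-identical FASTA/GFF3/TSV output.

## Known limitations

- Operon inference is distance-based only; no transcriptomic evidence.
- No mismatch tolerance or PWM scoring: the motif is matched exactly as a
  degenerate pattern, as in the original screen design.
- The step from the in-window candidate table to a shortlist of
  biologically relevant targets is manual by nature and not modelled.
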