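# Methods

## State model

An MSAP locus is a CCGG site amplified after parallel EcoRI+HpaII and
EcoRI+MspI digestion. The two binary lane flags decode bijectively into four
states — I (1,1) unmethylated, II (1,0) hemi-methylated, III (0,1) internal-C
fully methylated, IV (0,0) fully methylated at both cytosines — with a fixed
methylation rank I < II < III < IV. The rank ordering is a modelling
commitment, not a switch: the demethylation patterns (E–J) are exactly the
rank-decreasing pairs and the methylation patterns (K–P) the rank-increasing
ones, so reordering ranks would silently redefine the whole taxonomy. It is
therefore encoded as a constant.

Two caveats of the underlying assay carry into the model. First, type IV
(band absent in both lanes) is read as "fully methylated at both cytosines",
although band absence can also reflect sequence polymorphism at the
restriction site; `MsapDataset(exclude_all_type_iv=True)` optionally drops
loci that are type IV in every sample, and the default (include) matches the
conventional reading. Second, the input matrix is taken as given: no
replicate-consensus or band-reproducibility filter is applied, on the
assumption that only clear, reproducible bands were scored upstream.
Missing lane values are rejected outright rather than pairwise-deleted, so
every count has an unambiguous denominator.

## Summary arithmetic and rounding

All percentages (`msap_pct = 100·(II+III+IV)/total`, and the fully/hemi
splits) are computed and averaged on unrounded floats; rounding to two
decimals happens only in report writers. Published tables of this kind mix
rounding and truncation (e.g. an unrounded 38.277 printed as 38.27, a
2.9374 printed as 2.93), so comparisons against printed values use an
absolute ±0.01 band rather than string equality. Condition averages are
plain arithmetic means over timepoints; averaging summaries with different
locus totals warns but proceeds (weighted averaging is deliberately not
implied).

## Transition and recovery taxonomies

`classify_transition` is total on the 16 ordered state pairs; the label table
is stored as lane encodings and cross-checked at import time against the
rank rule. The chi-square test of independence between methylation level and
condition is the plain Pearson statistic without Yates correction, with the
asymptotic upper-tail p-value (delegated to `scipy.stats.chi2_contingency`);
expected cells below 5 trigger a warning, not an alternative test, and an
expected cell of exactly 0 is an error.

`classify_recovery` branches on the stress-vs-control rank comparison (so its
branch always equals the transition change class) and then tests the recovery
state: equal to control → reverted (a/d), equal to stress → persistent (b/e),
anything else → "different pattern" (c/f). "Different pattern" is an
interpretive reading of the class definitions — it includes, e.g., further
demethylation after recovery — and is flagged as such here. Classes a–h are
exhaustive on any single (control, stress, recovery) triple; class i
("others") is defined *operationally* as pooling disagreement: when several
stress/recovery timepoints are pooled, a locus whose per-timepoint classes
disagree under the unanimity rule is assigned to i. This is the only reading
under which i is non-empty, but whether published class-i counts reflect the
same rule is unknowable from summary tables alone, so it is documented as
this package's convention.

Pooling across timepoints uses unanimity (`consensus_transition`): loci are
pooled only when every timepoint pair agrees, and disagreements are reported
separately rather than resolved by majority. This is conservative and
auditable; it was chosen because no canonical pooling rule exists for this
design. `triples_for_genotype` pairs the k-th stress timepoint with the k-th
recovery timepoint (sorted by days-after-sowing) and the control at the same
index, falling back to the last control — an explicit, inspectable default;
callers needing a different pairing pass triples directly.

## Bisulfite calling

Only the top strand is analysed; clone sequences must be pre-aligned to the
untreated reference and gap-free (the intended inputs are full-length
amplicon clones of short loci, so no aligner is embedded). Context is
assigned by downstream lookahead from each reference C: CG, CHG, CHH with
H ∈ {A,T,C}; positions whose 1–2-base lookahead runs off the sequence end or
meets an N are UNDETERMINED. A clone base C at a reference C is called
methylated, T unmethylated, anything else ambiguous. Percentages follow the
count formula `%mC = 100·methylated/total` per context, pooling calls across
clones; ambiguous calls and UNDETERMINED contexts are excluded from both
numerator and denominator, and a context with no informative calls has *no*
percentage rather than 0. End-of-sequence and N handling are this package's
conventions; other callers may differ at those edge positions.

Positions are 0-based in machine-readable outputs (prose descriptions of
such loci are conventionally 1-based; add 1 when comparing).

## Simulators

`simulate_msap` emulates the study layout: one or more genotypes scored at
hundreds of loci (default 772, the scale of the design it stands in for)
under control/stress/recovery conditions with the default timepoint grid
control = (4, 7, 14, 15, 17), stress = (7, 14), recovery = (15, 17) days
after sowing. Default control state frequencies (0.535, 0.016, 0.187, 0.262)
are the empirical control-condition frequencies of a salt-tolerant cultivar
(implying an MSAP% of 46.5); the stress and recovery defaults shift mass
between I and IV in the directions observed for that cultivar. Two sampling
modes exist: *marginal* (each sample's loci drawn iid from its condition's
state law — replicate timepoints can then disagree, which exercises unanimity
pooling and class i) and *kernel* (one control→stress→recovery Markov chain
per locus via 4×4 row-stochastic kernels, the same condition state shared by
all of that condition's timepoints — which makes transition counts directly
interpretable against the kernel).

`simulate_bisulfite` draws a reference at a configurable GC content
(default 0.4, plant-genome-like), assigns each reference C a true methylation
state by its context probability (defaults CG 0.8, CHG 0.3, CHH 0.05 — the
CG-dominated profile typical of plant gene loci), and emits clones (default
15, a typical clone count per amplicon) in which methylated Cs always read C
and unmethylated Cs read T with probability equal to the conversion
efficiency (default 0.99). True states are assigned once at the reference
level and shared by all clones, so the unmethylated-site floor identifies the
conversion efficiency: the expected observed rate at a site with true
methylation probability p is `p + (1−p)·(1−e)`. What the simulator does *not*
model: epiallele haplotype structure (clone-to-clone true-state variation),
PCR and cloning bias, band co-migration/homoplasy in the MSAP matrix, and
locus-to-locus rate heterogeneity. Tests passing on simulated data therefore
validate the arithmetic and the calling rules, not robustness to those
real-data artefacts.

All randomness flows through `numpy.random.default_rng(seed)`; identical
configs and seeds give byte-identical outputs.

## Numerical and I/O conventions

Probability vectors must sum to 1 within 1e-9; kernels must be row-stochastic
at the same tolerance. Report writers emit deterministic orders (loci in
input order, patterns A→P, classes a→i), trailing newlines, sorted JSON keys,
comma-separated UTF-8 CSV with "." decimals. A written dataset reads back
exactly.

## Verification problem sizes

The statistical self-checks run at sizes chosen to make 3-standard-error
binomial bands tight enough to be meaningful: ≥ 2000 informative cytosine
calls per context for rate recovery (reference length 5000–6000, 10 clones),
20000 loci for state-frequency convergence, and 20 replicate seeds of
772 loci for the MSAP%-recovery mean. The acceptance script reuses these
sizes.

## Known limitations

- No per-locus association testing or multiple-testing machinery; the
  chi-square operation is generic over user-supplied contingency tables.
- No fragment sizing, peak calling or gel-image processing: the binary
  matrix is the entry point.
- Bottom-strand (G→A) bisulfite logic is not implemented.
- The unanimity pooling rule and the operational definition of class i are
  package conventions where the field has no single standard.
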