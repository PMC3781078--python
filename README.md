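# msapkit

Analysis toolkit for **MSAP** (Methylation-Sensitive Amplified Polymorphism)
fingerprints and low-throughput bisulfite sequencing, built around a study
design common in plant stress epigenetics: profile DNA methylation in
contrasting genotypes under control, stress, and post-stress recovery
conditions, and ask which methylation changes the stress induced and which of
them revert once the stress is relieved.

It is aimed at plant molecular biologists and epigeneticists who score MSAP
gels or electropherograms into binary band matrices and want the downstream
arithmetic — state calling, change taxonomy, recovery accounting, chi-square
testing, bisulfite context calling — to be reproducible, validated code
rather than spreadsheet work.

## The method

MSAP digests genomic DNA in parallel with two isoschizomers, HpaII and MspI,
which both cut 5'-CCGG-3' but are blocked by different cytosine-methylation
configurations. The presence/absence of a band in the two lanes decodes into
one of four per-locus states, ordered by methylation level:

| state | HpaII | MspI | interpretation                          | rank |
|-------|-------|------|-----------------------------------------|------|
| I     | 1     | 1    | unmethylated                            | 0    |
| II    | 1     | 0    | hemi-methylated                         | 1    |
| III   | 0     | 1    | full CG (internal cytosine) methylation | 2    |
| IV    | 0     | 0    | full methylation at both cytosines      | 3    |

Per sample, the **MSAP %** (total methylation level) is
`100 · (nII + nIII + nIV) / n_loci`, split into fully- (III+IV) and
hemi-methylated (II) ratios.

Comparing a locus between two conditions gives an ordered state pair, one of
16 **transition patterns A–P**: A–D are the identity transitions, E–J the
rank-decreasing (demethylation) ones, K–P the rank-increasing (methylation)
ones. A (control, stress, recovery) triple is assigned one of nine
**recovery classes a–i**: a/b/c for loci demethylated by stress that revert /
persist / take another state after recovery, d/e/f the mirror image for
stress-methylated loci, g/h for stress-stable loci, and i for loci whose
classification disagrees across pooled timepoints.

For bisulfite data, unmethylated cytosines read as T after conversion while
5-methylcytosines stay C; calls are tallied per plant sequence context (CG,
CHG, CHH with H ∈ {A,T,C}) as
`%mC = 100 · methylated C / total C of that context`.

Seeded simulators generate both data types under configurable state
frequencies, control→stress→recovery transition kernels, per-context
methylation rates and bisulfite conversion efficiency.

## Worked example

Per-sample summary from the band-type counts of a salt-tolerant rapeseed
cultivar (water control, 4 days after sowing; 772 scored loci), the
control-condition mean, and the control-vs-stress transition classes:

```python
from msapkit import MethylationSummary, average_summaries
from msapkit.datasets import band_type_summaries, transition_summary

s = MethylationSummary.from_counts(404, 12, 144, 212, sample_id="Exagone_control_4")
print(f"{s.sample_id}: total={s.n_total} methylated={s.n_methylated} "
      f"fully={s.n_fully} MSAP%={s.msap_pct:.2f} fully%={s.fully_pct:.2f} hemi%={s.hemi_pct:.2f}")

avg = average_summaries(band_type_summaries("Exagone", "control"))
print(f"control mean MSAP% over {avg.n_samples} timepoints: {avg.msap_pct:.2f}")

t = transition_summary("Exagone")
for cls in ("no_change", "demethylation", "methylation"):
    print(f"{cls}: {t.class_counts[cls]} ({t.class_percentages[cls]:.1f}%)")
```

prints

```
Exagone_control_4: total=772 methylated=368 fully=356 MSAP%=47.67 fully%=46.11 hemi%=1.55
control mean MSAP% over 5 timepoints: 46.58
no_change: 620 (80.3%)
demethylation: 121 (15.7%)
methylation: 31 (4.0%)
```

That is: 47.67% of the 772 CCGG loci are methylated in some form in this
control sample; across the five control timepoints the level averages 46.58%;
and under salt stress 80.3% of loci keep their state while 15.7% demethylate
and 4.0% gain methylation — the demethylation-dominated response typical of a
salt-tolerant genotype.

The same analyses run from the shell on matrix + metadata CSV files:

```bash
msapkit score    --matrix matrix.csv --meta meta.csv --out summary.csv
msapkit compare  --matrix matrix.csv --meta meta.csv --before Exagone_control_7 \
                 --after Exagone_stress_7 --out transitions.csv
msapkit recover  --matrix matrix.csv --meta meta.csv --genotype Exagone --out recovery.csv
msapkit bisulfite --fasta clones.fasta --ref reference --out contexts.csv
msapkit simulate msap --seed 1 --out-prefix sim
```

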