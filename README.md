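# lcrscape

Entropy-calibrated detection and positional analysis of **low-complexity
regions (LCRs)** in protein sequences.

LCRs are segments with strongly biased amino-acid composition — poly-Q
tracts, serine-rich stretches, simple repeats.  They are abundant,
structurally elusive, and increasingly implicated in flexible,
low-specificity binding.  `lcrscape` implements a complete analysis
pipeline for asking *where* LCRs sit within protein sequences and what
that position implies functionally:

1. **Detection.**  Every window of every length `w` in a configurable
   range (default 16–300 aa) is scored by its Shannon entropy
   `H = −Σ_a f_a log₂ f_a` over the residue frequencies in the window.
   Because the entropy distribution depends on `w`, a per-window-length
   threshold `t_w` is calibrated empirically as the entropy bounding the
   lowest 0.5% of all length-`w` windows in a reference corpus; a window
   with `H < t_w` is a candidate LCR.  Overlapping candidates are
   resolved by keeping the region with the most extreme standardised
   score `Z = (H − μ_w)/σ_w`.
2. **Positional bias.**  Each region's centre is normalised by protein
   length and folded onto a centre-to-extremity scale in [0, 0.5].  The
   observed distribution is compared, with a two-sample
   Kolmogorov–Smirnov test, to an empirical null obtained by re-inserting
   every LCR 1000 times at uniformly random admissible starts within its
   own protein.
3. **Positional classes.**  Regions within 25 aa of either extremity are
   *terminal* (t-LCR); regions at least 50 aa from both extremities are
   *central* (c-LCR); the 25–50 aa buffer is *intermediate*.
4. **Connectivity.**  Over one or more protein-interaction networks
   (tab-delimited edge lists, with an optional physical-interaction
   filter), the pipeline compares degree distributions of LCR /
   terminal / central / non-LCR protein groups (Wilcoxon–Mann–Whitney),
   regresses degree on LCR length per positional subset (OLS), and
   reports the LCR enrichment of network nodes as
   `(Observed − Expected)/Expected`.
5. **Function.**  GO-term over-representation of each protein subset
   against a proteome background, via the one-sided Fisher exact
   (hypergeometric tail) test with Benjamini–Hochberg q-values computed
   per ontology branch.

A seeded synthetic-data generator (`lcrscape.simulate`) produces
proteome + network + annotation bundles in which every one of those
signals is planted with known strength, so the entire pipeline is
validated by parameter recovery without any external downloads.

## Worked example

Simulate a small bundle, detect LCRs, and test for positional bias:

```
$ cat sim.yaml
n_proteins: 400
length_min: 200
length_max: 500
fraction_with_lcr: 0.3
lcr_len_min: 20
lcr_len_max: 60

$ lcrscape simulate --config sim.yaml --seed 17 --outdir bundle
$ lcrscape detect --fasta bundle/proteome.fasta --wmin 16 --wmax 60 --out lcrs.tsv
69/400 proteins with LCRs (69 single-LCR) -> lcrs.tsv

$ head -3 lcrs.tsv
protein_id  start0  end_excl  length  H       Z       centre_norm  folded  pos_class
P0004       163     196       33      0.1959  -8.644  0.8333       0.1667  terminal
P0012       207     263       56      1.5720  -7.885  0.8502       0.1498  terminal

$ lcrscape position-test --lcrs lcrs.tsv --fasta bundle/proteome.fasta --reps 1000 --seed 17
{
 "D": 0.5164927536231884,
 "p": 1.25047019800951e-17,
 ...
}
```

Reading the output: 69 of 400 proteins carry a detected LCR (the
generator planted them in 30% of proteins, placed terminally with
probability 0.7; the conservative 0.5% threshold recovers the most
biased ones).  Each row gives the region's coordinates (0-based
half-open in the export), entropy in bits, standardised Z-score,
normalised and folded centre position, and positional class.  The KS
statistic D ≈ 0.52 with p ≈ 10⁻¹⁷ says the observed folded positions are
far from the re-insertion null — the planted terminal bias is recovered.

The same stages are available programmatically (`annotate_proteome`,
`positional_test`, `compare_degrees`, `go_enrichment`, `analyse`), and
`lcrscape run-all --config run.yaml --out report.json` executes
everything — calibration, detection, position test, per-network degree
analyses and GO enrichment — into a single machine-readable report.
Real datasets (a UniProt proteome FASTA, BioGrid-style edge lists, GAF
annotations) plug into the same commands.

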