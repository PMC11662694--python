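# Methods

## Frameshift-translation model

A coding sequence (CDS) is an ATG-initiated ORF ending in TAA/TAG/TGA
with no internal in-frame stop, in its own coordinate system (0-based,
half-open). Input may be RNA or lowercase; U→T normalization happens at
construction and the internal alphabet is DNA, so the rare leucine codons
UUA/CUA are handled as TTA/CTA.

A ribosomal frameshift at the in-frame target codon with 0-based codon
index *k* is modeled as: the ribosome translates codons `0..k-1`
normally, fails to decode the target codon (which therefore contributes
no residue), and resumes in the shifted frame — at nucleotide `3k+1` for
a +1 shift (one nucleotide skipped) or `3k-1` for a −1 shift (one
nucleotide re-read). The shifted frame is translated to the first stop
(excluded); if no stop occurs before the end of the sequence the product
runs off the end (`ran_off_end`, trailing partial codon dropped). When
the *first* codon of a +1 shifted frame is itself a stop, translation
terminates at the junction and the product is classed `truncated`
(prefix only); otherwise it is a `trans_frame` chimera.

This anchor convention is fixed by the immediate-stop arithmetic: a +1
shift at TTA or CTA reads `TA+N`, and N ∈ {A, G} completes TAA/TAG, so
the immediate-stop probability is exactly 2/4 = 0.5 for both codons
under a uniform next nucleotide. A −1 shift reads `N+TT` or `N+CT`,
never a stop, so truncation is a +1-only phenomenon and is asserted
rather than configured.

Open choices resolved here (alternatives were defensible): the residue
of the target codon is excluded from the product, since the shift is
modeled as a decoding failure at that codon; identical products from
different source transcripts are all retained (no deduplication), so
provenance headers stay one-to-one with occurrences.

### Databases

- Proteome DB: one record per (CDS, in-frame target occurrence,
  direction), both ±1 directions, truncated products retained — a
  truncated protein is itself evidence of a +1 event. Records with an
  empty product (a codon-0 target truncating immediately) are dropped.
  Headers encode source, 1-based codon number, target codon, direction
  and class.
- Immunopeptidome windows: +1 direction only; the last ≤ 10 in-frame
  residues before the junction joined to the first ≤ 10 out-of-frame
  residues after it. Both parts must be non-empty — immediate-stop
  occurrences and codon-0 targets yield no window — so every window is
  chimeric by construction.
- Decoys: reversed product sequences with `rev_`-prefixed headers, for
  pipelines that want target-decoy appended in one file.

## A-site occupancy

The A-site of a 28–30 nt ribosome-protected fragment is taken at a fixed
+15 nt from the 5′ end, for all read lengths; a read whose A-site
nucleotide is off-frame is floored onto the codon containing it. Reads
whose A-site falls before the CDS, past the last sense codon, or outside
the read itself are discarded. A per-length offset table would be a
straightforward extension but a single offset is the convention
implemented and documented here (taken as 0-based: 5′ position + 15).

For the differential profile, replicates are pooled per condition and a
gene is retained only when its assigned-read count reaches the floor
(default 100) in **every** condition, so all conditions share one
retained-gene set and composition shifts cannot be driven by gene-set
differences. Frequencies are counts over the profile total (stop codons
excluded by default), and the per-codon statistic is
`log2((f_treat + ε)/(f_ctrl + ε))` with ε = 0.5/total per condition —
the pseudocount only matters for near-empty codons; the tested contract
is the ranking and sign, not the absolute y-value.

The density view (gene floor 25) normalizes the A-site count at each
codon occurrence by the gene's mean reads per sense codon, making the
measure invariant to sequencing depth and gene expression, then averages
over occurrences per codon type and reports the treated/control log2
ratio of means.

## Peptide classification and filtration

Identified peptides (from any search engine, consumed as a table) pass
four gates:

1. **Canonical map-back.** An exact-substring match anywhere in the
   canonical proteome means the peptide can originate in-frame:
   class `canonical_ambiguous`, excluded from induction counts. Matching
   is exact by default; an optional I/L-equivalence flag collapses the
   isobaric pair, off by default since it only widens the exclusion.
2. **Junction classification.** The peptide is located in frameshift
   products; with the junction at residue index `prefix_len`, a span
   with ≥ 1 residue on each side is a `trans_frame_chimera` (the only
   class that proves a codon-specific frameshift); wholly past the
   junction is `out_of_frame_only` (could derive from any overlapping
   product); wholly before is canonical-side; the C-terminal peptide of
   a truncated product ending exactly at the junction is
   `truncation_consistent` (accepted as evidence in proteome mode only).
   Multi-mapping peptides keep the strongest class and are flagged.
3. **Replicate presence.** Proteome mode: present in all replicates of
   at least one condition (default 2 per condition). Immunopeptidome
   mode: present in ≥ 2 of (default) 3 replicates of a condition.
   Survival is recorded per condition independently.
4. **Treatment specificity.** Counted peptides survive the replicate
   filter in treated and fail it in control; distinct sequences are
   counted per target codon.

## Translation-efficiency integration

Each gene's canonical transcript is its longest transcript with an
intact ORF (ties broken by smallest transcript id), and the gene's UUA
count is the number of in-frame TTA codons in that CDS. mRNA counts
(consumed as normalized counts; normalization is upstream) are floored
to 10 before averaging so ratio denominators cannot collapse; protein
intensities are not floored. TE per condition is mean intensity / mean
floored count over replicates; ratios are reported as log2
treated/control. Per-gene log2 ratios are binned by UUA content —
presence ({0, ≥1}) or content ({0, 1, 2, 3, ≥4}, edges configurable) —
and each bin is compared to the 0-UUA bin with a two-sided Wilcoxon
rank-sum test (the package's choice of test; medians and quartiles are
reported per bin).

## Synthetic data

The generator produces the study conditions the rest of the package is
validated under; one RNG stream per sub-generator, all spawned from the
master seed, so any stage is independently reproducible and a fixed
configuration gives byte-identical outputs.

- **CDS sets** (default 200 genes, 60–120 codons): ATG + body codons
  drawn uniformly from sense codons excluding the targets + random stop,
  with exactly 2 TTA and 2 CTA planted per gene at codon indices ≥ 6 so
  footprints can cover them. No internal stop can arise by construction.
- **Footprints** (default 1,000 reads/gene/condition, lengths 28–30):
  A-site codon indices drawn multinomially over codons 5..last-sense,
  with weight `stall_factor` (default 5) on the stall codon in the
  treated condition and 1 in control; the 5′ position is
  `3·index − 15` plus frame jitter 0/±1 with probabilities
  (0.9, 0.05, 0.05), emulating imperfect periodicity.
- **Peptide tables**: planted trans-frame chimeras are junction-spanning
  9-mers sampled from trans-frame products, checked absent from the
  canonical proteome and rejected if they span a junction in any record
  of a different target codon (so the planted truth is unambiguous);
  they appear only in treated replicates. Default plan: 8 TTA and 1 CTA
  chimera — the characteristic UUA-biased asymmetry — plus 5 canonical
  peptides present in both conditions; per-replicate dropout is
  configurable (default 0).
- **Expression**: gene count means log-normal around 200 (so the floor
  of 10 rarely binds), negative-binomial counts with dispersion 0.1;
  intensities log-normal with replicate scale 0.5; the treated-condition
  intensity is multiplied by `te_effect(uua_count)` (identity under the
  null).

What the generator does **not** emulate: sequence-dependent ligation and
cloning bias, codon-usage realism (body codons are uniform), 5′UTR
reads, isoform structure, missing-value structure in proteomics, and
search-engine score distributions. Passing tests therefore demonstrate
correctness of the pipeline's logic and statistics under its stated
model, not robustness to every artifact of real libraries.

## Numerical and procedural choices

- Coordinates 0-based half-open everywhere internally; FASTA headers
  report 1-based codon numbers.
- Degenerate inputs: empty retained-gene sets, zero profile totals,
  negative counts, too-few replicates and invalid ORFs raise explicit
  errors; invalid CDS in batch database construction are skipped,
  counted and logged.
- Problem sizes in the automated checks: the frameshift algebra is
  verified against a brute-force string-slicing oracle on 1,000 random
  ORFs; stall recovery uses the default scenario over 20 seeds; chimera
  recovery uses 20 datasets of 40 genes; the TE null uses 100 seeds of
  300 genes (presence bins, Kolmogorov–Smirnov uniformity of rank-sum
  p-values) and recovery uses 500 genes with ≥ 4 UUA codons, where a
  planted 0.5× effect must return a median log2 TE ratio within ±0.15
  of −1. The permutation-null check for occupancy runs 50 label
  permutations on a 30-gene dataset.

## Known limitations

- One CDS per gene (gene ≡ transcript) in the occupancy module;
  multi-isoform collapsing is out of scope.
- A single A-site offset for all read lengths; no per-length calibration.
- Canonical map-back is exact-substring; one-mismatch tolerance is not
  implemented.
- The differential-occupancy statistic is a pseudocounted log2 frequency
  ratio; it is a ranking statistic, not a calibrated effect size with a
  standard error.
- Decoy generation is plain sequence reversal; contaminant libraries and
  search-engine FDR modeling are out of scope.
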