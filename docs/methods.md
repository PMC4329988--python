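# Methods

## Ratio model

Each pull-down experiment is modelled as a mixture of two lysates: tagged
cells in one SILAC channel, untagged controls in the other. The measured
quantity per protein group is the normalized H/L intensity ratio. Ratios
are analysed on the log2 scale (ratio distributions are approximately
log-normal and the reciprocal-labelling symmetry is a sign flip in log
space) and oriented onto a common tagged/control axis: with the tagged
cells heavy, log2(tagged/control) = log2(H/L); with the tagged cells
light it is −log2(H/L).

Significance is a distance-from-the-crowd test. The bulk of every
pull-down is non-specific, so the per-experiment median *m* is an estimate
of the null (ratio = 1 after normalization drift) and the per-experiment
SD *s* an estimate of the combined technical and biological spread. A
quantified protein is significant when |x − m|/s > k, two-sided, with the
direction recorded; only the enriched direction supports interaction
verdicts, since enrichment in the tagged channel is what bait association
predicts. Assumptions: the planted/genuine fraction is small enough not to
distort *m* (the median is robust; *s* is not, which is why a
`robust=True` option substitutes 1.4826·MAD for heavy-tailed data), and
each experiment's distribution is characterised independently — statistics
are computed per experiment (resin × orientation × replicate), not pooled,
because normalization drift and spread differ between runs.

Statistics use the sample SD (ddof = 1) by default; `ddof=0` is exposed
for the population convention. At least `min_stats_n = 10` quantified
proteins are required, otherwise the experiment is rejected as unable to
support a distribution-based threshold. A zero-dispersion distribution
(all ratios identical) makes every protein not-significant, with a
warning.

Proteins detected in only one channel have no ratio; they are handled by
presence/absence logic. An absent ratio with intensity only in the tagged
channel and at least `exclusive_min_peptides = 2` peptides is an
exclusive-tagged detection and counts as supporting evidence alongside
significant enrichment; intensity only in the control channel is
exclusive-control. The peptide floor mirrors the quantification filter
(`min_peptides = 2` unique+razor peptides), the conventional guard against
one-hit identifications.

## Decision table

Per resin, calls are aggregated into counts: supporting (significant
enriched or exclusive tagged), near-one (quantified, not significant),
depleted, exclusive-control, unobserved. Depleted calls are treated as
near-one by the artefact logic: depletion is not evidence of bait
association, and for artefact detection what matters is that the parallel
resin saw the protein without enrichment.

Verdicts, in decision order:

1. **bait** — declared in the design; reported first, never ranked.
2. **genuine** — at least `min_sig_per_resin` supporting experiments in
   each of ≥ 2 resins.
3. **tag_specific_artefact** — supporting evidence with some resin while
   another resin quantified the protein near 1 with no support at all.
4. **non_specific** — quantified somewhere, supported nowhere.
5. **insufficient_data** — everything else, notably proteins seen with a
   single resin only (single-resin candidates are listed, not promoted:
   without the parallel resin the artefact test cannot run).

A protein supported by two resins and near-1 with a third is classified
genuine with a warning: multi-resin support dominates.

`min_sig_per_resin` defaults to 1 — one significant replicate per resin
suffices — which favours sensitivity. The `consistent=True` mode instead
requires a majority of each resin's observed experiments. The trade-off is
quantified by the simulation benchmarks (see `scripts/acceptance.py`): at
the default, planted 4×-noise partners are recovered completely but a few
percent of non-specific proteins reach the genuine class through one lucky
replicate per resin; majority support eliminates these at no sensitivity
cost under those conditions.

Confidence ranks for genuine partners encode reproducibility:

* **high** — supported in ≥ `frac_high` (default 0.75) of the observed
  experiments of *every* resin, and both labelling orientations supporting
  in at least one resin;
* **medium** — ≥ `frac_medium` (default 0.5) reproducibility in every
  resin but missing the high bar (typically single-orientation support);
* **low** — meets the genuine floor only, e.g. 4/4 support with one resin
  but 1/4 with the other.

The two fractions are declared conventions: reproducibility ranking has no
canonical cutoff, and the chosen values separate "supported by most
replicates everywhere" from "supported at least half the time everywhere"
from "barely qualified".

## Beadome and emPAI

Control-only pull-downs (untagged lysate on each resin) define the
beadome; membership is the union of per-resin identification lists, and
the multi-resin subset (default `min_resins = 2`) captures proteins sticky
across distinct resin chemistries — the strongest contaminant candidates.
Abundance is ranked by emPAI = 10^(N_obs/N_observable) − 1. N_observable
counts distinct in-silico tryptic peptides (cleavage after K or R, not
before P; up to 2 missed cleavages) with monoisotopic mass in a closed
500–3000 Da window — a typical LC-MS/MS detectability range; the window
and missed-cleavage count are configurable and echoed into output headers,
since emPAI denominators are convention-dependent and absolute scores from
different conventions should not be mixed. N_observed counts distinct
observed peptide sequences, modification- and charge-agnostic. Peptide
masses come from the standard monoisotopic residue table plus one water
(18.010565 Da). Ties in the abundome rank break by observed count, then
accession, so reports are deterministic.

## Simulator

`simulate_dataset` emulates the statistical structure of a two-tag
parallel capture. Defaults: 500 proteins, 20 genuine partners at log2
enrichment 2.0, 5 tag artefacts per resin, 2 resins × 2 orientations × 2
replicates, per-experiment log2 ratio noise 0.5 (so the planted effect is
4× noise), log-normal abundance (ln-scale μ = 8, σ = 1), 98% heavy
incorporation and a 5% chance that a strongly enriched protein loses its
control channel entirely (exercising the exclusive-detection path).

Generative model per protein × experiment: the true tagged/control ratio
is 2^e for enriched species (bait everywhere; genuine everywhere; artefact
on its sticky resin) and 1 otherwise; multiplicative noise 2^N(0,
noise_sd) is applied; channel intensities follow the labelling
orientation. Incomplete incorporation is modelled physically: the
heavy-grown cell line contributes fraction *i* of its signal at the heavy
mass and (1 − *i*) at the light mass. With the tagged cells heavy this
attenuates apparent enrichment (H = i·T, L = C + (1−i)·T); with the tagged
cells light the leakage adds to the tagged channel and slightly
exaggerates it (L = T + (1−i)·C, H = i·C). Averaged over a reciprocal
pair the net effect is attenuation toward 1, monotone in decreasing
incorporation, which is what the attenuation test asserts (on the mean
across orientations, not per experiment).

Detection is Bernoulli with a logistic probability in the log mean eluate
signal, midpoint at μ − 2.5σ and slope 2 — nearly everything of average
abundance is seen, the faint tail drops out at random, and enriched
proteins are easier to detect because detection responds to the amount in
the tube, not the lysate abundance. The bait is always detected (it is
what was purified). Per-experiment peptide counts are 1 + Poisson(L/50)
with a log-normal length proxy L (median 350 residues), so a small
fraction of records fail the 2-peptide filter.

What the simulator does **not** model: peptide-level quantification and
outlier rejection, ratio compression from co-eluting species,
arginine-to-proline conversion, protein groups sharing peptides
(accessions are unique), correlated replicates (noise is independent
across experiments), chromatographic or spectral detail. Passing the
recovery benchmarks therefore shows the decision logic is correct under
the stated generative model, not that real datasets will reach the same
sensitivity; in particular real replicate correlation would make the
one-replicate support rule leakier than simulated, strengthening the case
for `consistent=True` on real data.

## Numerical and interface choices

* Ratios of exactly 0 or infinity in input tables encode single-channel
  detection and are coerced to absent with a warning, feeding the
  exclusive-detection path instead of arithmetic.
* Table dialects are declared column-name mappings defaulting to MaxQuant
  1.3 `proteinGroups` conventions, with both long (experiment column) and
  wide (per-experiment column suffix) layouts melted to long form. The
  normalized ratio column is the default input; a flag switches to the raw
  ratio column.
* Optional gene-level collapsing keeps the group with most peptide
  evidence per gene, for redundant proteome databases where one protein
  appears under many accessions.
* Reports are deterministically ordered (verdict class, then descending
  confidence, then accession) and carry their thresholds in comment
  headers; classification reruns are byte-identical.
* CLI exit codes: 0 success, 1 analysis failure (e.g. an experiment with
  too few quantified proteins), 2 usage/configuration error.

## Problem sizes

The test suite and acceptance script run the simulator at 500–2000
proteins and 8 experiments, the decision-table cross-check at 10,000
random call patterns, and the digestion/emPAI oracles at dozens of random
sequences and count pairs; the whole suite completes in well under a
minute on one CPU. These sizes give Monte-Carlo standard errors an order
of magnitude below the asserted tolerances.

## Known limitations

* The significance test assumes a unimodal, mostly-null ratio
  distribution per experiment; pull-downs dominated by genuine complex
  members would violate it (use the robust scale, or an external null).
* Single-resin candidates are never promoted to genuine, even when highly
  reproducible — by design the parallel-resin artefact test is mandatory.
* emPAI is computed from counts supplied to it; when observed counts come
  from protein-group tables the unique+razor peptide count stands in for
  distinct observed peptides, which undercounts modified/charge variants
  exactly as the denominator convention expects but may differ from
  search-engine-internal emPAI values.
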