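# Methods

This note documents the statistical model behind `txrev`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## The experimental design

The canonical input is a 2×2×2 factorial of three agents — a drug (A,
adriamycin), zinc (Z) and the hypoxia-mimetic cobalt (C) — giving eight
conditions `0, A, Z, C, AZ, AC, ZC, AZC`, each hybridised in duplicate on
an intensity-scale array platform (~29k probe sets). The pipeline takes
the probe-level matrix after platform summarisation and normalisation;
summarisation itself (e.g. PLIER-family algorithms on raw .cel files,
Lowess-style corrections) is out of scope and assumed done upstream. The
code accepts any condition set; nothing is hard-wired to eight beyond the
packaged defaults.

## Preprocessing

1. log2 transform (if the matrix is delivered linear).
2. "Averaged data": per-condition arithmetic mean over replicates.
3. Expression mask per contrast: a probe is testable if it exceeds the
   log2 threshold `t = 4` in **all** replicates of at least one of the two
   conditions. With duplicates this is the "above threshold in both
   replicates, in at least one condition" rule; for deeper designs the
   natural generalisation (all replicates) preserves its intent — the
   probe is reliably expressed somewhere. `t` lives on the
   post-normalisation log2 scale; rescale it if your normalisation places
   the noise floor elsewhere.
4. Unique-gene view: probes with a known symbol are averaged per symbol;
   unannotated probes are kept for probe-level statistics and dropped only
   at gene collapse.

## Noise model and the DE statistic

With n = 2 replicates a per-probe variance estimate is useless, so the
null spread is borrowed across probes of similar intensity. For every
replicated condition, each probe contributes (pair mean, pair difference)
points; pooled points are sorted by mean and scanned with sliding windows
(default 500 points, step 250). Each window yields a knot at its median
intensity with

    sd_single = 1.4826 · MAD(differences) / √2,

the scaled MAD making genuinely regulated probes harmless outliers, and
the √2 converting a difference-SD to a single-measurement SD. Between
knots the SD is interpolated linearly; beyond the first/last knot it is
clamped. Window SDs are floored at the 1st percentile of all window SDs
(10⁻³ in fully degenerate data) so zero-variance stretches cannot produce
infinite statistics. The window default trades curve resolution against
per-knot sampling error (~5 % relative SE at 500 points); the tests that
assert tight recovery of a known noise curve use wider windows for that
reason.

The test statistic for contrast (a, b) is

    z = (x̄_a − x̄_b) / (σ(Ī) √(1/n_a + 1/n_b)),   Ī = (x̄_a + x̄_b)/2,

with a standard-normal reference and two-sided p-values. This treats the
pooled intensity-indexed SD as known — reasonable when each window pools
hundreds of probes — and is the package's documented choice where the
upstream method is underdetermined; it is a moderated z, not a t-test.
Benjamini–Hochberg is applied at 5 % over the masked probes of the
contrast only (via `statsmodels`; tests cross-check an independent
step-up oracle). A call additionally requires the signed linear fold
change to **exceed** 1.5 strictly. Gene-level calls require at least one
called probe plus a same-direction gene-level fold change > 1.5; genes
with probes called in both directions are dropped with a warning.

### Signed fold changes

For a log2 difference d, FC = 2^d if d ≥ 0 and −2^(−d) otherwise, so
decreases carry a negative sign, |FC| ≥ 1 always, and FC = +1 at d = 0.
Values in (−1, 1) are rejected everywhere as convention violations.

## Reversal scoring

Given a primary contrast (C−0) and a counter contrast (ZC−C), a gene
called in the primary contrast is

* **reversed** — counter FC opposite-signed and |FC| > 1.5 (strict, so a
  printed 1.55 counts and 1.50 does not);
* **partial** — opposite-signed but ≤ 1.5;
* **none** — same-signed.

Statuses partition the calls, and the headline statistic is the reversed
count per primary direction. The classification is deliberately
categorical (matching how such tables are reported) rather than an
interaction-term effect size. `band_fraction` gives the scatter-plot
companion: the fraction of net contrasts vs baseline inside the
|FC| ≤ 1.5 band. Reversal is scored at gene level, on the averaged,
collapsed matrix.

## Consensus signatures, set logic, enrichment

* Voting: symbols are upper-cased; membership needs ≥ `min_votes` (= 2)
  studies in the same direction. A symbol supported in both directions is
  kept in both lists and flagged rather than silently resolved, and
  downstream intersections are direction-matched.
* Venn partition of (AZC−AC, ZC−C, A−0) per direction, with named
  clusters: `pink`/`green` = shared by AZC−AC and A−0 excluding ZC−C
  (candidate drug-response genes restored by zinc), `light_blue`/`violet`
  = shared by AZC−AC and ZC−C (zinc response independent of drug). The
  triple intersection is reported separately and excluded from the shared
  clusters by default (`include_triple_in_shared` flips this), since the
  two-set descriptions are ambiguous about it.
* Enrichment: upper-tail hypergeometric p for the query/set overlap, set
  sizes measured **after** intersection with the universe and filtered to
  8–500 (out-of-platform members should not inflate sizes), BH across the
  tested sets per query, significant iff q ≤ 0.10 and overlap ≥ 5. The
  default universe is all collapsed gene symbols on the platform, not only
  expressed ones; callers can pass any universe.

## Ordination and the shift ratio

PCA is computed on the condition-averaged matrix (conditions as points,
probes as features), centered per feature and **not** scaled to unit
variance — unit scaling would equalise strongly and weakly responding
probes and distort the fold-change geometry. Component signs are fixed by
making each component's largest-magnitude loading positive. Two components
are retained by default. The rescue of a perturbation is summarised by

    shift_ratio = ‖rescued − baseline‖ / ‖perturbed − baseline‖

in the retained component space; 0 = perfect return to baseline, 1 = no
rescue. Using the retained space is intentional: it measures rescue along
the dominant response axes, ignoring residual directions the ordination
deems minor.

## Synthetic data: what it emulates

`simulate()` plants, per gene: a baseline log2 intensity (N(8, 1.8²)); a
drug effect (15 % of genes, ±2.0 log2); a cobalt effect (25 % of genes,
±1.5 log2 — 2,000 genes at the default 8,000); a zinc-alone effect (5 %,
±1.0); a reversal flag (probability ρ = 0.8) making zinc cancel the
cobalt effect wherever both agents are present; and a block flag
(probability 0.5 among drug genes) making cobalt suppress the drug effect,
lifted by zinc with the same probability ρ. The drug magnitude exceeds the
cobalt magnitude so the leading principal component is the drug axis and
the second the active-cobalt axis, the qualitative geometry the analysis
is designed to expose. Replicate noise is Gaussian with SD linear in
intensity from 0.45 (log2 intensity 4) to 0.15 (intensity 12) — the
low-expression end is noisier, as on real arrays. Probes (10,000 over
8,000 genes) carry a fixed offset (SD 0.25) so probe- and gene-level calls
agree; 5 % are unannotated. Pathway and multi-study signature inputs are
planted with known membership (a 50-gene pathway seeded with 30
zinc-reversed genes among 49 decoys; 150 up / 76 down core signature
genes, each in ≥ 2 of 10 study sets, plus study-private filler appearing
once).

What it does **not** emulate: probe-level sequence effects and
cross-hybridisation, correlated (co-regulated) gene modules, batch and
array-order effects, heavy-tailed or asymmetric noise, and
intensity-dependent fold-change compression. Passing tests therefore
demonstrate the pipeline's correctness and calibration under its own
model assumptions, not robustness to those real-data pathologies.

These defaults are the package's reference conditions; the calibration
studies in `scripts/acceptance.py` and the acceptance tests run at these
sizes (10,000 probes, duplicates, 10–20 seeds), which keeps a full run in
the seconds-to-minutes range on a laptop.

## Numerical and design choices

* BH, hypergeometric tails, PCA and the robust SD come from statsmodels,
  scipy and scikit-learn; the reversal statistic, noise model, voting and
  set logic are implemented here.
* The packaged shared-gene table stores fold changes exactly as printed
  (two decimals), not re-derived log2 values, and is validated on load
  (66 records, 54 up / 12 down, sign/direction consistency, |C−0| ≥ 1.5).
* The fold-change threshold is strict (>), consistent with the packaged
  table whose smallest magnitudes are 1.51/1.54.
* Ties in the noise-model knot positions (flat intensity stretches)
  collapse to one knot keeping the larger SD; a single-knot model is
  padded to a flat two-knot curve.
* Contrasts are caller-configurable; the packaged default list is the
  seven treatment-vs-untreated contrasts plus AC−A, ZC−C, AZC−AC and
  AZ−A. The original study's full 17-comparison scheme lived in
  supplementary material that is not machine-readable; the default list
  covers every contrast the downstream analyses consume.
* Degenerate inputs fail loudly: empty universes, conditions without
  samples, non-positive intensities before log2, fold changes inside
  (−1, 1), and unreplicated designs for noise fitting are all hard errors.

## Known limitations

* The normal reference for the moderated z is anti-conservative if the
  window SD underestimates the true spread (e.g. strong mean-variance
  misspecification); the calibration tests bound the realised null call
  rate under the generator's assumptions only.
* With duplicate arrays the expression mask is sensitive to single
  dropouts (one low replicate in both conditions removes the probe).
* Reversal is categorical; genes hovering at the 1.5 boundary flip status
  under measurement noise, which is why recovery of a planted reversal
  fraction is validated to ±0.05, not exactly.
* The consensus voter treats studies as exchangeable and ignores study
  size or quality weights.
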