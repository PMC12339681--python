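# Methods

`phagoscreen` reimplements, end to end and at desk scale, the analysis of a
high-content screen for modulators of microglial synaptosome phagocytosis:
assay quality control, exclusion filters, hit calling, cell morphotyping,
and transcriptomic "RNA-activity" determination. Because the raw plates,
images and sequencing libraries of such a screen are not shippable, every
stage is driven by a synthetic-data generator with known ground truth; the
tests and the analysis scripts quantify what the pipeline recovers from
that ground truth.

## The assay model

A well holds microglia-like cells that engulf pHrodo-labelled synaptosomes;
pHrodo fluoresces only in acidified phagolysosomes, so red signal marks
engulfed material. The **phagocytic index (PI)** of a well is

    PI = (Σ synaptosome signal area) / (Σ cell count)

summed over the well's image fields (not a mean of per-field ratios — a
deliberate convention that weights fields by their cell content).

Assay quality uses the standard two-control statistics, with DMSO carrier
as negative control and 2 µM cytochalasin D (an actin-polymerization
inhibitor that blocks phagocytosis) as positive control:

* Z′-factor: `1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg|`; ≥ 0.5 is an
  excellent screening window.
* SSMD: `(μ_neg − μ_pos) / √(σ_neg² + σ_pos²)`; > 5 is a robust assay.

Sample (n−1) standard deviations throughout, as is conventional for plate
QC.

## Screen simulation

`ScreenSimConfig` defaults encode the screen design: 489 compounds at
10 µM, three replicate wells per compound placed on different plates, 12
image fields per well in the primary screen (15 in the secondary), and
fixed control columns (8 DMSO + 4 CytoD wells) on every plate.

* **Field noise.** Per-field PI is log-normal around `baseline × multiplier`
  with CV 0.3 (a positive ratio quantity, hence log-normal; the well-level
  SD then scales as `μ·CV/√F` over F fields). Per-field cell counts are
  Poisson with mean 100.
* **Effect classes.** Each compound is a null, inhibitor (PI multiplier
  drawn uniformly from 0.2–0.7, so a spread of strong and borderline
  inhibitors as observed in confirmation screens), activator (multiplier
  > 1; default fraction 0), or toxic. Default fractions plant 47
  inhibitors and 35 toxic compounds among 489.
* **Toxicity** is Binomial thinning of cell counts to a surviving fraction
  of 0.05 — the simplest mechanism that puts toxic wells below the
  10 %-of-DMSO exclusion threshold while leaving the survivors' PI
  unchanged.
* **Morphology.** Field-level mean solidity, eccentricity and IBA1
  intensity are Gaussian around a DMSO baseline (0.72, 0.70, 1.0) plus a
  per-compound shift. Shifts are an effect-class offset plus correlated
  per-compound jitter: branched (ramified) cells are elongated and dimmer,
  so the jitter correlation is −0.9 between solidity and eccentricity,
  +0.624 solidity–IBA1 and −0.565 eccentricity–IBA1. Per-compound
  morphology overrides support planting signature phenotypes (e.g. a
  strongly ramifying, IBA1-lowering treatment).
* The closed-form control separation implied by the configured means and
  CVs is exposed (`predicted_z_factor`, `predicted_ssmd`) and checked
  against simulation at large n. Note that a Gaussian two-group model
  cannot reproduce every (Z′, SSMD) pair jointly — the two statistics
  constrain `σ_neg + σ_pos` and `√(σ_neg² + σ_pos²)` separately and some
  published pairs are infeasible under normality — so the defaults target
  the qualitative regime (Z′ ≈ 0.6–0.8, SSMD ≈ 9–15) rather than specific
  printed values.

What the generator does **not** model: plate-position (edge) effects,
batch drift between plates, optics (PSF, autofluorescence), or compound
chemistry. Passing tests therefore demonstrate correctness of the
statistics and filters, not robustness to those real-data artifacts.

## Field rendering and imaging

`render_field` paints non-overlapping cells (ellipses for ameboid/rod
cells; a core with four narrow arms for ramified cells, giving low
solidity) into three channels — nuclei, IBA1, pHrodo — over a uniform
background (0.05) with additive Gaussian noise (SD 0.01), and returns the
exact painted label masks as ground truth. Default canvas 512×512 px,
cells 15–40 px semi-major axis: large enough for stable region properties,
small enough for fast tests. Cells overlapping beyond a configurable cap
(5 % of their area) raise an error, since the assay assumes resolvable
cells.

The measurement recipe (a documented stand-in for the original
high-content pipeline, whose parameters are not public): median-filter
background subtraction (radius 50 px), Gaussian smoothing (σ = 2), Otsu
foreground on IBA1 with an intensity floor of 0.15 (Otsu on a signal-free
field would otherwise split the noise), nuclei-seeded watershed on the
distance transform to split touching cells, and a 50 px minimum object
size to suppress debris. Boundary-touching cells are retained. Solidity is
area over convex-hull area; eccentricity is that of the
second-central-moments ellipse (0 = circle) — stated explicitly because
"eccentricity" has competing definitions. Synaptosome area counts pHrodo
pixels above a fixed threshold (0.5) inside segmented cells; signal
outside cells is excluded by construction of the dye chemistry.

## Filters and hit calling

Filter order is fixed and idempotent: **over-segmentation** first (field
level: cell count above median + 5·MAD of same-plate DMSO fields; skipped
with a warning below 8 DMSO fields), then **toxicity** (well level: total
cell count strictly below 10 % of the DMSO mean; per-plate reference by
default to absorb plate effects, screen-wide available), then PI
computation over surviving fields. Per-compound toxicity (default for hit
calling) uses the mean of the replicate wells. The strict-inequality
boundary (a well at exactly 10 % is retained) follows the "< 10 %" rule.

Primary z-scores: compound replicate wells are aggregated by their mean,
then `z = (mean PI − μ_ref)/σ_ref`. Two references are implemented because
both are defensible: `vs_dmso` (DMSO well statistics; the default) and
`vs_library` (distribution of per-compound means; exactly standard normal
under the null, which is how the null-calibration property is checked).
Hits are non-toxic compounds with z ≤ −2 (inclusive); activators are
reported symmetrically at z ≥ +2 but never called hits.

Secondary screen: ratio of mean per-field PI to the DMSO mean, SEM
propagated from the compound group's field SEM over the DMSO mean.
Classification: toxic (dominates) → confirmed inhibitor (ratio ≤ 0.5,
inclusive) → weak inhibitor (< 1 − δ) → activator (> 1 + δ) → no effect,
with δ = 0.05. Every tested compound receives exactly one class.

## Counts simulation and differential expression

`CountsSimConfig` emulates a plate-multiplexed, well-barcoded bulk RNA-seq
(DRUG-seq-style) experiment: per-gene baseline means log-normal, per-well
library-size factors log-normal (CV 0.2), counts negative-binomial with
dispersion 0.1 (or gamma-distributed). Active compounds have `n_de_genes`
genes (default 300) shifted by ±`de_log2fc` (default 2, half up half
down); DE genes are planted on genes with baseline mean ≥ 10, since
treatment effects on genes below the detection floor are unmeasurable by
any method and would only dilute recovery statistics.

The DE engine is an explicit, documented stand-in for shrinkage-based
frameworks: median-of-ratios size factors (normalized to geometric mean 1,
with a warned fallback over per-well nonzero genes when no gene is nonzero
everywhere), method-of-moments NB dispersion pooled across the two groups
and floored at 1e−8, log2 fold change of normalized group means with a
0.5 pseudocount, and a Wald statistic on the log ratio referred to a t
distribution with n₁+n₂−2 degrees of freedom. The t reference is the
small-sample correction appropriate at group sizes of 3–4 wells: with a
plug-in dispersion the normal-reference Wald test is anticonservative,
while the t reference holds the empirical null rate at ≈ 5 % for
adequately expressed genes (it is conservative for very low counts, the
safe direction). A cross-check test confirms rank agreement of the fold
changes with an independent shrinkage-based implementation on a planted
fixture; numerical equality is not expected and not claimed — the
downstream activity rule consumes DEG *counts*, not per-gene estimates.

DEG definition: BH-adjusted p < 0.1 **and** |log2FC| > 1, both strict.

## The RNA-active rule

The empirical null is built from `n_draws` (default 100) random disjoint
splits of the DMSO wells into two groups of `group_size` (default: the
compound's replicate count), each scored by the same NB test + DEG count.
The threshold is the nearest-rank 95th percentile of the null DEG counts,
and a compound is RNA-active iff its DEG count is **strictly greater**
(more DEGs than 95 % of DMSO-vs-DMSO comparisons). By exchangeability this
controls the false-active rate at ≤ 5 % (often far less when the null is
degenerate at zero). Comparisons are restricted within batch when the
metadata carries several batches. Pathway over-representation is a plain
hypergeometric upper tail, provided as a generic enrichment primitive.

## Morphotyping

Cells are binned by solidity and eccentricity: ramified (solidity ≤ low
and eccentricity ≥ high), ameboid (solidity ≥ high and eccentricity ≤
low), rod/bipolar (both mid), and ambiguous for discordant corners (e.g.
a compact *and* elongated profile) — the four classes partition feature
space. No published numeric cutoffs exist, so the default derivation takes
tertiles of the DMSO cell population per screen, with a fixed override
(0.70/0.85 solidity, 0.60/0.80 eccentricity); the derivation is recorded
on the threshold object. Compound phenotypes are field means then compound
means; PCA runs on standardized compound-level features with a fixed sign
convention (largest-magnitude loading positive). Morphology is reported as
shape classes only; no activation-state claim is attached.

## Problem sizes

Defaults were chosen so a full screen (489 compounds × 3 wells × 12
fields ≈ 20k fields) simulates in well under a second and the complete
analysis, including a 100-draw DMSO null over 2000 genes, runs in a few
seconds; the test suite repeats the hit-recovery and RNA-calibration
experiments over 20 seeds each. Rendered-image tests use 512×512 fields
with ≤ 10 cells except for a single dense-field case.

## Known limitations

* Segmentation equivalence with the original (unpublished) high-content
  pipeline cannot be asserted — only fidelity to this module's own recipe,
  which is validated against rendered ground truth.
* The NB Wald engine differs numerically from shrinkage-based DE tools;
  per-gene estimates on marginal genes will not match.
* The generator's morphology model is compound-level Gaussian; it does not
  produce single-cell morphotype mixtures within a well unless per-cell
  tables are supplied from the imaging stage.
* No spatial plate-effect correction (B-score/median polish) is
  implemented; the simulator does not generate such effects.
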