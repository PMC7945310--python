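# Methods

## The growth model and the efficiency-corrected score

A base-editing screen measures the abundance change of each sgRNA between
the start and end of a growth competition.  The normalized end count of
guide *i* in experiment *j* is modeled as a mixture of edited cells
(fraction `p_ij`) growing at rate `b_j + f_ij` and unedited cells growing
at `b_j`:

    C_ij = S_ij [ p_ij e^{b_j + f_ij} + (1 − p_ij) e^{b_j} ].

Taking logs and subtracting the growth baseline estimated as the median
ln fold change of the non-targeting controls gives

    d_ij = ln(1 + p_ij (e^{f_ij} − 1)),

and, writing `p_ij = q_i l_j` (guide activity × experiment constant) and
linearizing for small `|p (e^f − 1)|`,

    d_ij ≈ q_i β_ij,   β_ij = l_j (e^{f_ij} − 1).

The functional score is therefore `β = d / q`.  Three consequences are
worth keeping in mind:

- β is identified only up to the experiment constant `l_j`, which is not
  estimable from a single screen; scores are reported in `l_j` units, and
  multiplying every activity by a constant `c` divides every β by `c`.
- The linearization is an approximation.  `scoring.linearity_gap` exposes
  the gap between `ln(1 + x)` and `x` (with `x = p(e^f − 1)`) in both
  absolute and relative form: on the ln-fold-change scale the absolute gap
  stays below 0.03 throughout `|x| < 0.2`, while the relative gap is
  roughly `|x|/2` (about 10% at the `|x| = 0.2` boundary and under 3% only
  for `|x| ≲ 0.055`).
- Because β = d/q diverges as q → 0, guides below an activity floor
  (default 0.05) are reported unscorable, and an optional activity filter
  (default threshold 0.2 of scaled activity, intended for low-efficiency
  editors) removes low-activity guides from classification.
  `scoring.fit_activity_response` recovers the shared slope `l(e^f − 1)`
  of a fixed-effect guide group by fitting the exact response
  `d = ln(1 + s q)` rather than a straight line, which would be biased by
  the curvature outside the linear regime.

## Guide design

For each reference strand, every C (CBE) or A (ABE) lying at protospacer
positions 4–8 — equivalently 13–17 bp upstream of an NGG or NG PAM — is
targetable.  When several protospacers place a base in the window, the one
placing it farthest 5′ of the PAM (minimal target offset) is selected;
bases whose winning protospacers coincide collapse into a single guide
record, so guides are unique per (contig, start, strand).  Uniqueness is a
0-mismatch exact-match scan (spacer + PAM of the configured class) over
both strands of the supplied references only; genome-scale specificity is
delegated to the user's choice of reference.  Internally coordinates are
0-based half-open; emitted tables are 1-based inclusive.  Control guides
(non-targeting, essential-stop) are curated inputs, not generated.

## Outcome and efficiency mapping

Assay reads have the structure `spacer — scaffold — target`.  Processing
steps, with their thresholds:

- **Scaffold anchoring**: minimal-Hamming placement of the scaffold; reads
  with more than 3 mismatches, ambiguous placement, or short flanks are
  rejected.  The spacer is the 20 nt 5′ of the scaffold, the target the
  configured length 3′ of it (default 26 nt = 3 nt context + 20 nt
  protospacer + PAM).
- **Recombination filter**: Jaro similarity between the observed spacer
  and the protospacer copy inside the target; reads below 0.75 are
  template-switching artifacts and are removed.  Random 20-mers over a
  4-letter alphabet have median Jaro similarity ≈ 0.73, so this flag is
  reliable only when the two guides involved are dissimilar; see the
  mismatch cap below for the complementary guard.
- **Library assignment**: exact spacer match, else unique nearest
  neighbour at ≥ 0.85 identity (≤ 3 mismatches) with a PAM-class-consistent
  observed PAM; ties stay unassigned.
- **Outcome calling**: an outcome key enumerates the window positions
  (4–8) carrying the editor's canonical transition.  Reads with no
  canonical transition but some mismatch are "other"; they count toward
  the assigned depth `D_j` but toward no outcome count `R_kj`, since they
  are the noise the background correction targets.  A read whose target
  carries more than 3 non-canonical mismatches is **rejected** outright
  (excluded from `D_j`): at a sequencing error rate of ~10⁻³ a genuine
  read essentially never accumulates 4 substitutions in 26 nt, whereas a
  recombinant that slipped past the Jaro filter typically differs at 10+
  positions.  Without this cap, surviving recombinants inflate `D_j` and
  bias every outcome fraction downward.
- **Background correction**: for outcome k,
  `f_k = mean_j (R_kj − D_j h_c) / (D_j − D_j h_c)` over edited samples
  with `D_j > 0`, where `h_c` is the mean fraction of control-sample reads
  whose called outcome equals k (0 for outcomes absent from controls).
  Negative corrected values are clamped to 0.
- **Merging and the major outcome**: coding outcomes with identical
  amino-acid changes are merged (fractions and read support summed);
  noncoding outcomes merge only at identical nucleotide changes.  The
  major outcome is the merged group with the highest `f_k`; ties break by
  fewer edited positions, then lexicographic key.  The guide's measured
  activity `q_raw` is the major outcome's corrected fraction averaged over
  edited replicates.  A guide fails the support filter only when its major
  outcome has coverage < 30 reads **or** frequency < 0.005 in *every*
  replicate (one adequate replicate rescues it).

Consequence annotation is a minimal strand-aware re-implementation: all
coding changes of an outcome are applied jointly before codon translation
with the standard genetic code; a change on the intronic side within 2 bp
of an exon–intron junction is splicing; types are prioritized
stop_gain > splicing > nonsynonymous > synonymous > UTR.

## Normalization and fold change

Raw counts get a +1 pseudocount (so dropped-out guides stay finite), are
divided by `w_j` — the geometric mean of the pseudocounted non-targeting
control counts in sample j — and the per-replicate fold change
`ln(C/S)` is re-centred on the control median `b̂_j`.  Two exact
invariants follow: any per-sample depth rescaling cancels, and the control
median of `d` is identically zero.  Essential-stop controls never anchor
the normalization; they ride along as a depletion QC class.  (The constant
`w_j` is a control-anchored geometric mean, not a per-guide
median-of-ratios as the name of the general technique might suggest.)

## Efficiency harmonization

When external activity predictions are supplied, measured and predicted
distributions are quantile-mapped (empirical order statistics, average
ranks for ties, linear interpolation): a guide with a measurement keeps
it; a guide with only a prediction receives the prediction mapped onto the
measured distribution; a guide with neither is excluded.  The harmonized
values are min–max scaled to [0, 1] per screen library.  With no
predictions the measured values pass through unchanged.

## Loss-of-function classification

A 4-component Gaussian mixture (EM, k-means initialization, 10 restarts,
tolerance 10⁻⁶, seeded) is fitted per screen library to the mean β of
guides passing the filters.  The expected structure is one null-like
component near zero, two negative-mean components and one positive; when
the fit does not produce exactly two negative means, the two smallest
means are used, with a warning.  `P_i` is the summed posterior of the two
negative-mean components at β_i; the LOF call is the strict inequality
`P_i > 0.8`.  The library's equivalent β cutoff is found by bisecting
`P(β) = 0.8` at its rightmost crossing between the negative means and
max(0, largest mean) — the search deliberately starts at the negative
means because a broad null component can re-dominate in the extreme left
tail, where `P(β)` is then non-monotone (a numerical check warns when
monotonicity fails on the negative span).  AIC/BIC over K = 2…6 are
emitted as diagnostics, but K = 4 is fixed for calling.  Wald z = mean/SE
across replicates against the standard normal, two-sided, with
Benjamini–Hochberg correction across the library; significance is
reported alongside but does not gate the LOF call.  Evaluation against
clinical labels uses −mean β as the ranking score for ROC/AUC, plus
per-category LOF fractions with two-sided Fisher exact tests.

## The simulator

`simulate_screen` draws day-0 counts from a multinomial at fixed depth
over lognormal guide abundances (σ = 0.3), computes expected day-N mass
per the growth model, and draws day-N counts multinomially.  Defaults
describe the study conditions: 5,000 guides, 10% non-targeting (f = 0,
p = 0), 15% deleterious with relative fitness e^f uniform on [0.3, 0.8],
remaining guides neutral; activity q uniform on (0, 1]; experiment scale
l = 1; growth factor b = 2; two replicates; sequencing depth 2,000 reads
per guide per sample (10⁷ total at the default library size), the
per-guide coverage of a typical screen.  Sampling is multinomial only —
no overdispersion knob in this version.

`simulate_target_reads` emulates the integrated target-site assay: reads
are spacer + scaffold + target with truth-drawn outcomes in the window,
uniform substitution errors (default 10⁻³), and a configured fraction of
recombinant molecules pairing a spacer with another guide's target
(default 5%).  Editing probabilities default to Beta(1.2, 6) — low and
highly variable, as such assays measure — and when a window holds a second
editable base, 20% of edited reads carry both changes (co-editing).  The
truth table records, per guide, the nucleotide-level expected major
fraction and (given a transcript model) the amino-acid-merged expectation,
which differs when the co-edit translates to the same amino-acid change.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: indels and large deletions, off-target
editing, PCR duplicates and chimera formation beyond simple template
switching, position-dependent error profiles, overdispersed counts, and
fitness effects that vary between replicates.  Recovery results on
simulated screens bound the statistical behaviour of the estimators under
the stated model, not the wet-lab artifacts of any particular experiment.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at desk scale, chosen to keep each end-to-end check well-powered yet
quick: the default 5,000-guide screen for β recovery and classification;
500 guides at a fixed effect (e^f = 0.7, depth 10⁶ ≈ 2,000 reads/guide)
for slope recovery; and a 100–120-guide assay library at 1,000 reads per
guide per sample, with 0.1% errors and 20% recombinants, for read-level
outcome mapping.  Brute-force oracles (exhaustive guide enumeration,
per-read recounting, hypergeometric summation, dense-grid posterior
search) validate each formula at smaller sizes.

## Known limitations

- The experiment constant `l_j` is not estimated; cross-screen β
  comparisons assume comparable editor delivery.
- The recombination filter's Jaro threshold is inherited from the assay
  literature; for libraries of highly similar guides (saturation tiling)
  the mismatch cap, not the Jaro flag, provides most of the protection,
  and recombinants between near-identical guides are undetectable in
  principle.
- Mixture-based calling assumes the β distribution is well described by
  four Gaussian components; strongly multimodal or heavy-tailed screens
  may need the emitted AIC/BIC diagnostics consulted before trusting the
  posterior threshold.
- The FDR of the LOF call set is reported only as an empirical proxy (the
  fraction of synonymous/non-targeting variants among calls); no
  model-based FDR estimate is attempted.
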