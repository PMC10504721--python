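# Methods

## The annotation problem

MALDI mass spectrometry imaging acquires one mass spectrum per pixel of a
tissue section. At the MS1 level a lipid can only be annotated by matching
observed m/z values against theoretical ion masses within a ppm tolerance —
and in-source decay (ISD) makes this ambiguous: fragments produced inside
the ion source are indistinguishable from intact endogenous lipids at the
same nominal mass. A classic example encoded in the bundled tables: the
inositol-headgroup loss of PI c:d is *exactly* isobaric with deprotonated
PA (c+2):(d+2), and PC c:d after methyl loss sits 0.55 mDa (≈0.7 ppm) from
deprotonated PE (c+2):d. Exact mass alone cannot resolve these.

## Likelihood ranking: S = LO · (1 + C)

The package exploits the fact that one lipid ionizes as a family of forms
(adducts and in-source fragments) that co-localize spatially. For each
candidate lipid:

* **LO** (lipid occurrences) — the number of distinct ion forms of the
  lipid's class found in the m/z axis (one best peak per form, chosen by
  minimum |ppm error|, so LO counts ion forms rather than tolerance-window
  multiplicity);
* **C** — the mean Pearson correlation over all LO·(LO−1)/2 distinct pairs
  of the matched ion images;
* **S = LO·(1 + C)** — the ranking score. A lipid observed once has S = 1;
  a lipid observed as 4 strongly co-localized forms has S ≈ 8.

Conventions where the definition is silent: a single-form group has no
pairs, so C = 0 and S = LO; a zero-variance ion image contributes pairwise
r = 0 rather than NaN. An intensity-weighted mean (pair weight = product of
mean ion intensities) is available behind `weighted_correlation=True`; the
unweighted mean is the default and the one all reference numbers use.
Annotations are ranked per m/z feature by descending S with deterministic
tie-breaks (ascending |ppm error|, then lipid name), and optionally
truncated to the top N per feature.

No intensity normalization is applied anywhere.

## Ion-transform arithmetic

Transforms are signed element compositions (gain/loss) plus a charge-carrier
rule: protonation adds one proton mass (1.00727646 Da), deprotonation
removes it, cation/anion attachment and neutral losses leave the proton
count alone. The electron mass is neglected (< 0.6 mDa, below the 2-decimal
reporting precision and well inside a 5 ppm window at lipid masses). Element
masses are IUPAC monoisotopic values; only singly charged ions are modeled.
The default ppm tolerance is 5 ppm (Orbitrap-class data) and is always
user-settable.

The per-class pathway table bundled with the package covers the transforms
listed above for seven phospholipid/sphingolipid classes (PC, PE, PS, PA,
PG, PI, SM); it is a documented default, not an empirical claim, and both
the transform and pathway tables are plain TSVs the user can replace
wholesale (e.g. with empirically derived class tables).

## Deisotoping

Before the search, m/z features attributable to heavy-isotope satellites
are removed: scanning in ascending m/z, peak j is dropped when a kept peak i
satisfies |mz_j − (mz_i + k·1.0033548)| within a ppm tolerance for
k ≤ max_order, the two ion images correlate at r ≥ min_corr, and the mean
intensity ratio j/i is ≤ max_ratio. Defaults: 20 ppm, max_order 2,
min_corr 0.7, max_ratio 1.0. Removed peaks never act as parents, so the
monoisotopic member of a chain always survives and the filter is
idempotent. This is a deliberately simple spacing/correlation/ratio rule: it
does not model theoretical isotope-abundance patterns from the molecular
formula, so a ¹³C₁ satellite more intense than its parent (possible only
for very large molecules, not lipids) or a chance doublet at Δm ≈ 1.0034
with r ≥ 0.7 would be mishandled. `--no-deisotope` skips it for pre-cleaned
matrices.

## Target-decoy validation

Annotation error rates are estimated by searching the same matrix with the
target library and with a decoy library of hypotheses that should not occur,
under identical tolerance, polarity and scoring.

*Implausible transforms*: each real transform is replaced by a decoy built
from one atom of an element foreign to lipid chemistry (B, Si, Sc, Ti, Mn)
plus an integer hydrogen loss sized so the decoy mass shift lands near the
target shift (± a few Da of seeded jitter). This keeps the decoy shift
multiset matched to the target's in count and range, so decoy hypotheses
sample the same m/z neighborhoods. Any decoy whose ion m/z falls within
twice the search tolerance of a target ion m/z is redrawn (bounded
rejection), so the two searches can never claim the same peak. The
construction is a pure function of (library, seed).

*Alternative compounds*: the species list is replaced by out-of-sample
compounds (user-supplied TSV), matched one-to-one to target species by
nearest neutral mass and accepted only if the two-sample Kolmogorov–Smirnov
distance between the mass distributions is ≤ 0.1, so a decoy hit is as
mass-plausible as a target hit. A seeded CHNOP pseudo-compound generator is
provided as a synthetic stand-in for tests and demos; it makes no claim of
biological realism.

Scoring both searches gives one S per candidate lipid (group level).
Performance is summarized as the ROC AUC — computed with the Mann–Whitney
rank formula with average ranks for ties, which is identical to trapezoidal
integration of the tie-grouped ROC curve — with target annotations as the
positive class. FDR is estimated two ways: per top-N cutoff (target and
decoy rows pooled per peak and jointly re-ranked by S; FDR = D/T over
retained rows, capped at 1, with D/(D+T) available as an alternative
estimator), and per S threshold. Raw D/T need not be monotone in the
threshold, so the threshold curve is monotonized to q-values (cumulative
minimum over looser cutoffs) by default.

## Synthetic data: what it emulates and what it does not

The generator plants lipids as families of ion forms sharing one spatial
pattern — a 2-D Gaussian blob with seeded center — plus multiplicative
log-normal pixel noise (sd 0.3 by default; MSI intensities are non-negative
and right-skewed), Gaussian m/z jitter (2 ppm sd), optional isotope
satellites at +k·1.0033548 Da with abundance 0.4^k, and uncorrelated noise
peaks with independent blobs. The reference conditions are a 64×64 grid,
8 planted lipids (4 PC + 4 PI species) × 4 ion forms each, and 30 noise
peaks.

Two deliberate simplifications keep the planted ground truth exact: the
default planted species are chosen so none of their ion forms alias another
species of the bundled table (the PC→PE and PI→PA isobars above are avoided
by picking species whose partners are absent), and random noise peaks are
rejected from ±15 ppm windows around library ion m/z. Real tissue offers no
such courtesy — isobaric overlap is precisely why the score exists — so
passing the recovery tests demonstrates that the machinery ranks a
multi-form, co-localized lipid above single-form isobars at a controlled
effect size, not that real-data annotation reaches any particular accuracy.

Desk-scale validation needs one more ingredient: a 62-peak synthetic matrix
contains no background sea for decoy hypotheses to hit, unlike real
matrices with thousands of unassigned peaks. `validation_scenario` (and
`synth --decoy-background N`) therefore plants N extra uncorrelated
background peaks at ion m/z of distinct decoy species, emulating background
ions that happen to fall in decoy windows. With the reference conditions
the planted lipids score S ≈ 7.6 and decoy hits S ≈ 1, giving AUC ≈ 1.0 —
an exaggerated, controllable separation, not a reproduction of real-data
performance (where reported AUCs for this family of methods sit near 0.7).

Other known gaps: no ion suppression, no matrix-cluster chemical noise, no
isotope-pattern scoring, no multiply charged species, and no sn-position or
isomer resolution (impossible at MS1).

## Numerical and design choices

* Mass jitter at 2 ppm sd against a 5 ppm window means a planted ion
  occasionally (≈1.2% of peaks) jitters outside the search tolerance; the
  recovery metric counts such peaks as misses rather than excluding them.
* Problem sizes in tests (grids 12×12–64×64, ≤ 300 pseudo-compounds,
  5 seeds per stochastic claim) were chosen so the full suite runs in
  seconds while keeping sampling error visibly below the asserted margins.
* Pixel coordinates are integer indices; no physical units enter any
  computation.
* CSV round-trips are bit-exact (intensities printed at full precision);
  imzML import accepts centroid ("processed") files sharing one m/z axis.
* Determinism: every stochastic component takes an explicit seed;
  annotation output order is fully specified by the tie-break rules.
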