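# Methods

`fennelpop` reconstructs, as a reusable and tested pipeline, a combined
chemotypic–genotypic population analysis of wild fennel (*Foeniculum
vulgare*): per-plant measurements are converted into putative allele
frequencies at three loci, populations are compared by Cavalli-Sforza &
Edwards chord distances, and relationships are summarized as neighbor-joining
phenograms.  This note describes the models, the parameters that matter, the
synthetic-data generator, and the numerical choices made where the design was
genuinely open.

## Allele-frequency model

Each plant contributes to three putative loci:

**Phenylpropanoid locus (erc / arc).**  Fennel essential oil is dominated by
two phenylpropanoids sharing a biosynthetic pathway, *trans*-anethole and
estragole.  The estragole relative content

    erc = A_estragole / (A_estragole + A_anethole)

(peak areas from gas chromatography) is treated as a direct allele-frequency
readout of a multicopy biosynthesis locus; `arc = 1 - erc` exactly.
Population frequencies are arithmetic means over plants.  Plants in which
both phenylpropanoid peaks are absent have no defined ratio and are rejected
at parse time rather than silently dropped.

**Fenchone locus (fp / fa).**  Fenchone (a bitter-fennel terpene) is scored
codominantly per plant from its percentage of the total integrated
essential-oil peak area: score 0 when the peak is absent, 2 above the 15 %
threshold, 1 otherwise.  A value exactly at 15 % scores 1: the published
criterion defines only the open intervals, and the heterozygote call is the
conservative choice.  The fenchone-presence frequency pools scores over
haploid genomes, `fp = Σ score / 2N`.  The fenchone percentage is taken
relative to the sum of the three recorded peaks (anethole + estragole +
fenchone); the generator produces areas under the same convention, so the
threshold scorer inverts generated genotypes exactly.

**ITS locus (itsA / itsB / itsC).**  The ~684 bp nrDNA ITS amplicon digested
with MspI (site CCGG, cut after the first C) separates into three diagnostic
bands: 684 bp (uncut allele *itsA*), 529 bp (one site, allele *itsB*,
companion fragment 153 bp) and 344 bp (two sites, allele *itsC*, companions
185 + 153 bp).  Per plant, allele fractions are the densitometric areas of
the 684/529/344 bands normalized to their sum; the small companion fragments
are deliberately excluded from the denominator and used only for structural
validation (344 present ⇒ 185 present; 344 + 185 ≈ 529; 529 + 153 ≈ 684,
±5 bp).  Incomplete digestion is *not* modeled: the full-length band is read
as the itsA signal even though part of it may be undigested template in real
gels — a known limitation of the band-area interpretation.

## Densitometry

Lane traces are reduced to bands by local-maximum detection above a
baseline (default: the 5 % intensity quantile) with a prominence floor
(default: 5 % of the above-baseline dynamic range); band areas integrate the
above-baseline signal between the minima separating adjacent peaks, so areas
partition the total signal.  Fragment sizing interpolates log(size)
piecewise-linearly against migration using the 100 bp ladder; the mapping is
exact at the anchors, and queries outside the anchor range are extrapolated
on the end segments and flagged rather than forbidden.  Detected bands are
assigned to the nearest diagnostic size within a relative tolerance (default
5 %); two bands competing for one diagnostic size is an error, not a silent
choice.

## Distances and trees

Between populations with allele-frequency vectors `p_l`, `q_l` at locus `l`:

    d_l = (2/π) · sqrt( 2 · (1 − Σ_j sqrt(p_lj · q_lj)) )

and the multi-locus distance is the arithmetic mean of `d_l` over the loci
selected by the mode (chemical = fenchone + phenylpropanoid; genetic = ITS;
combined = all three).  Zero frequencies are legal and unsmoothed
(`sqrt(0) = 0`); rounding-induced negative radicands are clamped to zero.
Because legacy software differs in constants, two alternative variants are
exposed (`pooled`: the 2√2/π factor applied once to the root of the
locus-averaged radicand; `unscaled`: the 2/π factor omitted); the default is
the per-locus angular form above.  Printed frequency tables carry three
decimals, so the table reader renormalizes locus blocks whose sums deviate
by up to 0.01 (e.g. ITS rows summing to 0.999); programmatic inputs are held
to 1e-6.

Neighbor joining follows the standard Q-criterion agglomeration with the
canonical branch-length closed forms.  Determinism: taxa are processed in
sorted-label order and Q-ties resolve to the lowest index pair, so results
are independent of input label order.  Negative branch-length estimates are
clamped to zero with the deficit moved to the sister branch, preserving path
lengths through the join.  On additive matrices the output reproduces the
input matrix exactly (tested against brute-force path distances and an
independent library implementation).

Phenogram reading is operationalized as: the *tight pair* is the sister-leaf
pair with the smallest leaf-to-leaf path distance, and the *outermost* leaf
maximizes the mean path distance to all other leaves — an explicit
interpretation of figure language on an unrooted tree; ties break
lexicographically and are flagged.  Clade assertions are checked as splits
of the unrooted tree not containing the outermost leaf.

## Synthetic data generator

The generator emulates the field study's stated structure, per population:

- genotype groups (score 0/1/2) drawn from explicit proportions — observed
  cohorts (8.5 % / 73.9 % / 17.6 % pooled) deviate from Hardy-Weinberg, so
  proportions are free parameters.  Default per-population proportions
  derive from the population's fp by maximal-heterozygosity allocation
  (fp ≤ 0.5 → (1−2fp, 2fp, 0); fp > 0.5 → (0, 2(1−fp), 2fp−1)), which
  reproduces the reference survey's all-heterozygote population (fp = 0.500,
  SD 0.00) exactly;
- fenchone percentage 0 / Uniform(1, 15) / Uniform(15.0001, 60) by genotype —
  the bands exclude the threshold so scoring inverts the genotype exactly;
  the distributions inside the bands are a modeling choice (only the
  threshold and group proportions are reported);
- per-plant erc from a Beta distribution reparameterized by mean and SD
  (defaults: the reference survey's population means and SDs; the wide SDs,
  up to 0.37, give U-shaped Betas matching the observed chemotype extremes);
- per-plant ITS fractions from a Dirichlet around the population target,
  with concentration fitted from the reference itsB SD (the
  largest-variance component; the printed per-component SDs imply slightly
  different concentrations, and one shared value is a deliberate
  simplification).  A zero itsC target produces exactly zero itsC in every
  plant, mirroring the two populations lacking that allele;
- gel bands at migrations from a log-linear gel geometry shared with the
  100 bp ladder, areas = fraction × lane intensity × mean-one lognormal
  noise with CV `noise_cv_band` (default 0.04, which lands replicate
  band-percentage SDs in the reported 0.3–3.5 percentage-point range);
  companion 153/185 bp fragments are rendered at reduced area and never
  quantitated.

Default study size is 17 plants per population (the survey collected ten to
twenty per site, 155 total over nine sites).  The generator does not emulate
PCR amplification bias, partial digestion, heteroduplexes, lane distortion,
or correlated within-plant measurement error; passing recovery tests
therefore validate the analysis chain and the stated noise model, not
robustness to those real-gel artifacts.  Since the raw per-plant field data
are unpublished, the reference population table is reproduced only via the
packaged fixture and via synthetic recovery — not from raw field data.
The true ITS amplicon sequence is likewise unpublished; the in-silico digest
is validated on synthetic stand-in sequences whose MspI sites are placed to
reproduce the diagnostic fragment lengths, and the 684/529/344/185/153
lengths are treated as constants.

## Reproducing the published topology statements

Running the analysis stages on the packaged nine-population reference table
reproduces, under the default chord variant: Rabac as the outermost
population on the chemical and combined phenograms, Ankaran–Padna as a
sister pair on the chemical phenogram, and Flengi–Padna (the two
itsC-lacking populations, also the closest genetic pair) as sisters on the
genetic phenogram.  Two finer combined-tree statements — the coastal
{Ankaran, Buje, Rovinj, Liznjan} and inland {Flengi, Padna, Vodnjan}
clusters — do **not** form clades from the printed three-decimal averages
under any implemented chord variant: the combined Flengi–Plomin distance
(0.059) is half the Flengi–Padna distance (0.121), so Flengi attaches to
Plomin first.  `pipeline.variant_topology_report()` makes the per-variant
outcome of every statement explicit, and `fennelpop check-topology` exits
non-zero when any assertion fails.  The published phenograms came from
legacy software whose exact chord constant and tie handling are not stated,
and only qualitative topology statements are checkable.

## Problem sizes and numerical defaults

Test and acceptance runs use: parameter recovery at 1000 plants per
population across the nine reference populations (recovered fp, erc and ITS
fractions within 3 SE of the generator targets, SE taken from the recovered
per-plant sample SDs); neighbor-joining fidelity on 100 random additive
matrices of 4–8 taxa (exact topology, path distances to 1e-9); digest
length conservation on 1000 random sequence/site/offset cases; replicate
reproducibility on 7 representative profiles in 4 replicates.  Key defaults:
fenchone threshold 15 %, band-matching tolerance 5 %, pattern-validation
slack ±5 bp, band-noise CV 4 %, frequency renormalization tolerance 1e-6
(programmatic) / 0.01 (printed tables).
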