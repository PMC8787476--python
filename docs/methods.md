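# Methods

This note documents the models behind each analysis, the conventions and
tunable parameters, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was open.

## Coordinate model and conventions

Structures are read with gemmi from mmCIF or PDB; residues are polymer when
their chemical component is a tabulated amino acid (so MSE stays in the chain
and is emitted as `X` in sequences), everything else — waters, ions, ligands —
is hetero. Author (envelope-precursor) residue numbering is preserved
everywhere; sequence indices are 1-based. For geometry the highest-occupancy
alternate conformer is used; atom counts can be taken over all records or over
unique atom names, the two conventions refinement tables use.

Chain assemblies are connected components of a chain-contact graph: two chains
are adjacent when at least `min_pairs` (default 10) heavy-atom pairs lie
within a cutoff. The default cutoff of 4.5 Å is an all-atom convention; the
synthetic models here carry only CA, CB and functional-group pseudo-atoms, so
their interchain contacts sit at 5–8 Å and a residue-level cutoff of 8 Å is
used for them (both are plain arguments, nothing is inferred).

## Heptad register and stutter detection

A coiled coil advances its Crick phase — the azimuth of each CA about the
local helix axis, measured from the direction pointing at the bundle core — by
720/7 ≈ 102.86° per residue, and the seven ideal letter phases form a uniform
grid spaced 360/7 ≈ 51.43°, with *a* and *d* flanking the core direction at
±25.7°.

Helices are detected from CA(i)–CA(i+3) and CA(i)–CA(i+4) distances
(defaults 4.5–5.7 Å and 5.7–6.9 Å). The distance series are median-filtered
(window 5) and isolated 1–2 residue violations inside a run are closed, so
moderate coordinate noise (σ ≈ 0.3 Å) does not fragment a genuine helix; on
noise-free coordinates this changes nothing.

The bundle axis is a least-squares line through the smoothed helix-axis
points, refined by minimizing the **variance of radial distances** (the axis
points of a bundle lie on a cylinder around the bundle axis). The cylinder
objective matters: a plain principal-axis fit is biased by several degrees
when segments cover unequal axial ranges, and an axis tilt of ε radians
injects a spurious phase drift of roughly ε·Δz/R₀ along each chain.

Register assignment fits the unwrapped measured phase to

    φ(i) = c + 102.86°·i − Σ_k ramp_k(i),

where each stutter contributes a linear 51.43° slip ramp spread over 8
residues (two helix turns) centred on its 4-residue span. The spread matters
physically — the heptad interruption unwinds the supercoil gradually over
about two turns, and a slip concentrated in 4 residues would push the local
CA geometry outside the α-helical distance windows. Candidate stutter
positions are scanned greedily; a candidate is accepted only when it removes
at least half the residual variance and the residual exceeds an 8° noise
floor. The base letter is quantized at a residue outside every ramp (the
model phase sits on the letter grid only there), and letters advance
canonically with the previous four letters repeated across each span. On
generator output this recovers the exact span (start, start+3) for every
noiseless stutter position and ≈98% of letters at σ = 0.3 Å, with no false
stutters on canonical bundles.

A sequence-only fallback chooses the heptad offset (and optional stutter)
maximizing hydrophobic enrichment at *a*/*d*. The hydrophobic pattern cannot
localize the insertion inside a run of non-core letters, so among equal
scores the canonical `defg` insertion (span preceded by a *g*) is preferred;
a stutter is only called when it beats the best canonical register by a
margin (default 2 score points).

Limitations: the phase model assumes the canonical 3.5-residue/turn advance;
strongly non-canonical supercoils (pitch far from ~175 Å) would register as a
systematic phase slope the model does not fit. Helical wheels classify
residues as hydrophobic {A,V,L,I,M,F,W,C}, acidic {D,E}, basic {K,R,H},
otherwise polar.

## Sequence motif annotation

`find_cx6cc` scans for C-x₆-C-C and reports (first, third) cysteine author
positions; `find_furin_sites` scans R-x-[K/R]-R and reports the final
arginine (cleavage follows it); overlapping matches are all reported.
Region segmentation is anchored on a single CX₆CC hit: CR spans from 6
residues before the first cysteine through the third cysteine (reproducing
543–557 for a motif at 549–557); the ISD is the 17-mer ending immediately
before the first cysteine (532–548); the tether is the 6 residues after the
CR; HR2 runs from there to the construct end and HR1 is everything before the
CR. {HR1, CR, tether, HR2} tile the construct exactly. The tether length and
the CR lead-in are constants of the retroviral TM architecture, exposed as
module parameters.

## Elastic structural alignment and Z-derived distances

The similarity of a monotone residue correspondence is the classic
distance-matrix elastic score, summed over ordered pairs of aligned positions:

    S = Σ_{(k,l)} [θ − |d_A(k,l) − d_B(k,l)| / d*(k,l)] · exp(−(d*(k,l)/α)²),

with d* the mean of the two intramolecular CA distances, θ = 0.20 and
α = 20 Å (both exposed); each diagonal k = l pair contributes θ. The score is
exactly invariant under rigid motion of either structure.

The optimizer seeds from all near-zero diagonal offsets, a coarse sweep of
other offsets, a few seeded random monotone matchings and — for structures of
≤ 12 residues — the exhaustively enumerated best 3-pair correspondences. Each
seed is refined by iterative dynamic programming: cell weights are the
marginal elastic gain of matching (i, j) against the current correspondence,
and a zero-gap-penalty Needleman–Wunsch pass yields the next correspondence;
iteration stops when the true score stops improving. Everything is
deterministic given the seed. Against an exhaustive oracle over all monotone
correspondences on ≤ 8-residue structures the heuristic attains the optimum
(ratio 1.0 over 50 random cases; the test bound is ≥ 0.95). Superposition
RMSD is computed by Kabsch SVD over the aligned CAs.

Z-scores use the published mean-score calibration
m(L) = 7.95 + 0.71·L − 2.59·10⁻⁴·L² − 1.92·10⁻⁶·L³ at L = √(L_A·L_B), held
constant above L = 400: Z = (S − m)/(0.5·m).

The pairwise distance is the literal published form
d(A,B) = max(0, Z_AA + Z_BB − Z_AB), with the diagonal forced to zero and
negatives clipped. This form is length-biased: for near-identical structures
d ≈ Z_self, which grows with length, so heterogeneous sets can show within-
family distances exceeding between-family ones. The normalized variant
d = max(0, Z_AA + Z_BB − 2·Z_AB) — zero for identical structures and
length-unbiased — is exposed via `normalized=True` and is what the clustering
pipeline and the lineage-recovery simulation use.

Dendrograms default to average-linkage (UPGMA) agglomeration with ties broken
by lexicographic leaf-label order; merge heights are half the cophenetic
distance, and the scipy-format linkage is kept so the k-cluster cut is exact.
Neighbor joining (scikit-bio) is available but supports no height-based cut.
Newick serialization sanitizes spaces to underscores and round-trips topology
and branch lengths.

## Six-helix-bundle electrostatics

Salt bridges are Asp/Glu carboxylate-O to Arg/Lys/His side-chain-N pairs with
minimum distance ≤ 4.0 Å (a common literature convention; His counts as basic
because TM bundles use Glu–His pairs at mildly acidic pH), deduplicated per
residue pair and classified inter/intrachain. Bridge networks are connected
components of the residue graph; a 3-residue component whose central residue
carries two bridges is reported as a triad (the acid-bridging-two-bases
cross-link motif).

The axial charge profile bins charged residues by the axial coordinate of
their side-chain centroid (bin width 4 Å; charges Asp/Glu −1, Arg/Lys +1,
His +0.5). The anion stripe is the most negative maximal contiguous bin run
with net charge ≤ −2 contributed by ≥ 2 chains; basic flanks are the nearest
runs with net ≥ +2 within 6 bins of each stripe edge. Continuum
(Poisson–Boltzmann) electrostatics is deliberately out of scope; the discrete
axial binning makes the stripe/flank description operational and testable.

Ion sites are hetero atoms of a chosen element with ≥ 3 protein N/O donors
within 3.5 Å; the radial offset from the bundle axis is reported when an axis
is supplied (an on-axis ion has offset ≈ 0).

## Conservation

The per-column score is the Jensen–Shannon divergence (base 2) between the
column's amino-acid composition (gaps excluded; columns > 50% gaps unscored)
and a background distribution (uniform over 20 by default), normalized by the
largest divergence any single-residue column can reach against that
background — so an invariant column scores exactly 1 and a background-like
column 0. Grades mimic the familiar 1–9 conservation scale: grade 9 is
reserved for invariant columns; variable scored columns are binned 1–8 by
empirical quantile. Mapping to the structure pairs the k-th non-gap reference
position with the k-th construct residue; region averages are arithmetic
means of grades. This score is a defined, reproducible substitute for
empirical-Bayes evolutionary-rate estimation: it preserves qualitative region
rankings but is not phylogeny-aware (no tree, no rate matrix), so absolute
grade values should not be compared with rate-based tools.

## SEC and CD biophysics

K_av = (V_e − V_o)/(V_c − V_o) with V_o = 8 mL and V_c = 24 mL as defaults
(the study's column). Calibration is a least-squares line of K_av against
log₁₀ MW ("log" is log₁₀, standard SEC practice) through the four Methods
standards (BSA 66.5 kDa, ovalbumin 44 kDa, carbonic anhydrase 30 kDa,
myoglobin 17 kDa; γ-globulin at 158 kDa marks the void volume and is not a
calibration point). MW estimation inverts the line; oligomeric state is the
nearest integer of apparent/monomer MW (monomer 13.3 kDa for the PERV TM
construct, one third of the 39.9 kDa theoretical trimer).

Mean residue ellipticity: θ_MRE = (MW/(N−1)) · (θ/(10·d·c)) with θ in mdeg,
d in cm, c in mg/mL.

Melt normalization maps the signal affinely so the folded baseline is 0 and
the unfolded baseline 1, with baselines estimated as the means of the two
lowest- and two highest-temperature points; endpoint averages are unbiased
under noise, whereas a global min/max map acquires an extreme-value bias of
~0.15 °C in the fitted midpoint at σ = 0.02.

Melts are fitted to y(T) = Σ_p f_p/(1 + exp((Tm_p − T)/k_p)) with Σf_p = 1 by
multi-start nonlinear least squares (lmfit); slopes are bounded k ≥ 1 °C
because transitions steeper than one 5 °C grid step cannot be resolved and
would overfit single noisy points. A biphasic fit falls back to a single
transition when an F-test (α = 0.05) finds the second transition
insignificant, when its amplitude is < 0.1 or below twice its standard error,
or when the two midpoints are closer than one grid step. On the study grid
(15–95 °C in 5 °C steps, σ = 0.02) the single-transition midpoint is
recovered with |bias| < 0.03 °C and per-fit scatter ≈ 0.2 °C — the
Cramér–Rao floor of a logistic midpoint on this design — so individual fits
are accurate to about half a degree, and roughly 95% of draws land within
±0.5 °C; genuine 0.4/0.6 biphasic curves retain both transitions within
±1 °C. The Tm-vs-pH table reports the dominant transition per pH and the
max–min spread (≈ 0.5 °C for pH-independent synthetic suites).

## Synthetic generators: what they emulate, and what they do not

`make_coiled_coil` places CAs on Crick curves (R₀ = 6.5 Å, R₁ = 2.26 Å,
rise 1.51 Å, left-handed pitch 175 Å — textbook trimer values, all exposed)
with the ground-truth register string returned alongside; stutters enter as
the 8-residue slip ramp with a compensating local supercoil unwinding, so the
local helix geometry stays canonical — exactly the structure the register
analyzer models. Residues carry CA, a CB pseudo-atom 1.5 Å further out, and a
single functional-group pseudo-atom for charged residues. `make_6hb` adds
antiparallel outer helices in the grooves plus optional engineered Glu/Arg
rings and an axial ion with its Asn donor ring. `make_protomer` builds
HR1–loop–HR2 hairpins whose chain-reversal length is the lineage driver.
`make_msa` is a tree-free block model (independent rows, per-region
substitution probabilities, uniform replacement); `make_melt` and
`make_sec_standards` realize the logistic-sum and calibration-line models
with seeded Gaussian noise. All generators are bit-reproducible given a seed.

These objects are schematic: no backbone N/C/O atoms, no rotamers, no
physical relaxation, no phylogenetic correlation between MSA rows, and
engineered functional groups are placed to realize stated interaction
geometries rather than derived from side-chain chemistry. Passing tests
therefore demonstrate that each algorithm recovers the ground truth its input
encodes under the stated noise — they do not certify performance on
experimental coordinates, where side-chain flexibility, missing atoms and
non-ideal helices add failure modes these generators do not model.

`perv_standin` composes these pieces into a synthetic reference object with
the residue-level layout of the postfusion PERV TM: the 493–587 construct
span, the CX₆CC motif at 549–557, the 506-VTED-509 stutter, the QNRR motif at
533–536 with the N534 chloride ring, the six reported salt bridges, the
E521/E522/D561 anion stripe with its K572/R574/R576 and R535/R536 basic
flanks, and a two-trimer crystal-form arrangement. Its coordinates are
synthetic throughout — it is a ground-truth test object, not the deposited
structure.

## Problem sizes used by the test suite and acceptance script

Register properties use 100 random 42-residue trimers at σ = 0.3 Å; the
alignment oracle uses 50 random 5–8-residue toys (exhaustive enumeration is
exponential); the lineage simulation runs 20 replicates of 3 families × 3
protomers (chain-reversal lengths 3/14/28, σ = 0.3 Å); melt recovery uses 100
seeded curves on the 17-point study grid; conservation ranking uses 100
block-model MSAs of 16 rows × 95 columns. These sizes make every check
re-runnable in minutes on one CPU while keeping the Monte-Carlo assertions
well away from their pass thresholds.
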