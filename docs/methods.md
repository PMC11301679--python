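# Methods

This note records the models, conventions and numerical choices behind the
toolkit, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Mass bookkeeping and chemistry model

Every annotated species reduces to an elemental composition: residue
formulas (pyteomics `std_aa_comp`) plus one water, then adduct deltas.
The adduct chemistry (configurable via `data/chemistry.yaml`) is:

| adduct | elements | H displaced | Cys consumed |
|---|---|---|---|
| Cu(I) | +Cu | 1 | 0 (budget uses `min_cys_per_metal`) |
| Zn(II), Cd(II) | +Zn / +Cd | 2 | 0 (idem) |
| NEM | +C6H7NO2 | 0 | 1 |
| CAM (from iodoacetamide) | +C2H3NO | 0 | 1 |
| disulfide (SS, "ox") | — | 2 | 2 |
| N-terminal acetyl | +C2H2O | 0 | 0 |

Charge arithmetic uses the proton mass 1.007276 Da (distinct from the H
atom, 1.007825 Da): `m/z = (M + z·1.007276)/z`.  Metals displace protons at
the neutral level, so the observed charge is carried entirely by added
protons.

Candidate enumeration filters the Cartesian product of per-adduct ranges by
the cysteine budget `n_NEM + n_IAM + 2·n_SS + m·n_metals ≤ n_Cys` with
`min_cys_per_metal` m = 1 by default, not 2: a 20-Cys protein is observed
carrying four Cu(I), up to thirteen NEM and two disulfides simultaneously,
which is arithmetically incompatible with strict two-thiolates-per-metal;
bridging thiolates make 1 the safe lower bound.  Ordering is lexicographic
for reproducibility.

**Element reference data.**  Isotope masses and abundances come from the
NIST table vendored with pyteomics (`nist_mass`).  Element *average* masses
are computed as abundance-weighted means over that table (pyteomics stores
the most abundant isotope, not the element average, at key 0).

**"Monoisotopic" convention.**  Default is most-abundant-isotope per
element.  For C/H/N/O/S/Cu/Zn this equals the lightest isotope; for Cd the
lightest isotope (106Cd, ~1.2%) is rare, so the most-abundant convention
(114Cd) is the useful one.  A `convention="lightest"` flag exists.  All
pattern *fitting* uses full aggregated patterns, so the convention affects
only single-number reporting.

**Residue numbering** is 1-based counting the initiator Met of the supplied
sequence (Met1 included).  Literature on these proteins alternates between
Met-inclusive ("Cys6 and Cys8") and Met-exclusive ("Cys5 and Cys7")
numbering for the same β-domain residues; outputs that report positions
carry both columns (`cys_position_met1`, `cys_position_no_met`) rather than
guessing which convention a reader expects.

## Aggregated isotope patterns

Isotope patterns are *aggregated isotopologue* distributions: one peak per
total nucleon count, with the exact conditional-mean mass as centroid.
Per-element distributions are raised to their atom counts by binary
exponentiation and convolved across elements; after each step peaks below
the pruning threshold (default 1e-6 relative to the base peak; a 1000×
tighter threshold is used for intermediate steps) are discarded, and the
final pattern is renormalized to unit total abundance.  Convolving
aggregates keeps the mean masses exact: the mean of a ~7 kDa protein's
pattern reproduces its average mass to <1e-5 Da.  Fine isotope structure is
deliberately out of scope — native-MS peak widths at the default resolving
power (10,000, Q-ToF class) are two orders of magnitude wider than the
fine-structure splittings.

## Native-spectrum annotation

The fit metric between an observed profile segment and a candidate's
theoretical profile (isotopologues rendered as Gaussians with
FWHM = m/z ÷ resolving power, summed, max-normalized) is cosine
similarity.  It is scale-invariant in the observed intensities and behaves
well when several envelope series interleave.  The acceptance threshold
(`min_score`, default 0.7) and the metric itself are design choices of this
package; the search window is ±3 m/z around each candidate apex, sized for
5+ ions of a ~7.4 kDa protein (one Zn(II) step is ~12.7 m/z at 5+, one NEM
~25 m/z, so windows of distinct stoichiometric neighbours do not fuse,
while genuinely near-isobaric pairs — e.g. Cu4Zn4-ox vs Cu4NEM2-ox, 0.67
m/z apart — share one window).

Candidates that pass the score threshold and share an overlapping window
are jointly deconvolved by non-negative least squares on the profile grid.
The NNLS solution is then refined by backward elimination: components
contributing less than 25% of the largest coefficient in their group are
removed and the remainder refitted, iterating to a fixed point.  Rationale:
one-metal-swap neighbours (e.g. Cu5Zn3 vs Cu4Zn4, 0.17 m/z apart at 5+)
are nearly collinear with the true envelope and siphon 5–20% of its
intensity under noise, while genuinely co-occurring overlap partners
observed in these mixtures contribute well above 25% of their group
maximum.  The trade-off is documented: a true species below ~25% of an
overlapping neighbour's abundance will be reported with score but zero
fitted abundance.  Assignments below `min_score` are dropped entirely;
surviving near-isobaric sets share an ambiguity `group_id` instead of being
collapsed to one answer, with parsimony tie-breaks (fewer adducts, then
fewer metals) ordering equal scores.

Measured behaviour of these defaults on the synthetic harness (recomputed
by `scripts/acceptance.py` and the acceptance tests at run time): top-1
recovery on seeded single-species spectra at SNR 20 and mixture-proportion
errors at SNR 50 for the seven-species Cu/Zn mixture.

## Top-down fragments

Standard conventions: neutral b_i = Σ residues(1..i); neutral
y_j = Σ residues(n−j+1..n) + H2O; so b_i + y_{n−i} = M(parent).  The
N-terminal acetyl rides on b ions.  Adduct partitions between the two
fragments of a cleavage conserve the parent totals by construction; labels
are capped by the cysteine count of the fragment span; metals may sit on
either side (no domain assumption — the data decide).

**Disulfides.**  One S–S bridge removes 2 H, but its connectivity is
unknown, and a bridge can only ride on a fragment containing both of its
cysteines.  Default (`ss_mode="parent_only"`): fragments carry no
disulfide, and the conservation identity is stated against the
disulfide-free parent mass.  Override (`ss_mode="partition"`): bridges are
distributed to fragments with ≥ 2·s cysteines and the full parent mass is
conserved.

**Matching** is nearest-candidate within a tolerance (default 20 ppm, a
conventional fragment-search default; an absolute-m/z mode exists for
native top-down data), ties broken by smaller |error| then parsimony.
Note an intrinsic degeneracy: with all adduct partitions enumerated, some
candidates of different identity are isobaric to <1 ppm (e.g. b12 vs
y7+3NEM on the MT3 sequence), so a small fraction of matches is
irreducibly ambiguous no matter the tolerance; the tests quantify this
(≥95% identity-correct on planted spectra).

**Label localization** walks the b-ladder N→C and the y-ladder mirrored:
an increment of k labels across an interval containing exactly k cysteines
assigns the label to each of them; a zero increment marks them unmodified;
any other increment leaves them undetermined.  Indices annotated with
conflicting label counts (co-selected proteoforms) are dropped as
uninformative, and b/y disagreements are flagged as conflicts.  The result
is invariant to annotation input order.

**Fragmentation maps** tabulate supporting ions per cleavage site;
sequence coverage is the percentage of the n−1 sites with ≥1 ion.

## Survival yield and spectrum comparison

SY(V) = precursor-window intensity ÷ total ion intensity of the spectrum
(the alternative fixed-denominator mode — e.g. the precursor intensity at
V = 0 — is available via `reference_total`).  Voltages convert to
center-of-mass energies with argon (39.948 Da) as collision gas:
`E_com = z·V·m_gas/(m_gas + M_ion)`, linear in both V and z.  The decline
is fitted with the logistic `SY(E) = 1/(1+exp((E−E50)/k))`, initialized at
the empirical 50% crossing; fits require ≥4 points and an SY range >0.1,
and an E50 outside the scanned range is flagged extrapolated.  The
logistic form and the all-ion denominator are field-conventional choices
made by this package; both are configurable.

Spectrum comparison pools centroid peaks and clusters them by single
linkage with a 0.05 m/z default tolerance; absent peaks are imputed as
zero intensity for the Pearson correlation (documented consequence:
correlations are computed on the union support, so sparse spectra
correlate lower).  Shared-ion analysis reports per-spectrum counts,
pairwise shared counts with percentages over the pair's union, the
percentage of the global union common to all spectra, and the exact
UpSet-style exclusive-combination table.

## Synthetic data generator

The generator stands in for the instrument in every recovery harness.  It
emulates: isotope envelopes of arbitrary metalloform mixtures at a
configurable resolving power (default 10,000) and charge, baseline offset,
seeded Gaussian intensity noise parametrized as max-signal/SNR, uniform
ppm mass jitter, planted fragment spectra consistent with a chosen label
placement, and SY voltage series following a known logistic.  Default seed
1234; all randomness flows through `numpy.random.default_rng(seed)`, so
outputs are bit-reproducible given the seed.

It does **not** emulate electrospray charge-state distributions, adducts
of ammonium/salt clusters, detector saturation or peak-shape asymmetry.
Passing recovery tests therefore demonstrate the correctness of the
fitting/localization logic under the stated noise model, not instrument-
level robustness; real-data reanalysis should start from mzML conversions
of the deposited raw data.

Problem sizes used by the test and acceptance harnesses — 200
single-species simulations for annotation recovery, a 245-candidate
search space (Cu 0–6, Zn 0–4, NEM 0–6, two disulfides, 5+), 100 SY
replicates at noise σ = 0.02, 12-point voltage series — were chosen as the
smallest sizes at which the recovery statistics stabilize.

The companion 61-residue, 20-cysteine "MT2-like" protein is a
deliberately artificial sequence (the natural liver-isoform sequences are
not bundled); it exists so the N-acetylated two-domain case is exercised.

## Known limitations

- Vendor raw formats are not read; mzML support covers the standard's
  common core (32/64-bit float arrays, base64, optional zlib) but not
  numpress compression or chromatograms.
- No intensity-based absolute quantification; NNLS abundances are relative
  within a spectrum.
- Disulfide connectivity is bookkeeping only (−2H per bridge); structural
  placement is out of scope.
- ETD/ETnoD spectra, internal fragments and c/z ions are not modelled.
- The localizer assumes one dominant proteoform per selected precursor;
  co-selected proteoforms are detected (conflicting ladder counts) and
  dropped from the ladder rather than deconvolved.
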