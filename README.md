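# metalloform

Annotation of metal/label proteoforms ("metalloforms") of cysteine-rich
proteins from native and top-down mass spectra.

## The problem

Metalloproteins such as the metallothioneins (MTs) exist as mixtures of
*metalloforms*: variants of one protein that differ in the identity and
count of bound metal ions — Cu(I), Zn(II), Cd(II) — on top of covalent
states such as intramolecular disulfides and cysteine alkylation by
N-ethylmaleimide (NEM, +C6H7NO2 per Cys) or iodoacetamide (leaving a
carbamidomethyl/CAM adduct, +C2H3NO per Cys).  Native electrospray MS
preserves the metal–protein complexes, so each metalloform appears as its
own isotope envelope; but many stoichiometries are near-isobaric (one Zn(II)
differs from two NEM by ~3 Da on a ~7.4 kDa protein; one NEM differs from
two CAM by 11.0045 Da), so annotation by accurate mass alone is ambiguous.
This toolkit implements the computational side of a differential-labeling
workflow that resolves such ambiguities:

- **Candidate enumeration** over a configurable chemistry (metals displace
  1 proton for Cu(I), 2 for Zn/Cd; labels and disulfides consume cysteines)
  under the protein's cysteine budget:
  `n_NEM + n_IAM + 2·n_SS + m·n_metals ≤ n_Cys`.
- **Isotope-pattern fitting**: aggregated isotopologue distributions by
  per-element convolution, rendered at the instrument resolving power and
  scored against the observed profile by cosine similarity; overlapping
  candidates are jointly deconvolved by non-negative least squares and
  near-isobaric survivors are reported as an ambiguity group.
- **Top-down CID b/y fragment annotation** with metal/label adduct
  partitions (b_i + y_{n−i} conserve the parent's mass and adduct totals),
  parent-stoichiometry reconstruction from complementary pairs, and
  cysteine-resolved label localization from b/y ladder increments.
- **Survival-yield (SY) analysis**: SY(V) per collision voltage, converted
  to center-of-mass energy `E_com = z·V·m_gas/(m_gas + M_ion)` (argon) and
  fitted with a logistic `SY(E) = 1/(1 + exp((E − E50)/k))`; E50 is the
  relative gas-phase stability.
- **Fragmentation-spectrum comparison**: union peak tables, Pearson
  correlation matrices, and UpSet-style shared-ion percentages.
- **A synthetic-spectrum generator** with seeded noise and full ground
  truth, used by the recovery test harnesses.

The bundled fixture is human metallothionein-3 (UniProt P25713, 68
residues, 20 Cys, Met1-inclusive numbering).

## Worked example

```python
from metalloform import (
    MetalloformComposition, SimulationSpec, annotate, enumerate_candidates,
    mt3, mz, simulate_native,
)

protein = mt3()
cu4zn4 = MetalloformComposition(n_cu=4, n_zn=4, n_ss=2, z=5)
cu4nem2 = MetalloformComposition(n_cu=4, n_nem=2, n_ss=2, z=5)
print(f"Cu4Zn4-ox 5+:  {mz(protein, cu4zn4, 'average'):.2f} m/z")
print(f"Cu4NEM2-ox 5+: {mz(protein, cu4nem2, 'average'):.2f} m/z")

candidates = enumerate_candidates(
    protein, {"Cu": (0, 6), "Zn": (0, 4), "NEM": (0, 2), "SS": (2, 2)}, charges=[5]
)
observed = simulate_native(
    SimulationSpec(protein, [(cu4zn4, 1.0), (cu4nem2, 0.8)], snr=50.0, seed=5)
)
for a in annotate(observed, candidates):
    if a.abundance > 0:
        print(f"{a.composition.name():20s} score={a.score:.3f} "
              f"abundance={a.abundance:.2f} group={a.group_id}")
```

prints

```
Cu4Zn4-ox 5+:  1486.35 m/z
Cu4NEM2-ox 5+: 1485.68 m/z
Cu4Zn4(ox2)5+        score=0.961 abundance=1.00 group=0
Cu4NEM2(ox2)5+       score=0.916 abundance=0.80 group=0
```

Both species round to the same nominal 1486 m/z signal at 5+ — the classic
ambiguity — yet the pattern fit separates them: both are assigned, their
mixing proportions (1.0 : 0.8) are recovered by the joint NNLS fit, and the
shared `group` id records that they are near-isobaric alternatives within
one m/z window.

The same API drives the command line:
`metalloform simulate|annotate|fragmap|sy|compare --config run.yaml`
(all tabular outputs are CSV with stable schemas; every run writes a
`provenance.json` with the config hash, package version and seed).

## Limitations

Vendor raw formats are not read (convert to mzML first); ion mobility,
ETD/ETnoD interpretation, fine-structure isotope resolution and structural
disulfide-connectivity inference are out of scope.  See `docs/methods.md`
for the model assumptions, parameter defaults, and known limitations.
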