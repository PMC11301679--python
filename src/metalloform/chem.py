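"""Elemental compositions, masses and aggregated isotope patterns.

This module is the mass-bookkeeping foundation of the toolkit.  Every
annotated species — an intact metalloform, a b/y fragment, an alkylated
proteoform — reduces to an :class:`ElementalComposition`, and every fit
against an observed native spectrum starts from the aggregated isotope
pattern of that composition.

Isotope masses and abundances come from the NIST reference table vendored
with :mod:`pyteomics` (``pyteomics.mass.nist_mass``); amino-acid residue
formulas come from ``pyteomics.mass.std_aa_comp``.  The isotope-pattern
computation itself (iterative per-element convolution of *aggregated*
isotopologues with pruning) is implemented here: native spectra of ~7 kDa
proteins are fitted at resolving powers where isotopologues aggregated by
nucleon count are the natural peak unit, and fine structure is deliberately
out of scope.

Conventions
-----------
* Residue numbering is 1-based and counts the initiator Met of the supplied
  sequence (Met1 included).  Published work on these proteins alternates
  between Met-inclusive and Met-exclusive numbering for the same β-domain
  cysteines; outputs that report residue positions also carry the
  Met-exclusive alias where relevant (see :mod:`metalloform.topdown`).
* "Monoisotopic" defaults to the most-abundant-isotope-per-element
  convention.  For C/H/N/O/S/Cu/Zn that coincides with the lightest
  isotope; for Cd the lightest isotope (106Cd) is rare and the convention
  matters.  Pattern fitting always uses full aggregated patterns, so the
  convention affects reporting only.
* Proton mass for charge arithmetic is 1.007276 Da (not the H atom mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from pyteomics import fasta as _fasta
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ElementalComposition",
    "ProteinSpecies",
    "AdductDelta",
    "IsotopePattern",
    "ADDUCTS",
    "composition_from_sequence",
    "monoisotopic_mass",
    "average_mass",
    "isotope_pattern",
    "load_chemistry",
    "read_fasta",
]

#: Mass of a proton in Da, used for all m/z <-> neutral-mass arithmetic.
PROTON_MASS = 1.007276

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

_WATER = {"H": 2, "O": 1}


class ElementalComposition(dict):
    """Integer element counts (``{"C": 6, "H": 7, ...}``) with arithmetic.

    Counts must be non-negative after any adduct delta is applied; the
    arithmetic helpers enforce this.  Behaves as a plain mapping otherwise.
    """

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        super().__init__()
        merged: dict[str, int] = dict(counts or {})
        merged.update(kwargs)
        for element, n in merged.items():
            if element not in _pmass.nist_mass:
                raise ValueError(f"unknown element symbol: {element!r}")
            if int(n) != n:
                raise ValueError(f"non-integer count for {element}: {n!r}")
            if n:
                self[element] = int(n)

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for element, n in other.items():
            out[element] = out.get(element, 0) + n
        if any(v < 0 for v in out.values()):
            bad = [e for e, v in out.items() if v < 0]
            raise ValueError(f"negative element count after addition: {bad}")
        return ElementalComposition(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        return self + {e: -n for e, n in other.items()}

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ValueError("cannot scale a composition by a negative factor")
        return ElementalComposition({e: n * k for e, n in self.items()})

    __rmul__ = __mul__

    def hill_formula(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        keys = sorted(self, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{e}{self[e]}" if self[e] != 1 else e for e in keys)


@dataclass(frozen=True)
class AdductDelta:
    """A named mass delta: element gain, hydrogen displacement, Cys budget.

    ``element_delta`` lists the atoms *added* (metal atom, label formula);
    ``hydrogen_displacement`` is the number of backbone/thiol protons lost on
    binding (1 for Cu(I), 2 for divalent metals, 2 per disulfide);
    ``cys_consumed`` is the number of cysteine thiols the adduct occupies for
    budget bookkeeping (labels 1, disulfide 2; metal Cys demand is a separate
    configurable minimum because thiolates bridge).
    """

    name: str
    element_delta: Mapping[str, int]
    hydrogen_displacement: int = 0
    cys_consumed: int = 0

    def net(self) -> dict[str, int]:
        """Net element change including displaced hydrogens."""
        out = dict(self.element_delta)
        if self.hydrogen_displacement:
            out["H"] = out.get("H", 0) - self.hydrogen_displacement
        return out

    def apply(self, comp: ElementalComposition, count: int = 1) -> ElementalComposition:
        delta = {e: n * count for e, n in self.net().items()}
        return comp + delta

    def remove(self, comp: ElementalComposition, count: int = 1) -> ElementalComposition:
        delta = {e: -n * count for e, n in self.net().items()}
        return comp + delta


#: Built-in adduct chemistry: Cu(I) displaces one proton, Zn(II)/Cd(II) two;
#: NEM (N-ethylmaleimide, Michael addition) adds C6H7NO2 on one Cys;
#: CAM (carbamidomethyl, the iodoacetamide adduct) adds C2H3NO on one Cys;
#: one intramolecular disulfide removes two hydrogens and ties up two Cys;
#: N-terminal acetylation adds C2H2O.
ADDUCTS: dict[str, AdductDelta] = {
    "Cu_I": AdductDelta("Cu_I", {"Cu": 1}, hydrogen_displacement=1),
    "Zn_II": AdductDelta("Zn_II", {"Zn": 1}, hydrogen_displacement=2),
    "Cd_II": AdductDelta("Cd_II", {"Cd": 1}, hydrogen_displacement=2),
    "NEM": AdductDelta("NEM", {"C": 6, "H": 7, "N": 1, "O": 2}, cys_consumed=1),
    "CAM": AdductDelta("CAM", {"C": 2, "H": 3, "N": 1, "O": 1}, cys_consumed=1),
    "SS": AdductDelta("SS", {}, hydrogen_displacement=2, cys_consumed=2),
    "NtermAcetyl": AdductDelta("NtermAcetyl", {"C": 2, "H": 2, "O": 1}),
}


@dataclass(frozen=True)
class FixedModification:
    """A fixed covalent modification applied to every matching residue."""

    name: str
    formula: Mapping[str, int]
    residue: str  # one-letter target


@dataclass(frozen=True)
class ProteinSpecies:
    """A protein sequence plus terminal state and fixed modifications."""

    identifier: str
    sequence: str
    n_terminal_acetyl: bool = False
    fixed_modifications: tuple[FixedModification, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = [
            (i + 1, aa)
            for i, aa in enumerate(self.sequence)
            if aa not in _CANONICAL
        ]
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if bad:
            pos, aa = bad[0]
            raise ValueError(
                f"non-canonical residue {aa!r} at position {pos} in {self.identifier}"
            )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    def cys_positions(self) -> tuple[int, ...]:
        """1-based cysteine positions, Met1 included in the numbering."""
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa == "C")

    def cys_in_span(self, start: int, stop: int) -> int:
        """Number of cysteines in the 1-based inclusive residue span."""
        return self.sequence[start - 1 : stop].count("C")


def _residue_composition(aa: str) -> ElementalComposition:
    return ElementalComposition(dict(_pmass.std_aa_comp[aa]))


def composition_from_sequence(protein: ProteinSpecies) -> ElementalComposition:
    """Elemental composition of the intact (reduced, apo) protein.

    Sum of residue compositions plus one water for the termini; the
    N-terminal acetyl delta is included when flagged, as are any fixed
    modifications (once per matching residue).
    """
    comp = ElementalComposition(_WATER)
    for aa in protein.sequence:
        comp = comp + _residue_composition(aa)
    if protein.n_terminal_acetyl:
        comp = ADDUCTS["NtermAcetyl"].apply(comp)
    for mod in protein.fixed_modifications:
        n = protein.sequence.count(mod.residue)
        comp = comp + {e: c * n for e, c in mod.formula.items()}
    return comp


def _isotopes(element: str) -> list[tuple[int, float, float]]:
    """(mass number, mass, abundance) for naturally occurring isotopes."""
    table = _pmass.nist_mass[element]
    iso = [(k, m, a) for k, (m, a) in table.items() if k != 0 and a > 0]
    if not iso:
        # mono-isotopic synthetic entries: fall back to the key-0 mass
        m, _ = table[0]
        iso = [(int(round(m)), m, 1.0)]
    return sorted(iso)


def monoisotopic_mass(
    comp: Mapping[str, int], convention: str = "most_abundant"
) -> float:
    """Single-isotopologue mass of a composition.

    ``convention="most_abundant"`` (default) picks each element's most
    abundant isotope; ``"lightest"`` picks the lightest naturally occurring
    one.  The two differ only for elements like Cd whose lightest isotope is
    rare.
    """
    if convention not in ("most_abundant", "lightest"):
        raise ValueError(f"unknown monoisotopic convention: {convention!r}")
    total = 0.0
    for element, n in comp.items():
        iso = _isotopes(element)
        if convention == "lightest":
            m = iso[0][1]
        else:
            m = max(iso, key=lambda t: t[2])[1]
        total += n * m
    return total


def average_mass(comp: Mapping[str, int]) -> float:
    """Abundance-weighted average mass of a composition in Da."""
    total = 0.0
    for element, n in comp.items():
        iso = _isotopes(element)
        total += n * sum(m * a for _, m, a in iso)
    return total


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue distribution of a neutral composition.

    ``masses`` are centroid neutral masses (Da) of isotopologues aggregated
    by total nucleon count, strictly increasing; ``abundances`` are
    normalized to sum to 1.
    """

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, float))
        object.__setattr__(self, "abundances", np.asarray(self.abundances, float))
        if self.masses.shape != self.abundances.shape:
            raise ValueError("masses and abundances must have equal length")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("masses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.masses)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.masses.tolist(), self.abundances.tolist()))

    def mean_mass(self) -> float:
        return float(np.dot(self.masses, self.abundances))

    def apex_mass(self) -> float:
        return float(self.masses[int(np.argmax(self.abundances))])

    def charged_mz(self, z: int) -> np.ndarray:
        """m/z positions of the pattern for a +z protonated ion."""
        if z < 1:
            raise ValueError("charge must be >= 1")
        return (self.masses + z * PROTON_MASS) / z


# -- aggregated-distribution arithmetic ------------------------------------
# A distribution is a pair (mu, p): arrays indexed by nucleon offset k from
# the lightest isotopologue; p[k] is the probability mass, mu[k] the
# conditional-mean mass.  Convolution of aggregates keeps means exact:
# E[m1+m2 | k1+k2=k] is a p-weighted average of mu1[k1]+mu2[k2].


def _convolve(mu1, p1, mu2, p2):
    p = np.convolve(p1, p2)
    w = np.convolve(p1 * mu1, p2) + np.convolve(p1, p2 * mu2)
    mu = np.divide(w, p, out=np.zeros_like(w), where=p > 0)
    return mu, p


def _prune(mu, p, threshold):
    if p.size == 0:
        return mu, p
    keep = p >= threshold * p.max()
    # trim leading/trailing zeros but preserve index offsets by re-anchoring:
    # we only ever prune tails, so drop contiguous False runs at both ends
    idx = np.where(keep)[0]
    lo, hi = idx[0], idx[-1] + 1
    return mu[lo:hi].copy(), p[lo:hi].copy()


def _element_distribution(element: str) -> tuple[np.ndarray, np.ndarray]:
    iso = _isotopes(element)
    k0 = iso[0][0]
    size = iso[-1][0] - k0 + 1
    mu = np.zeros(size)
    p = np.zeros(size)
    for k, m, a in iso:
        mu[k - k0] = m
        p[k - k0] = a
    return mu, p


def _element_power(element: str, n: int, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of n atoms of one element by binary exponentiation."""
    mu_base, p_base = _element_distribution(element)
    result: tuple[np.ndarray, np.ndarray] | None = None
    mu, p = mu_base, p_base
    while n > 0:
        if n & 1:
            if result is None:
                result = (mu.copy(), p.copy())
            else:
                result = _prune(*_convolve(*result, mu, p), threshold)
        n >>= 1
        if n:
            mu, p = _prune(*_convolve(mu, p, mu, p), threshold)
    assert result is not None
    return result


def isotope_pattern(
    comp: Mapping[str, int], prune: float = 1e-6
) -> IsotopePattern:
    """Aggregated isotope pattern of a neutral composition.

    Per-element distributions are raised to their atom counts by repeated
    squaring and convolved across elements; after each step, aggregated
    peaks below ``prune`` (relative to the most abundant peak, with a
    tighter internal threshold during intermediate steps to protect
    accuracy) are discarded.  The result is normalized to unit total
    abundance.
    """
    if not (0 < prune < 1):
        raise ValueError("prune must be in (0, 1)")
    inner = prune * 1e-3
    mu = np.array([0.0])
    p = np.array([1.0])
    for element, n in sorted(comp.items()):
        if n < 0:
            raise ValueError(f"negative count for element {element}")
        if n == 0:
            continue
        mu_e, p_e = _element_power(element, n, inner)
        mu, p = _prune(*_convolve(mu, p, mu_e, p_e), inner)
    mu, p = _prune(mu, p, prune)
    p = p / p.sum()
    order = np.argsort(mu)
    return IsotopePattern(mu[order], p[order])


def convolve_patterns(
    a: IsotopePattern, b: IsotopePattern, prune: float = 1e-6
) -> IsotopePattern:
    """Convolution of two aggregated patterns (pattern of the summed species).

    Aggregation is by nearest-Da bins of the summed centroid masses, which
    matches the nucleon-count aggregation used by :func:`isotope_pattern`.
    """
    masses = (a.masses[:, None] + b.masses[None, :]).ravel()
    probs = (a.abundances[:, None] * b.abundances[None, :]).ravel()
    bins = np.round(masses - masses.min()).astype(int)
    size = bins.max() + 1
    p = np.bincount(bins, weights=probs, minlength=size)
    w = np.bincount(bins, weights=probs * masses, minlength=size)
    keep = p > 0
    mu = w[keep] / p[keep]
    p = p[keep]
    sel = p >= prune * p.max()
    mu, p = mu[sel], p[sel]
    p = p / p.sum()
    order = np.argsort(mu)
    return IsotopePattern(mu[order], p[order])


def load_chemistry(path: str | Path | None = None) -> dict[str, AdductDelta]:
    """Load an adduct chemistry model from a YAML file.

    The file maps adduct names to element deltas, hydrogen displacement and
    cysteine consumption (see ``data/chemistry.yaml`` for the bundled
    defaults, which ``path=None`` returns).  Entries replace or extend the
    built-in set.
    """
    import yaml
    from importlib import resources

    if path is None:
        src = resources.files("metalloform.data") / "chemistry.yaml"
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    adducts = dict(ADDUCTS)
    for name, entry in (raw or {}).get("adducts", {}).items():
        adducts[name] = AdductDelta(
            name=name,
            element_delta={str(k): int(v) for k, v in (entry.get("elements") or {}).items()},
            hydrogen_displacement=int(entry.get("hydrogen_displacement", 0)),
            cys_consumed=int(entry.get("cys_consumed", 0)),
        )
    return adducts


def read_fasta(path: str | Path) -> list[ProteinSpecies]:
    """Read a single- or multi-record FASTA file into protein species.

    The record description becomes the identifier; sequences are validated
    against the 20 canonical letters.
    """
    records = []
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            identifier = description.split()[0] if description else "unnamed"
            records.append(ProteinSpecies(identifier, sequence.strip("*")))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records
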