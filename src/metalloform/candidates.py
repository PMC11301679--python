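"""Candidate metalloform enumeration under the cysteine budget.

A metalloform/proteoform candidate is a count vector over the adducts the
chemistry supports: Cu(I), Zn(II), Cd(II), NEM and CAM (iodoacetamide)
labels, intramolecular disulfides, plus the N-terminal acetyl flag and a
charge state.  The enumeration is a Cartesian product over user-supplied
per-adduct ranges filtered by the cysteine budget

    n_NEM + n_IAM + 2*n_SS + m * (n_Cu + n_Zn + n_Cd) <= n_Cys(protein)

where ``m`` (``min_cys_per_metal``, default 1) is the minimum number of
thiolates a bound metal must engage.  One is the safe lower bound for
bridged metal-thiolate clusters: a 20-Cys protein is observed carrying four
Cu(I) together with up to thirteen NEM labels and two disulfides, which is
incompatible with a strict two-thiolates-per-metal rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .chem import (
    ADDUCTS,
    PROTON_MASS,
    ElementalComposition,
    ProteinSpecies,
    average_mass,
    composition_from_sequence,
    monoisotopic_mass,
)

__all__ = [
    "MetalloformComposition",
    "CandidateSet",
    "enumerate_candidates",
    "neutral_composition",
    "neutral_mass",
    "mz",
    "isobaric_groups",
]

_METALS = ("Cu_I", "Zn_II", "Cd_II")


@dataclass(frozen=True, order=True)
class MetalloformComposition:
    """Adduct stoichiometry of one candidate species.

    Field order defines the deterministic (lexicographic) sort used for
    reproducible candidate tables.
    """

    n_cu: int = 0
    n_zn: int = 0
    n_cd: int = 0
    n_nem: int = 0
    n_iam: int = 0
    n_ss: int = 0
    acetyl: bool = False
    z: int = 1

    def __post_init__(self) -> None:
        for name in ("n_cu", "n_zn", "n_cd", "n_nem", "n_iam", "n_ss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.z < 1:
            raise ValueError("charge z must be >= 1")

    @property
    def n_metals(self) -> int:
        return self.n_cu + self.n_zn + self.n_cd

    @property
    def n_labels(self) -> int:
        return self.n_nem + self.n_iam

    def cys_required(self, min_cys_per_metal: int = 1) -> int:
        return self.n_labels + 2 * self.n_ss + min_cys_per_metal * self.n_metals

    def adduct_counts(self) -> dict[str, int]:
        out = {
            "Cu_I": self.n_cu,
            "Zn_II": self.n_zn,
            "Cd_II": self.n_cd,
            "NEM": self.n_nem,
            "CAM": self.n_iam,
            "SS": self.n_ss,
        }
        if self.acetyl:
            out["NtermAcetyl"] = 1
        return out

    def name(self) -> str:
        """Compact species label, e.g. ``Cu4Zn4(ox2)5+``."""
        parts = []
        for label, n in (
            ("Cu", self.n_cu),
            ("Zn", self.n_zn),
            ("Cd", self.n_cd),
            ("NEM", self.n_nem),
            ("IAM", self.n_iam),
        ):
            if n:
                parts.append(f"{label}{n}")
        if self.acetyl:
            parts.insert(0, "NAc-")
        if not parts:
            parts.append("apo")
        if self.n_ss:
            parts.append(f"(ox{self.n_ss})")
        return "".join(parts) + f"{self.z}+"


def neutral_composition(
    protein: ProteinSpecies, mfc: MetalloformComposition
) -> ElementalComposition:
    """Elemental composition of the neutral adducted species."""
    comp = composition_from_sequence(protein)
    if mfc.acetyl and not protein.n_terminal_acetyl:
        comp = ADDUCTS["NtermAcetyl"].apply(comp)
    for adduct, n in (
        ("Cu_I", mfc.n_cu),
        ("Zn_II", mfc.n_zn),
        ("Cd_II", mfc.n_cd),
        ("NEM", mfc.n_nem),
        ("CAM", mfc.n_iam),
        ("SS", mfc.n_ss),
    ):
        if n:
            comp = ADDUCTS[adduct].apply(comp, n)
    return comp


def neutral_mass(
    protein: ProteinSpecies,
    mfc: MetalloformComposition,
    scale: str = "average",
) -> float:
    """Neutral mass in Da on the requested scale (``average``/``monoisotopic``)."""
    comp = neutral_composition(protein, mfc)
    if scale == "average":
        return average_mass(comp)
    if scale == "monoisotopic":
        return monoisotopic_mass(comp)
    raise ValueError(f"unknown mass scale: {scale!r}")


def mz(
    protein: ProteinSpecies,
    mfc: MetalloformComposition,
    scale: str = "average",
) -> float:
    """m/z of the +z protonated species: (M + z*1.007276)/z.

    Metal charge is already accounted for at the neutral level (metals
    displace protons per the adduct chemistry), so observed charge is
    carried entirely by added protons.
    """
    m = neutral_mass(protein, mfc, scale)
    return (m + mfc.z * PROTON_MASS) / mfc.z


@dataclass
class CandidateSet:
    """Enumerated candidates for one protein with precomputed masses."""

    protein: ProteinSpecies
    candidates: list[MetalloformComposition]
    min_cys_per_metal: int = 1

    def __post_init__(self) -> None:
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidate compositions")

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def table(self) -> pd.DataFrame:
        """Candidate table with neutral masses and m/z on both scales."""
        rows = []
        for c in self.candidates:
            m_avg = neutral_mass(self.protein, c, "average")
            m_mono = neutral_mass(self.protein, c, "monoisotopic")
            rows.append(
                {
                    "species": c.name(),
                    "n_cu": c.n_cu,
                    "n_zn": c.n_zn,
                    "n_cd": c.n_cd,
                    "n_nem": c.n_nem,
                    "n_iam": c.n_iam,
                    "n_ss": c.n_ss,
                    "acetyl": c.acetyl,
                    "z": c.z,
                    "neutral_mass_avg": m_avg,
                    "neutral_mass_mono": m_mono,
                    "mz_avg": (m_avg + c.z * PROTON_MASS) / c.z,
                    "mz_mono": (m_mono + c.z * PROTON_MASS) / c.z,
                }
            )
        return pd.DataFrame(rows)


def enumerate_candidates(
    protein: ProteinSpecies,
    ranges: Mapping[str, tuple[int, int]],
    charges: Sequence[int],
    min_cys_per_metal: int = 1,
    acetyl: bool | None = None,
) -> CandidateSet:
    """Enumerate all compositions admitted by the cysteine budget.

    ``ranges`` maps adduct keys (``Cu``, ``Zn``, ``Cd``, ``NEM``, ``IAM``,
    ``SS``) to inclusive (min, max) count ranges; omitted adducts are fixed
    at zero.  ``acetyl=None`` inherits the protein's flag.  Ordering is
    lexicographic over (n_cu, n_zn, n_cd, n_nem, n_iam, n_ss, z) for
    reproducibility.  Ranges admitting no candidate yield an empty set with
    a warning, not an error.
    """
    if min_cys_per_metal < 0:
        raise ValueError("min_cys_per_metal must be >= 0")
    known = {"Cu", "Zn", "Cd", "NEM", "IAM", "SS"}
    unknown = set(ranges) - known
    if unknown:
        raise ValueError(f"unknown adduct keys in ranges: {sorted(unknown)}")

    def span(key: str) -> range:
        lo, hi = ranges.get(key, (0, 0))
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
        return range(lo, hi + 1)

    use_acetyl = protein.n_terminal_acetyl if acetyl is None else acetyl
    budget = protein.n_cys
    out: list[MetalloformComposition] = []
    for n_cu, n_zn, n_cd, n_nem, n_iam, n_ss in itertools.product(
        span("Cu"), span("Zn"), span("Cd"), span("NEM"), span("IAM"), span("SS")
    ):
        for z in sorted(charges):
            cand = MetalloformComposition(
                n_cu, n_zn, n_cd, n_nem, n_iam, n_ss, acetyl=use_acetyl, z=z
            )
            if cand.cys_required(min_cys_per_metal) <= budget:
                out.append(cand)
    if not out:
        warnings.warn("candidate ranges admit no composition", stacklevel=2)
    out.sort()
    return CandidateSet(protein, out, min_cys_per_metal)


def isobaric_groups(
    cands: CandidateSet,
    z: int,
    window: float = 3.0,
    scale: str = "average",
) -> list[list[MetalloformComposition]]:
    """Partition candidates at charge z into near-isobaric m/z groups.

    Single-linkage clustering: consecutive candidates (by m/z) closer than
    ``window`` m/z join the same group.  Groups and members are sorted by
    m/z; isolated candidates form singleton groups.  This reproduces the
    near-isobaric triads NEM_x IAM_y / NEM_{x+1} IAM_{y-2} / NEM_{x+2}
    IAM_{y-4} seen in double-labeling spectra (one NEM is nearly isobaric
    with two CAM: +11.0045 Da on ~7400 Da, i.e. ~2.2 m/z at 5+).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    members = [c for c in cands if c.z == z]
    if not members:
        return []
    keyed = sorted(
        (mz(cands.protein, c, scale), c) for c in members
    )
    groups: list[list[MetalloformComposition]] = [[keyed[0][1]]]
    last = keyed[0][0]
    for m, c in keyed[1:]:
        if m - last <= window:
            groups[-1].append(c)
        else:
            groups.append([c])
        last = m
    return groups
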