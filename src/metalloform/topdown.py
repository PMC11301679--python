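"""CID b/y fragment generation, matching, label localization and maps.

Fragment mass conventions are the standard ones: for a protein of n
residues, the neutral b_i fragment is the sum of residues 1..i and the
neutral y_j fragment is the sum of residues n-j+1..n plus one water, so
that complementary pairs satisfy b_i + y_{n-i} = M(parent).

Metal and label adducts of the precursor are partitioned between the two
fragments of each cleavage.  Labels are capped by the cysteine count inside
the fragment span; metals may sit on either side of the cleavage (no domain
assumption — the data decide).  Disulfides are a special case: one S-S
bridge removes two hydrogens but its connectivity is unknown, so by default
(``ss_mode="parent_only"``) fragments carry no disulfide and conservation
is stated against the disulfide-free parent mass; ``ss_mode="partition"``
distributes bridges to fragments with at least two cysteines and conserves
the full parent mass.

Residue numbering is Met1-inclusive.  Because the literature on these
proteins also uses Met-exclusive numbering for the β-domain cysteines, the
localization result and fragmentation map report both conventions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .candidates import MetalloformComposition
from .chem import (
    ADDUCTS,
    PROTON_MASS,
    ElementalComposition,
    ProteinSpecies,
    monoisotopic_mass,
)
from .spectra import CENTROID, Spectrum

__all__ = [
    "FragmentCandidate",
    "FragmentAnnotation",
    "LocalizationResult",
    "generate_fragments",
    "match_fragments",
    "complementary_reconstruction",
    "localize_labels",
    "fragmentation_map",
]

_WATER = ElementalComposition({"H": 2, "O": 1})

# adduct partition keys carried on fragments
_PART_KEYS = ("Cu_I", "Zn_II", "Cd_II", "NEM", "CAM", "SS")


def _span_composition(protein: ProteinSpecies, start: int, stop: int) -> ElementalComposition:
    """Residue-sum composition of the 1-based inclusive span (no water)."""
    from pyteomics.mass import std_aa_comp

    comp = ElementalComposition()
    for aa in protein.sequence[start - 1 : stop]:
        comp = comp + dict(std_aa_comp[aa])
    return comp


@dataclass(frozen=True)
class FragmentCandidate:
    """A theoretical b/y fragment with an adduct partition and charge."""

    ion_type: str  # 'b' | 'y'
    index: int  # i in b_i / j in y_j
    adducts: Mapping[str, int]  # counts per _PART_KEYS entry
    z: int
    neutral_mass: float  # monoisotopic, Da
    mz: float

    @property
    def n_adducts(self) -> int:
        return sum(self.adducts.values())

    def span(self, n_residues: int) -> tuple[int, int]:
        """1-based inclusive residue span covered by this fragment."""
        if self.ion_type == "b":
            return (1, self.index)
        return (n_residues - self.index + 1, n_residues)

    def label(self) -> str:
        extras = "".join(
            f"+{n}{k.replace('_I', '').replace('_II', '')}"
            for k, n in sorted(self.adducts.items())
            if n
        )
        return f"{self.ion_type}{self.index}{extras}^{self.z}+"


@dataclass(frozen=True)
class FragmentAnnotation:
    """A fragment candidate matched to an observed peak."""

    candidate: FragmentCandidate
    obs_mz: float
    ppm: float
    intensity: float


def _fragment_neutral_composition(
    protein: ProteinSpecies,
    ion_type: str,
    index: int,
    adducts: Mapping[str, int],
    acetyl: bool,
) -> ElementalComposition:
    n = protein.n_residues
    if ion_type == "b":
        comp = _span_composition(protein, 1, index)
        if acetyl:
            comp = ADDUCTS["NtermAcetyl"].apply(comp)
    elif ion_type == "y":
        comp = _span_composition(protein, n - index + 1, n) + _WATER
    else:
        raise ValueError(f"unsupported ion type: {ion_type!r}")
    for key, count in adducts.items():
        if count:
            comp = ADDUCTS[key].apply(comp, count)
    return comp


def generate_fragments(
    protein: ProteinSpecies,
    parent: MetalloformComposition,
    types: Iterable[str] = ("b", "y"),
    charges: Sequence[int] = (1,),
    partition_cap: int | None = None,
    ss_mode: str = "parent_only",
) -> list[FragmentCandidate]:
    """Enumerate b/y fragment candidates with all admissible adduct partitions.

    For each cleavage i, the parent's metals may land on either fragment
    (0..count each), labels are additionally capped by the cysteine count of
    the fragment span, and disulfides follow ``ss_mode``.  Complementary
    partitions conserve the parent's adduct totals by construction.
    ``partition_cap`` truncates the number of partitions per fragment
    (parsimony order: fewest adducts first); None keeps all.
    """
    if ss_mode not in ("parent_only", "partition"):
        raise ValueError(f"unknown ss_mode: {ss_mode!r}")
    budget_needed = parent.n_labels + 2 * parent.n_ss
    if budget_needed > protein.n_cys:
        raise ValueError(
            f"parent adducts need {budget_needed} Cys, protein has {protein.n_cys}"
        )
    n = protein.n_residues
    acetyl = parent.acetyl or protein.n_terminal_acetyl
    out: list[FragmentCandidate] = []
    for ion_type in types:
        if ion_type not in ("b", "y"):
            raise ValueError(f"unsupported ion type: {ion_type!r}")
        for index in range(1, n):
            if ion_type == "b":
                span = (1, index)
            else:
                span = (n - index + 1, n)
            cys_here = protein.cys_in_span(*span)
            cu_r = range(0, parent.n_cu + 1)
            zn_r = range(0, parent.n_zn + 1)
            cd_r = range(0, parent.n_cd + 1)
            nem_r = range(0, min(parent.n_nem, cys_here) + 1)
            iam_r = range(0, min(parent.n_iam, cys_here) + 1)
            if ss_mode == "partition":
                ss_r = range(0, min(parent.n_ss, cys_here // 2) + 1)
            else:
                ss_r = range(0, 1)
            partitions = [
                dict(zip(_PART_KEYS, combo))
                for combo in itertools.product(cu_r, zn_r, cd_r, nem_r, iam_r, ss_r)
                if combo[3] + combo[4] + 2 * combo[5] <= cys_here
            ]
            partitions.sort(key=lambda p: (sum(p.values()), sorted(p.items())))
            if partition_cap is not None:
                partitions = partitions[:partition_cap]
            for adducts in partitions:
                frag_acetyl = acetyl and ion_type == "b"
                comp = _fragment_neutral_composition(
                    protein, ion_type, index, adducts, frag_acetyl
                )
                m0 = monoisotopic_mass(comp)
                for z in charges:
                    out.append(
                        FragmentCandidate(
                            ion_type,
                            index,
                            adducts,
                            z,
                            m0,
                            (m0 + z * PROTON_MASS) / z,
                        )
                    )
    return out


def match_fragments(
    observed: Spectrum,
    candidates: Sequence[FragmentCandidate],
    tol: float = 20.0,
    tol_unit: str = "ppm",
) -> list[FragmentAnnotation]:
    """Match observed centroid peaks to the nearest candidate within tolerance.

    One candidate per peak; ties are broken by smaller |error|, then by
    parsimony (fewer adducts).  ``tol_unit`` is ``"ppm"`` (default, borrowed
    from typical fragment search tolerances) or ``"mz"`` for an absolute
    window.
    """
    if observed.mode != CENTROID:
        raise ValueError("match_fragments requires a centroided spectrum")
    if tol_unit not in ("ppm", "mz"):
        raise ValueError(f"unknown tolerance unit: {tol_unit!r}")
    if not len(observed) or not candidates:
        return []
    cand_mz = np.array([c.mz for c in candidates])
    order = np.argsort(cand_mz, kind="stable")
    cand_mz = cand_mz[order]
    ordered = [candidates[i] for i in order]
    out: list[FragmentAnnotation] = []
    for m, inten in zip(observed.mz, observed.intensity):
        limit = m * tol * 1e-6 if tol_unit == "ppm" else tol
        lo = np.searchsorted(cand_mz, m - limit, side="left")
        hi = np.searchsorted(cand_mz, m + limit, side="right")
        if lo == hi:
            continue
        best = min(
            range(lo, hi),
            key=lambda i: (abs(cand_mz[i] - m), ordered[i].n_adducts),
        )
        c = ordered[best]
        out.append(
            FragmentAnnotation(c, float(m), float((m - c.mz) / c.mz * 1e6), float(inten))
        )
    return out


def complementary_reconstruction(
    b_ann: FragmentAnnotation,
    y_ann: FragmentAnnotation,
    protein: ProteinSpecies,
) -> MetalloformComposition:
    """Reconstruct the parent stoichiometry from a complementary b/y pair.

    Requires i + j = n; sums the two adduct partitions into the implied
    parent composition (the residue spans tile the full sequence by
    construction).  Raises ValueError otherwise.
    """
    b, y = b_ann.candidate, y_ann.candidate
    if b.ion_type != "b" or y.ion_type != "y":
        raise ValueError("expects one b and one y annotation, in that order")
    n = protein.n_residues
    if b.index + y.index != n:
        raise ValueError(
            f"fragments are not complementary: b{b.index} + y{y.index} != {n} residues"
        )
    totals = {k: b.adducts.get(k, 0) + y.adducts.get(k, 0) for k in _PART_KEYS}
    return MetalloformComposition(
        n_cu=totals["Cu_I"],
        n_zn=totals["Zn_II"],
        n_cd=totals["Cd_II"],
        n_nem=totals["NEM"],
        n_iam=totals["CAM"],
        n_ss=totals["SS"],
        acetyl=protein.n_terminal_acetyl,
        z=1,
    )


#: Cys states reported by the localizer.
LABELED_NEM = "labeled-NEM"
LABELED_IAM = "labeled-IAM"
UNMODIFIED = "unmodified"
UNDETERMINED = "undetermined"


@dataclass
class LocalizationResult:
    """Per-cysteine label states inferred from b/y ladders.

    ``states`` maps Met1-inclusive Cys positions to one of
    ``labeled-NEM`` / ``labeled-IAM`` / ``unmodified`` / ``undetermined``.
    ``support`` maps positions to the fragment labels that bracketed them.
    ``conflicts`` lists positions where the b- and y-ladders disagreed.
    """

    states: dict[int, str]
    support: dict[int, list[str]] = field(default_factory=dict)
    conflicts: list[int] = field(default_factory=list)

    def positions(self, state: str) -> list[int]:
        return sorted(p for p, s in self.states.items() if s == state)

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "cys_position_met1": pos,
                "cys_position_no_met": pos - 1,
                "state": state,
                "support": ";".join(self.support.get(pos, [])),
            }
            for pos, state in sorted(self.states.items())
        ]
        return pd.DataFrame(rows)


def _ladder_walk(
    protein: ProteinSpecies,
    ladder: list[tuple[int, int, str]],
    label_key: str,
    positions_for_index,
) -> tuple[dict[int, str], dict[int, list[str]]]:
    """Walk one ladder of (index, label_count, frag_label) entries.

    Between consecutive informative indices, an increment equal to the
    number of cysteines in the bracketed interval localizes the labels to
    all of them; a zero increment marks them unmodified; anything else is
    ambiguous.
    """
    states: dict[int, str] = {}
    support: dict[int, list[str]] = {}
    prev_index, prev_count, prev_lab = 0, 0, "origin"
    state_name = LABELED_NEM if label_key == "NEM" else LABELED_IAM
    for index, count, lab in sorted(ladder):
        interval = positions_for_index(prev_index, index)
        delta = count - prev_count
        n_cys = len(interval)
        if n_cys:
            if delta == 0:
                verdict = UNMODIFIED
            elif delta == n_cys:
                verdict = state_name
            else:
                verdict = UNDETERMINED
            for pos in interval:
                states[pos] = verdict
                support.setdefault(pos, []).extend([prev_lab, lab])
        prev_index, prev_count, prev_lab = index, count, lab
    return states, support


def localize_labels(
    annotations: Sequence[FragmentAnnotation],
    protein: ProteinSpecies,
    label_key: str = "NEM",
) -> LocalizationResult:
    """Localize one label type on cysteines from annotated b/y ladders.

    The b-ladder is walked N→C and the y-ladder mirrored C→N.  An increment
    of k labels across an interval containing exactly k cysteines assigns
    the label to each of them; intervals with more cysteines than the
    increment stay undetermined.  Indices annotated with conflicting label
    counts (two co-selected proteoforms) are dropped from the ladder as
    uninformative.  Disagreement between the two ladders marks the position
    undetermined and records a conflict.  The result is independent of
    annotation input order.
    """
    if label_key not in ("NEM", "CAM"):
        raise ValueError("label_key must be 'NEM' or 'CAM'")
    n = protein.n_residues
    cys = protein.cys_positions()

    def collect(ion_type: str) -> list[tuple[int, int, str]]:
        by_index: dict[int, set[int]] = {}
        for ann in annotations:
            c = ann.candidate
            if c.ion_type != ion_type:
                continue
            by_index.setdefault(c.index, set()).add(c.adducts.get(label_key, 0))
        return [
            (idx, counts.pop(), f"{ion_type}{idx}")
            for idx, counts in by_index.items()
            if len(counts) == 1
        ]

    # b-ladder: interval (prev, cur] in residue positions
    b_states, b_support = _ladder_walk(
        protein,
        collect("b"),
        label_key,
        lambda prev, cur: [p for p in cys if prev < p <= cur],
    )
    # y-ladder mirrored: y_j covers residues n-j+1..n; walking increasing j
    # brackets positions (n-cur, n-prev] from the C-terminus inward
    y_states, y_support = _ladder_walk(
        protein,
        collect("y"),
        label_key,
        lambda prev, cur: [p for p in cys if n - cur < p <= n - prev],
    )

    states: dict[int, str] = {}
    support: dict[int, list[str]] = {}
    conflicts: list[int] = []
    for pos in cys:
        sb, sy = b_states.get(pos), y_states.get(pos)
        verdicts = {s for s in (sb, sy) if s is not None}
        if not verdicts:
            continue
        informative = verdicts - {UNDETERMINED}
        if len(informative) > 1:
            states[pos] = UNDETERMINED
            conflicts.append(pos)
        elif informative:
            states[pos] = informative.pop()
        else:
            states[pos] = UNDETERMINED
        support[pos] = b_support.get(pos, []) + y_support.get(pos, [])
    return LocalizationResult(states, support, conflicts)


def fragmentation_map(
    annotations: Sequence[FragmentAnnotation],
    protein: ProteinSpecies,
) -> tuple[pd.DataFrame, float]:
    """Per-cleavage-site table of supporting ions plus sequence coverage.

    Cleavage site k (1..n-1) sits between residues k and k+1; b_k and
    y_{n-k} both inform it.  Coverage is the percentage of the n-1 sites
    supported by at least one annotated ion.
    """
    n = protein.n_residues
    rows = []
    covered = 0
    by_site: dict[int, list[FragmentAnnotation]] = {}
    for ann in annotations:
        c = ann.candidate
        site = c.index if c.ion_type == "b" else n - c.index
        if 1 <= site <= n - 1:
            by_site.setdefault(site, []).append(ann)
    for site in range(1, n):
        anns = by_site.get(site, [])
        if anns:
            covered += 1
        rows.append(
            {
                "site": site,
                "residue_nterm": protein.sequence[site - 1],
                "residue_cterm": protein.sequence[site],
                "n_ions": len(anns),
                "b_ions": ";".join(
                    a.candidate.label() for a in anns if a.candidate.ion_type == "b"
                ),
                "y_ions": ";".join(
                    a.candidate.label() for a in anns if a.candidate.ion_type == "y"
                ),
            }
        )
    coverage = 100.0 * covered / (n - 1)
    return pd.DataFrame(rows), coverage
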