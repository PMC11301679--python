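"""Assign metalloform compositions to native MS peaks by isotope-pattern fit.

The procedure mirrors standard native-MS practice for metal-protein
complexes: for every candidate stoichiometry a theoretical isotopologue
profile is rendered at the instrument resolving power, each candidate with
observed signal near its apex is scored by cosine similarity against the
observed profile segment, overlapping candidates are jointly deconvolved by
non-negative least squares, and near-isobaric survivors are flagged as an
ambiguity group rather than silently collapsed to one answer.

The fit metric is cosine similarity on resolution-matched profiles — a
scale-invariant choice that behaves well when several envelope series
(e.g. a Cu_x Zn_y series and a Cu_x NEM_z series) interleave in the same
m/z region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import nnls as _nnls

from .candidates import CandidateSet, MetalloformComposition, mz as _candidate_mz, neutral_composition
from .chem import PROTON_MASS, IsotopePattern, ProteinSpecies, isotope_pattern
from .spectra import PROFILE, Spectrum, centroid

__all__ = [
    "Assignment",
    "AnnotatorConfig",
    "theoretical_profile",
    "score_fit",
    "annotate",
]


@dataclass(frozen=True)
class Assignment:
    """One annotated species in an observed spectrum."""

    composition: MetalloformComposition
    z: int
    theo_mz: float
    score: float
    abundance: float
    group_id: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-9):
            raise ValueError("score must lie in [0, 1]")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass
class AnnotatorConfig:
    """Tunable knobs of the annotator.

    resolving_power : m/z over FWHM of a rendered isotopologue peak
        (default 10000, typical of Q-ToF native instruments).
    window : half-width in m/z of the envelope search/score window around
        each candidate apex (default 3.0, sized for 5+ ions of ~7 kDa).
    min_score : assignments scoring below this are dropped (default 0.7).
    snr_min : centroiding signal-to-noise cutoff for envelope detection.
    prune : relative-abundance pruning threshold for isotope patterns.
    """

    resolving_power: float = 10_000.0
    window: float = 3.0
    min_score: float = 0.7
    snr_min: float = 3.0
    prune: float = 1e-6
    grid_step: float | None = None


@lru_cache(maxsize=4096)
def _cached_pattern(
    protein: ProteinSpecies, mfc: MetalloformComposition, prune: float
) -> IsotopePattern:
    """Isotope pattern of a candidate's neutral composition (memoized).

    The charge does not enter the neutral pattern, so callers key with z=1.
    """
    return isotope_pattern(neutral_composition(protein, mfc), prune)


def theoretical_profile(
    protein: ProteinSpecies,
    mfc: MetalloformComposition,
    z: int | None = None,
    resolving_power: float = 10_000.0,
    grid: np.ndarray | None = None,
    prune: float = 1e-6,
) -> Spectrum:
    """Render the charged isotope pattern of a candidate as a profile.

    Each aggregated isotopologue becomes a Gaussian centred at its m/z with
    FWHM = m/z / resolving_power; the summed profile is normalized to unit
    maximum.  A shared ``grid`` may be supplied to sample several candidates
    on the same axis (for joint deconvolution).
    """
    if resolving_power <= 0:
        raise ValueError("resolving_power must be > 0")
    z = mfc.z if z is None else z
    pattern = _cached_pattern(protein, replace(mfc, z=1), prune)
    mz_pos = (pattern.masses + z * PROTON_MASS) / z
    fwhm = mz_pos / resolving_power
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if grid is None:
        lo = mz_pos[0] - 6 * sigma[0]
        hi = mz_pos[-1] + 6 * sigma[-1]
        step = sigma.min() / 4.0
        grid = np.arange(lo, hi + step, step)
    y = np.zeros_like(grid, dtype=float)
    for m, a, s in zip(mz_pos, pattern.abundances, sigma):
        sel = slice(
            np.searchsorted(grid, m - 6 * s), np.searchsorted(grid, m + 6 * s)
        )
        y[sel] += a * np.exp(-0.5 * ((grid[sel] - m) / s) ** 2)
    peak = y.max()
    if peak > 0:
        y = y / peak
    return Spectrum(grid, y, PROFILE, {"label": mfc.name(), "z": z})


def score_fit(
    observed: Spectrum,
    theo: Spectrum,
    window: tuple[float, float] | None = None,
) -> float:
    """Cosine similarity between observed and theoretical profiles.

    The observed spectrum is restricted to ``window`` (default: the
    theoretical profile's support), the theoretical profile is interpolated
    onto the observed grid, and the normalized dot product is returned.
    Scale-invariant in the observed intensities; an empty window scores 0
    with a warning.
    """
    lo, hi = window if window is not None else (theo.mz[0], theo.mz[-1])
    seg = observed.slice(lo, hi)
    if len(seg) == 0 or seg.intensity.max() == 0:
        warnings.warn("empty observation window; score 0", stacklevel=2)
        return 0.0
    t = np.interp(seg.mz, theo.mz, theo.intensity, left=0.0, right=0.0)
    num = float(np.dot(seg.intensity, t))
    den = float(np.linalg.norm(seg.intensity) * np.linalg.norm(t))
    if den == 0:
        return 0.0
    return min(1.0, num / den)


def _overlap_groups(intervals: list[tuple[float, float]]) -> list[list[int]]:
    """Indices grouped by overlapping (lo, hi) intervals, single linkage."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    groups: list[list[int]] = []
    current_hi = -np.inf
    for i in order:
        lo, hi = intervals[i]
        if groups and lo <= current_hi:
            groups[-1].append(i)
            current_hi = max(current_hi, hi)
        else:
            groups.append([i])
            current_hi = hi
    return groups


def annotate(
    observed: Spectrum,
    cands: CandidateSet,
    config: AnnotatorConfig | None = None,
) -> list[Assignment]:
    """Annotate an observed native spectrum against a candidate set.

    Steps: centroid the observation for envelope detection; for every
    candidate whose apex m/z has detected signal within the search window,
    score the resolution-matched theoretical profile by cosine similarity;
    jointly deconvolve candidates with overlapping windows by NNLS on the
    profile; drop scores below ``min_score``; flag surviving near-isobaric
    sets with a shared ambiguity group id.  Returns assignments sorted by
    descending score with parsimony tie-breaks (fewer total adducts, then
    lower metal count).
    """
    cfg = config or AnnotatorConfig()
    protein = cands.protein

    if observed.mode == PROFILE:
        profile = observed
        peaks = centroid(observed, cfg.snr_min)
    else:
        peaks = observed
        # rasterize centroids at the working resolving power for fitting
        if len(observed) == 0:
            return []
        step = observed.mz[0] / cfg.resolving_power / 5.0
        grid = np.arange(observed.mz[0] - 5, observed.mz[-1] + 5, step)
        sigma = grid / cfg.resolving_power / 2.3548
        y = np.zeros_like(grid)
        for m, i in zip(observed.mz, observed.intensity):
            s = m / cfg.resolving_power / 2.3548
            sel = slice(
                np.searchsorted(grid, m - 6 * s), np.searchsorted(grid, m + 6 * s)
            )
            y[sel] += i * np.exp(-0.5 * ((grid[sel] - m) / s) ** 2)
        profile = Spectrum(grid, y, PROFILE, dict(observed.metadata))

    if len(peaks) == 0:
        return []

    # cheap prefilter on the average-mass m/z before any pattern is computed
    peak_mz = peaks.mz
    candidates = [
        c
        for c in cands
        if np.any(np.abs(peak_mz - _candidate_mz(protein, c, "average")) <= cfg.window + 1.0)
    ]

    # candidates with detected signal near their apex
    supported: list[tuple[MetalloformComposition, float, Spectrum]] = []
    for c in candidates:
        theo = theoretical_profile(
            protein, c, resolving_power=cfg.resolving_power, prune=cfg.prune
        )
        apex = float(theo.mz[int(np.argmax(theo.intensity))])
        near = peaks.slice(apex - cfg.window, apex + cfg.window)
        if len(near) == 0:
            continue
        supported.append((c, apex, theo))
    if not supported:
        return []

    scores = [
        score_fit(profile, theo, (apex - cfg.window, apex + cfg.window))
        for _, apex, theo in supported
    ]

    # candidates that fit well enough to enter the joint deconvolution;
    # excluding poor fits keeps NNLS from siphoning intensity into them
    passing = [i for i, s in enumerate(scores) if s >= cfg.min_score]
    if not passing:
        return []

    intervals = {
        i: (supported[i][1] - cfg.window, supported[i][1] + cfg.window)
        for i in passing
    }
    abundances = np.zeros(len(supported))
    for group in _overlap_groups([intervals[i] for i in passing]):
        members = [passing[g] for g in group]
        lo = min(intervals[i][0] for i in members)
        hi = max(intervals[i][1] for i in members)
        seg = profile.slice(lo, hi)
        if len(seg) == 0:
            continue
        design = np.column_stack(
            [
                np.interp(seg.mz, supported[i][2].mz, supported[i][2].intensity,
                          left=0.0, right=0.0)
                for i in members
            ]
        )
        coef, _ = _nnls(design, seg.intensity)
        # backward elimination: components contributing marginally are
        # usually near-collinear neighbours (one-metal swaps ~0.2 m/z away
        # at 5+) siphoning intensity; drop them and refit until stable.
        # 0.25 sits between observed siphon fractions (<~0.2 of the local
        # maximum) and genuinely co-occurring overlap partners.
        active = list(range(len(members)))
        while len(active) > 1:
            sub = coef[active] if len(active) == len(members) else coef
            small = [k for k, a in zip(active, sub) if a < 0.25 * sub.max()]
            if not small:
                break
            active = [k for k in active if k not in small]
            coef, _ = _nnls(design[:, active], seg.intensity)
        if len(active) == len(members):
            final = coef
        else:
            final = np.zeros(len(members))
            final[active] = coef
        for i, a in zip(members, final):
            abundances[i] = a

    kept = [
        (supported[i][0], supported[i][1], scores[i], abundances[i]) for i in passing
    ]

    # ambiguity groups among kept assignments (near-isobaric at same z)
    group_id: dict[int, int | None] = {}
    by_mz = sorted(range(len(kept)), key=lambda i: kept[i][1])
    gid = 0
    run = [by_mz[0]]
    for i in by_mz[1:]:
        if kept[i][1] - kept[run[-1]][1] <= cfg.window and kept[i][0].z == kept[run[-1]][0].z:
            run.append(i)
        else:
            for j in run:
                group_id[j] = gid if len(run) > 1 else None
            if len(run) > 1:
                gid += 1
            run = [i]
    for j in run:
        group_id[j] = gid if len(run) > 1 else None

    def sort_key(item):
        i, (c, apex, s, a) = item
        total_adducts = c.n_metals + c.n_labels + c.n_ss
        return (-s, total_adducts, c.n_metals, c)

    out = [
        Assignment(c, c.z, apex, s, a, group_id[i])
        for i, (c, apex, s, a) in sorted(enumerate(kept), key=sort_key)
    ]
    return out
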