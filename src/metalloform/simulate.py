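"""Synthetic native and fragment spectra with known ground truth.

The simulator stands in for the instrument in every recovery test: it
renders mixtures of metalloform isotope envelopes at a configurable
resolving power with seeded noise, plants fragment ions consistent with a
chosen label placement, and produces survival-yield voltage series from a
known logistic.  Every function is deterministic given its seed; ground
truth is always returned alongside the spectra.

It deliberately does not emulate electrospray charge-state distributions
or detector artifacts — the noise model (Gaussian intensity noise, uniform
ppm jitter on positions) is the simplest one sufficient for parameter
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import theoretical_profile
from .candidates import MetalloformComposition, mz as _mz
from .chem import PROTON_MASS, ProteinSpecies, read_fasta
from .cid import ARGON_MASS, e_com
from .spectra import CENTROID, PROFILE, Spectrum
from .topdown import FragmentCandidate, generate_fragments

__all__ = [
    "DEFAULT_SEED",
    "SimulationSpec",
    "simulate_native",
    "simulate_fragments",
    "simulate_sy_series",
    "mt3",
    "mt2_like",
]

DEFAULT_SEED = 1234


def mt3() -> ProteinSpecies:
    """Human metallothionein-3 (UniProt P25713): 68 residues, 20 Cys.

    The brain isoform whose Cu(I)/Zn(II) metalloforms the toolkit's worked
    examples are built around.  Vendored FASTA; Met1 included in numbering.
    """
    path = resources.files("metalloform.data") / "P25713.fasta"
    with resources.as_file(path) as p:
        return read_fasta(p)[0]


# 61 non-Cys scaffold; cysteines are planted at fixed positions below.
_MT2LIKE_SCAFFOLD = "MDPNASTGGSKEAAQGSVKGASDKEAGSKSDAAKTGEAAKSGEAAKSGDAAKSEAAGKSQA"
_MT2LIKE_CYS = (5, 7, 13, 15, 19, 21, 24, 26, 29, 33, 34, 36, 37, 41, 44, 48, 50, 57, 59, 60)


def mt2_like(acetyl: bool = True) -> ProteinSpecies:
    """Synthetic 61-residue, 20-cysteine companion test protein.

    A deliberately artificial stand-in for a liver-type two-domain MT
    isoform (the real rabbit MT2a/b/c sequences are not bundled): 9 Cys in
    the N-terminal half, 11 in the C-terminal half, optionally N-acetylated
    as the natural isoforms are.  Use real FASTA input for any reanalysis
    of actual MT2 data.
    """
    seq = list(_MT2LIKE_SCAFFOLD)
    for pos in _MT2LIKE_CYS:
        seq[pos - 1] = "C"
    return ProteinSpecies("MT2like-synthetic", "".join(seq), n_terminal_acetyl=acetyl)


@dataclass
class SimulationSpec:
    """Ground-truth description of one simulated native spectrum.

    ``species`` maps compositions (each carrying its charge) to relative
    abundances (> 0).  ``snr`` sets the Gaussian intensity-noise level as
    max_signal/snr; ``baseline`` adds a constant offset in the same units
    (fraction of max signal); ``ppm_error`` shifts every envelope by a
    seeded uniform mass error.
    """

    protein: ProteinSpecies
    species: Sequence[tuple[MetalloformComposition, float]]
    resolving_power: float = 10_000.0
    snr: float | None = 20.0
    baseline: float = 0.0
    ppm_error: float = 0.0
    seed: int = DEFAULT_SEED
    mz_margin: float = 6.0
    grid_step: float | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        if any(a <= 0 for _, a in self.species):
            raise ValueError("species abundances must be > 0")
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be > 0")


def simulate_native(spec: SimulationSpec) -> Spectrum:
    """Render a profile-mode native spectrum for a species mixture.

    Sum of theoretical isotope profiles scaled by abundance, plus baseline
    and seeded Gaussian noise (clipped at zero).  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    apexes = [_mz(spec.protein, c, "average") for c, _ in spec.species]
    lo = min(apexes) - spec.mz_margin
    hi = max(apexes) + spec.mz_margin
    step = spec.grid_step or lo / spec.resolving_power / 6.0
    grid = np.arange(lo, hi + step, step)
    y = np.zeros_like(grid)
    for (c, abundance) in spec.species:
        profile = theoretical_profile(
            spec.protein, c, resolving_power=spec.resolving_power, grid=grid
        )
        shift = 1.0 + rng.uniform(-spec.ppm_error, spec.ppm_error) * 1e-6
        if shift != 1.0:
            y += abundance * np.interp(grid, profile.mz * shift, profile.intensity,
                                       left=0.0, right=0.0)
        else:
            y += abundance * profile.intensity
    peak = y.max() if y.max() > 0 else 1.0
    y = y + spec.baseline * peak
    if spec.snr is not None and spec.snr > 0:
        y = y + rng.normal(0.0, peak / spec.snr, y.size)
    y = np.clip(y, 0.0, None)
    truth = [(c.name(), a) for c, a in spec.species]
    return Spectrum(grid, y, PROFILE, {"label": "simulated", "ground_truth": truth})


def _labels_in_span(placement: Mapping[int, str], span: tuple[int, int], label: str) -> int:
    return sum(
        1 for pos, lab in placement.items() if lab == label and span[0] <= pos <= span[1]
    )


def simulate_fragments(
    protein: ProteinSpecies,
    parent: MetalloformComposition,
    placement: Mapping[int, str],
    types: Sequence[str] = ("b", "y"),
    charges: Sequence[int] = (1,),
    indices: Sequence[int] | None = None,
    metal_span: tuple[int, int] | None = None,
    ppm_jitter: float = 1.0,
    decay: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> tuple[Spectrum, list[FragmentCandidate]]:
    """Simulate a centroided CID fragment spectrum for a known parent.

    ``placement`` maps Cys positions (Met1-inclusive) to 'NEM' or 'CAM';
    its counts must match the parent stoichiometry.  Each requested b/y
    index yields one fragment carrying exactly the labels its span covers;
    parent metals ride on a fragment only when its span contains the whole
    ``metal_span`` (None = metals stay on the precursor).  Peak positions
    get seeded uniform ppm jitter; intensities follow exp(-decay * index)
    (flat by default).  Returns the spectrum and the planted ground-truth
    candidates.
    """
    n_nem = sum(1 for v in placement.values() if v == "NEM")
    n_iam = sum(1 for v in placement.values() if v == "CAM")
    if n_nem != parent.n_nem or n_iam != parent.n_iam:
        raise ValueError(
            f"placement ({n_nem} NEM, {n_iam} CAM) inconsistent with parent "
            f"({parent.n_nem} NEM, {parent.n_iam} CAM)"
        )
    bad = [p for p in placement if protein.sequence[p - 1] != "C"]
    if bad:
        raise ValueError(f"placement on non-Cys positions: {bad}")
    rng = np.random.default_rng(seed)
    n = protein.n_residues
    all_candidates = generate_fragments(protein, parent, types, charges)
    lookup = {
        (c.ion_type, c.index, tuple(sorted(c.adducts.items())), c.z): c
        for c in all_candidates
    }
    planted: list[FragmentCandidate] = []
    use_indices = list(indices) if indices is not None else list(range(1, n))
    for ion_type in types:
        for index in use_indices:
            span = (1, index) if ion_type == "b" else (n - index + 1, n)
            adducts = {
                "Cu_I": 0, "Zn_II": 0, "Cd_II": 0,
                "NEM": _labels_in_span(placement, span, "NEM"),
                "CAM": _labels_in_span(placement, span, "CAM"),
                "SS": 0,
            }
            if metal_span is not None and span[0] <= metal_span[0] and metal_span[1] <= span[1]:
                adducts["Cu_I"] = parent.n_cu
                adducts["Zn_II"] = parent.n_zn
                adducts["Cd_II"] = parent.n_cd
            for z in charges:
                key = (ion_type, index, tuple(sorted(adducts.items())), z)
                cand = lookup.get(key)
                if cand is not None:
                    planted.append(cand)
    if not planted:
        return (
            Spectrum(np.array([]), np.array([]), CENTROID, {"label": "simulated-frag"}),
            [],
        )
    mz_list, int_list = [], []
    for c in planted:
        jitter = 1.0 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6
        mz_list.append(c.mz * jitter)
        int_list.append(float(np.exp(-decay * c.index)))
    order = np.argsort(mz_list, kind="stable")
    mz_arr = np.asarray(mz_list)[order]
    int_arr = np.asarray(int_list)[order]
    keep = np.concatenate(([True], np.diff(mz_arr) > 0))
    spectrum = Spectrum(
        mz_arr[keep], int_arr[keep], CENTROID, {"label": "simulated-frag"}
    )
    return spectrum, planted


def simulate_sy_series(
    e50: float,
    slope: float,
    voltages: Sequence[float],
    z: int,
    ion_mass: float,
    precursor_mz: float | None = None,
    sigma: float = 0.0,
    gas_mass: float = ARGON_MASS,
    seed: int = DEFAULT_SEED,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Voltage series of two-peak spectra following a logistic SY decline.

    At each voltage the precursor peak carries SY(E_com) of the total
    intensity and a single fragment peak the rest; seeded Gaussian noise of
    standard deviation ``sigma`` perturbs the SY value (clipped to [0, 1]).
    Returns the spectra (voltage-tagged) plus a tidy voltage table.
    """
    if len(voltages) == 0:
        raise ValueError("need at least one voltage")
    rng = np.random.default_rng(seed)
    pre_mz = precursor_mz if precursor_mz is not None else (ion_mass + z * PROTON_MASS) / z
    frag_mz = pre_mz / 2.0
    spectra: list[Spectrum] = []
    rows = []
    for v in voltages:
        E = e_com(v, z, ion_mass, gas_mass)
        sy = 1.0 / (1.0 + np.exp((E - e50) / slope))
        if sigma > 0:
            sy = float(np.clip(sy + rng.normal(0.0, sigma), 0.0, 1.0))
        total = 1000.0
        s = Spectrum(
            np.array([frag_mz, pre_mz]),
            np.array([(1.0 - sy) * total, sy * total]),
            CENTROID,
            {"label": f"cid_{v}V", "collision_voltage": float(v)},
        )
        spectra.append(s)
        rows.append({"label": s.metadata["label"], "voltage_V": float(v),
                     "e_com_eV": E, "sy_true": sy})
    return spectra, pd.DataFrame(rows)
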