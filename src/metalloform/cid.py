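"""Survival-yield analysis, E50 fitting, and fragmentation-spectrum comparison.

Survival yield (SY) at one collision voltage is the precursor-window
intensity divided by the total ion intensity (precursor plus fragments) of
that spectrum.  Laboratory collision voltages are converted to
center-of-mass energies

    E_com = z * V * m_gas / (m_gas + M_ion)        [eV]

(argon, 39.948 Da, by default), which puts ions of different mass and
charge on a common energy axis.  The SY decline is fitted with a logistic

    SY(E) = 1 / (1 + exp((E - E50) / k))

whose midpoint E50 is the relative gas-phase stability measure.

Spectrum comparison aligns centroid peaks across spectra into a union peak
table (peaks within ``match_tol`` m/z are the same ion; absent peaks are
zero intensity), from which Pearson correlation matrices and UpSet-style
shared-ion tables are computed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .spectra import CENTROID, Spectrum

__all__ = [
    "ARGON_MASS",
    "SYCurve",
    "SYFit",
    "SYFitError",
    "e_com",
    "survival_yield",
    "fit_sy",
    "union_peak_table",
    "spectral_correlation",
    "shared_ion_analysis",
    "SharedIonResult",
]

#: Average mass of argon, the collision gas, in Da.
ARGON_MASS = 39.948


def e_com(V: float, z: int, ion_mass: float, gas_mass: float = ARGON_MASS) -> float:
    """Center-of-mass collision energy in eV for a +z ion at lab voltage V."""
    if V < 0 or z < 1 or ion_mass <= 0 or gas_mass <= 0:
        raise ValueError("V >= 0, z >= 1, masses > 0 required")
    return z * V * gas_mass / (gas_mass + ion_mass)


@dataclass
class SYCurve:
    """Survival-yield curve for one quadrupole-selected precursor."""

    voltages: np.ndarray  # lab collision voltage, V
    e_com: np.ndarray  # center-of-mass energy, eV
    sy: np.ndarray  # survival yield, [0, 1]
    precursor_window: tuple[float, float]
    z: int
    ion_mass: float

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, float)
        self.e_com = np.asarray(self.e_com, float)
        self.sy = np.asarray(self.sy, float)
        if np.any((self.sy < 0) | (self.sy > 1)):
            raise ValueError("survival yield must lie in [0, 1]")
        if np.any(self.e_com < 0):
            raise ValueError("E_com must be >= 0")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"voltage_V": self.voltages, "e_com_eV": self.e_com, "sy": self.sy}
        )


@dataclass(frozen=True)
class SYFit:
    """Logistic fit of an SY curve."""

    e50: float  # eV
    slope: float  # k in the logistic, eV
    residual_norm: float
    extrapolated: bool  # E50 outside the scanned E_com range


class SYFitError(RuntimeError):
    """SY fitting failed (degenerate curve or no convergence)."""


def survival_yield(
    spectra: Sequence[Spectrum],
    precursor_window: tuple[float, float],
    z: int,
    ion_mass: float,
    gas_mass: float = ARGON_MASS,
    reference_total: float | None = None,
) -> SYCurve:
    """Build an SY curve from voltage-tagged spectra.

    Each spectrum must carry ``collision_voltage`` metadata.  SY(V) is the
    intensity inside the precursor window over the total ion intensity of
    the spectrum; passing ``reference_total`` instead divides by that fixed
    denominator (e.g. the precursor intensity at V=0).  Zero-total spectra
    are dropped with a warning.  Points are returned sorted by voltage.
    """
    lo, hi = precursor_window
    if not (hi > lo):
        raise ValueError("precursor window must be a non-empty (lo, hi) interval")
    rows = []
    for s in spectra:
        v = s.metadata.get("collision_voltage")
        if v is None:
            raise ValueError("every spectrum needs collision_voltage metadata")
        total = reference_total if reference_total is not None else s.total_intensity()
        if total <= 0:
            warnings.warn(f"zero total intensity at {v} V; point dropped", stacklevel=2)
            continue
        sy = min(1.0, s.total_intensity(lo, hi) / total)
        rows.append((float(v), sy))
    rows.sort()
    volts = np.array([r[0] for r in rows])
    sy = np.array([r[1] for r in rows])
    energies = np.array([e_com(v, z, ion_mass, gas_mass) for v in volts])
    return SYCurve(volts, energies, sy, (lo, hi), z, ion_mass)


def _logistic(E, e50, k):
    return 1.0 / (1.0 + np.exp((E - e50) / k))


def fit_sy(curve: SYCurve) -> SYFit:
    """Least-squares logistic fit; E50 initialized at the empirical crossing.

    Requires at least four points spanning an actual SY decline (range
    > 0.1); flat or rising curves raise :class:`SYFitError`, as does
    non-convergence.
    """
    E, y = curve.e_com, curve.sy
    if E.size < 4:
        raise SYFitError(f"need >= 4 points, got {E.size}")
    if y.max() - y.min() < 0.1:
        raise SYFitError(
            f"no SY decline to fit (range {y.max() - y.min():.3f} over "
            f"{E.min():.3g}-{E.max():.3g} eV)"
        )
    # empirical 50% crossing for initialization
    half = 0.5 * (y.max() + y.min())
    below = np.where(y <= half)[0]
    e50_0 = E[below[0]] if below.size else E[-1]
    k_0 = max((E.max() - E.min()) / 10.0, 1e-3)
    try:
        popt, _ = curve_fit(
            _logistic, E, y, p0=(e50_0, k_0), maxfev=20_000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise SYFitError(f"logistic fit did not converge: {exc}") from exc
    e50, k = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(_logistic(E, *popt) - y))
    extrapolated = not (E.min() <= e50 <= E.max())
    return SYFit(e50, k, resid, extrapolated)


def union_peak_table(
    spectra: Sequence[Spectrum], match_tol: float = 0.05
) -> pd.DataFrame:
    """Align centroid peaks across spectra into a union intensity table.

    Peaks from all spectra are pooled and clustered by single linkage:
    consecutive pooled m/z values closer than ``match_tol`` belong to the
    same ion.  Rows are spectra (by metadata label or index), columns are
    cluster centroid m/z; absent ions are 0.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    for s in spectra:
        if s.mode != CENTROID:
            raise ValueError("union_peak_table requires centroided spectra")
    labels = [
        str(s.metadata.get("label", f"spectrum_{i}")) for i, s in enumerate(spectra)
    ]
    pool = []
    for row, s in enumerate(spectra):
        for m, i in zip(s.mz, s.intensity):
            pool.append((m, row, i))
    if not pool:
        return pd.DataFrame(index=labels)
    pool.sort()
    clusters: list[list[tuple[float, int, float]]] = [[pool[0]]]
    for entry in pool[1:]:
        if entry[0] - clusters[-1][-1][0] <= match_tol:
            clusters[-1].append(entry)
        else:
            clusters.append([entry])
    data = np.zeros((len(spectra), len(clusters)))
    centers = []
    for j, cl in enumerate(clusters):
        centers.append(float(np.mean([e[0] for e in cl])))
        for _, row, inten in cl:
            data[row, j] += inten
    return pd.DataFrame(data, index=labels, columns=centers)


def spectral_correlation(
    spectra: Sequence[Spectrum], match_tol: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation matrix of ion intensities across spectra.

    Built on the union peak table (absent peaks imputed as zero).
    Symmetric with unit diagonal; rows for spectra with fewer than two
    peaks are undefined (NaN off-diagonal) and flagged with a warning.
    """
    table = union_peak_table(spectra, match_tol)
    n = len(spectra)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    x = table.to_numpy()
    degenerate = [i for i, s in enumerate(spectra) if len(s) < 2]
    if degenerate:
        warnings.warn(
            f"spectra with <2 peaks have undefined correlations: {degenerate}",
            stacklevel=2,
        )
    for i in range(n):
        for j in range(i + 1, n):
            if i in degenerate or j in degenerate:
                continue
            xi, xj = x[i], x[j]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=table.index, columns=table.index)


@dataclass
class SharedIonResult:
    """UpSet-style shared-ion bookkeeping across fragmentation spectra.

    ``counts``: detected-peak count per spectrum.
    ``pairwise``: for every spectrum pair, shared-ion count and percentage
    (shared over the pair's union).
    ``common_pct``: percentage of the global union detected in *all* spectra.
    ``exclusive``: exact UpSet combination table — for every non-empty
    membership pattern, the number of union ions detected in exactly that
    subset of spectra.
    """

    counts: pd.Series
    pairwise: pd.DataFrame
    common_pct: float
    exclusive: pd.DataFrame


def shared_ion_analysis(
    spectra: Sequence[Spectrum], match_tol: float = 0.05
) -> SharedIonResult:
    """Shared-ion (UpSet-style) analysis of >= 2 centroided spectra."""
    table = union_peak_table(spectra, match_tol)
    present = table.to_numpy() > 0
    labels = list(table.index)
    counts = pd.Series(present.sum(axis=1), index=labels, name="n_peaks")
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        shared = int(np.sum(present[i] & present[j]))
        union = int(np.sum(present[i] | present[j]))
        rows.append(
            {
                "a": labels[i],
                "b": labels[j],
                "shared": shared,
                "union": union,
                "shared_pct": 100.0 * shared / union if union else 0.0,
            }
        )
    pairwise = pd.DataFrame(rows)
    n_union = present.any(axis=0).sum()
    n_common = present.all(axis=0).sum()
    common_pct = 100.0 * n_common / n_union if n_union else 0.0
    patterns: dict[tuple[bool, ...], int] = {}
    for col in range(present.shape[1]):
        key = tuple(bool(v) for v in present[:, col])
        patterns[key] = patterns.get(key, 0) + 1
    excl_rows = [
        {
            "members": ";".join(l for l, flag in zip(labels, key) if flag),
            "degree": sum(key),
            "count": count,
            "pct_of_union": 100.0 * count / n_union if n_union else 0.0,
        }
        for key, count in sorted(patterns.items(), key=lambda kv: (-sum(kv[0]), kv[0]))
        if any(key)
    ]
    exclusive = pd.DataFrame(excl_rows)
    return SharedIonResult(counts, pairwise, common_pct, exclusive)
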