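"""Suspension-level accounting for a liposome population.

Scales the per-vesicle geometry up to a whole suspension: how many vesicles
a given lipid concentration can form, what fraction of the suspension volume
their cores (or membranes) occupy, and the mass balances of the bench
protocol (filter-centrifugation concentration, drug-aliquot mixing).

Size polydispersity is described by the DLS polydispersity index (PDI),
interpreted as the squared coefficient of variation of the diameter
distribution — the standard cumulant-analysis convention.  Polydisperse
populations are modelled as lognormal in diameter and all expectations are
taken by deterministic quadrature; a seeded Monte-Carlo sampler is provided
as an independent cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import integrate, stats

from ._units import AVOGADRO, LITRES_PER_NM3, MOLAR_PER_MM
from .geometry import (
    DEFAULT_AREA_PER_LIPID_NM2,
    DEFAULT_BILAYER_THICKNESS_NM,
    Vesicle,
    core_volume,
    lipids_per_vesicle,
    membrane_volume,
)

__all__ = [
    "SizeDistribution",
    "Suspension",
    "number_density",
    "excluded_volume_fraction",
    "concentrate",
    "mix",
    "sample_diameters",
    "read_diameters_csv",
    "write_diameters_csv",
]

#: Margin (nm) above the degenerate diameter 2t at which lognormal
#: distributions are truncated to keep the vesicle geometry valid.
TRUNCATION_MARGIN_NM = 1.0

Phase = Literal["core", "membrane"]


@dataclass(frozen=True)
class SizeDistribution:
    """Diameter distribution of a vesicle population.

    ``pdi`` is the DLS polydispersity index == squared coefficient of
    variation of the diameters.  ``pdi == 0`` denotes a monodisperse
    population; otherwise diameters are lognormal with

        sigma_ln^2 = ln(1 + pdi),   mu = ln(mean) - sigma_ln^2 / 2

    so that the distribution mean equals ``mean_diameter_nm`` and
    CV^2 equals ``pdi`` exactly.
    """

    mean_diameter_nm: float
    pdi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mean_diameter_nm > 0.0):
            raise ValueError(
                f"mean_diameter_nm must be > 0, got {self.mean_diameter_nm}"
            )
        if not (0.0 <= self.pdi < 1.0):
            raise ValueError(f"pdi must be in [0, 1), got {self.pdi}")

    @property
    def kind(self) -> str:
        return "monodisperse" if self.pdi == 0.0 else "lognormal"

    @property
    def sigma_ln(self) -> float:
        return math.sqrt(math.log1p(self.pdi))

    @property
    def mu_ln(self) -> float:
        return math.log(self.mean_diameter_nm) - 0.5 * math.log1p(self.pdi)

    def frozen(self) -> stats.rv_continuous:
        """The untruncated lognormal as a frozen scipy distribution."""
        if self.pdi == 0.0:
            raise ValueError("a monodisperse distribution has no density")
        return stats.lognorm(s=self.sigma_ln, scale=math.exp(self.mu_ln))


@dataclass(frozen=True)
class Suspension:
    """A liposome suspension.

    ``lipid_concentration_mM`` is the *countable* lipid (DSPC by default;
    cholesterol contributes to membrane geometry but not to drug-to-lipid
    mole ratios unless the caller folds it in).
    """

    lipid_concentration_mM: float
    volume_uL: float
    distribution: SizeDistribution
    bilayer_thickness_nm: float = DEFAULT_BILAYER_THICKNESS_NM
    area_per_lipid_nm2: float = DEFAULT_AREA_PER_LIPID_NM2

    def __post_init__(self) -> None:
        if self.lipid_concentration_mM < 0.0:
            raise ValueError("lipid_concentration_mM must be >= 0")
        if not (self.volume_uL > 0.0):
            raise ValueError("volume_uL must be > 0")
        if self.bilayer_thickness_nm < 0.0:
            raise ValueError("bilayer_thickness_nm must be >= 0")
        if not (self.area_per_lipid_nm2 > 0.0):
            raise ValueError("area_per_lipid_nm2 must be > 0")
        d_min = 2.0 * self.bilayer_thickness_nm
        if self.distribution.mean_diameter_nm <= d_min:
            raise ValueError(
                "mean diameter must exceed twice the bilayer thickness "
                f"({self.distribution.mean_diameter_nm} nm <= {d_min} nm)"
            )

    @property
    def lipid_mol(self) -> float:
        """Moles of countable lipid in the suspension."""
        return self.lipid_concentration_mM * MOLAR_PER_MM * self.volume_uL * 1e-6

    def mean_vesicle(self) -> Vesicle:
        return Vesicle(
            self.distribution.mean_diameter_nm,
            self.bilayer_thickness_nm,
            self.area_per_lipid_nm2,
        )

    def aliquot(self, volume_uL: float) -> "Suspension":
        """A sub-volume of the suspension (same concentrations)."""
        if not (0.0 < volume_uL <= self.volume_uL):
            raise ValueError(
                f"aliquot volume {volume_uL} uL not in (0, {self.volume_uL}]"
            )
        return replace(self, volume_uL=volume_uL)


def _expectation(
    s: Suspension, f: Callable[[Vesicle], float]
) -> float:
    """E[f(vesicle)] over the suspension's size distribution.

    Monodisperse: evaluated at the mean diameter.  Lognormal: quadrature
    over the distribution truncated at ``2t + TRUNCATION_MARGIN_NM`` (the
    smallest geometrically valid diameter); the truncated probability mass
    is reported as a warning when non-negligible.
    """
    dist = s.distribution
    if dist.pdi == 0.0:
        return f(s.mean_vesicle())

    rv = dist.frozen()
    d_min = 2.0 * s.bilayer_thickness_nm + TRUNCATION_MARGIN_NM
    lost = rv.cdf(d_min)
    if lost > 1e-9:
        warnings.warn(
            f"size distribution truncated at {d_min} nm: {lost:.3g} of its "
            "probability mass lies below the smallest valid diameter",
            stacklevel=3,
        )
    norm = 1.0 - lost

    def integrand(d: float) -> float:
        v = Vesicle(d, s.bilayer_thickness_nm, s.area_per_lipid_nm2)
        return f(v) * rv.pdf(d)

    val, _ = integrate.quad(
        integrand, d_min, rv.ppf(1.0 - 1e-12), limit=200
    )
    return val / norm


def number_density(s: Suspension) -> float:
    """Vesicle number density (vesicles per litre of suspension).

    The lipid pool C_L * N_A (molecules per litre) is divided by the mean
    number of lipids per vesicle, E[N_lipids], taken over the size
    distribution.
    """
    if s.lipid_concentration_mM == 0.0:
        return 0.0
    mean_lipids = _expectation(s, lipids_per_vesicle)
    return s.lipid_concentration_mM * MOLAR_PER_MM * AVOGADRO / mean_lipids


def excluded_volume_fraction(s: Suspension, phase: Phase = "core") -> float:
    """Excluded-volume fraction alpha = V_excluded / V_total.

    The cumulative core volume (``phase="core"``, hydrophilic loading) or
    membrane volume (``phase="membrane"``, lipophilic loading) of all
    vesicles, per litre of suspension.  For a polydisperse population both
    the per-vesicle volume and lipid count are averaged over the size
    distribution, so alpha depends only on the ratio E[V] / E[N].
    """
    if phase == "core":
        vol = core_volume
    elif phase == "membrane":
        vol = membrane_volume
    else:
        raise ValueError(f"phase must be 'core' or 'membrane', got {phase!r}")
    if s.lipid_concentration_mM == 0.0:
        return 0.0
    mean_vol_nm3 = _expectation(s, vol)
    mean_lipids = _expectation(s, lipids_per_vesicle)
    alpha = (
        s.lipid_concentration_mM
        * MOLAR_PER_MM
        * AVOGADRO
        * mean_vol_nm3
        * LITRES_PER_NM3
        / mean_lipids
    )
    if alpha >= 1.0:
        raise ValueError(
            f"excluded-volume fraction alpha={alpha:.3g} >= 1: the vesicles "
            "would occupy the whole suspension; check lipid concentration "
            "and geometry"
        )
    return alpha


def concentrate(
    s: Suspension, fold: float, lipid_retention: float = 1.0
) -> Suspension:
    """Concentrate the suspension ``fold`` times by filter centrifugation.

    The volume drops by ``fold``; the lipid concentration rises by
    ``fold * lipid_retention``, where ``lipid_retention`` is the fraction of
    lipid that survives the filter (1.0 for a lossless step).  The size
    distribution is unchanged — filter centrifugation does not significantly
    shift the population diameter.
    """
    if fold < 1.0:
        raise ValueError(f"fold must be >= 1, got {fold}")
    if not (0.0 < lipid_retention <= 1.0):
        raise ValueError(f"lipid_retention must be in (0, 1], got {lipid_retention}")
    return replace(
        s,
        volume_uL=s.volume_uL / fold,
        lipid_concentration_mM=s.lipid_concentration_mM * fold * lipid_retention,
    )


def mix(
    s: Suspension, aliquot_volume_uL: float, aliquot_concentration_mM: float
) -> tuple[Suspension, float]:
    """Add a drug aliquot to the suspension.

    Returns the diluted suspension and the bulk drug concentration C_T
    (mM) after mixing.  Both lipid and drug moles are conserved:

        C_T = C_stock * V_aliquot / (V_aliquot + V_suspension)
    """
    if not (aliquot_volume_uL > 0.0):
        raise ValueError("aliquot_volume_uL must be > 0")
    if aliquot_concentration_mM < 0.0:
        raise ValueError("aliquot_concentration_mM must be >= 0")
    total = s.volume_uL + aliquot_volume_uL
    diluted = replace(
        s,
        volume_uL=total,
        lipid_concentration_mM=s.lipid_concentration_mM * s.volume_uL / total,
    )
    c_t = aliquot_concentration_mM * aliquot_volume_uL / total
    return diluted, c_t


def sample_diameters(
    dist: SizeDistribution,
    n: int,
    seed: int,
    bilayer_thickness_nm: float = DEFAULT_BILAYER_THICKNESS_NM,
) -> np.ndarray:
    """Draw ``n`` vesicle diameters (nm) from the size distribution.

    Lognormal draws below the smallest valid diameter ``2t + 1 nm`` are
    rejected and redrawn; the rejected fraction is reported as a warning.
    Reproducible for a fixed seed.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    rng = np.random.default_rng(seed)
    if dist.pdi == 0.0:
        return np.full(n, dist.mean_diameter_nm)

    d_min = 2.0 * bilayer_thickness_nm + TRUNCATION_MARGIN_NM
    out = np.empty(0)
    drawn = 0
    while out.size < n:
        batch = rng.lognormal(dist.mu_ln, dist.sigma_ln, size=max(n, 1024))
        drawn += batch.size
        out = np.concatenate([out, batch[batch > d_min]])
    rejected = 1.0 - (out.size / drawn) if drawn else 0.0
    if rejected > 1e-6:
        warnings.warn(
            f"rejected {rejected:.3g} of lognormal draws below the minimum "
            f"valid diameter {d_min} nm",
            stacklevel=2,
        )
    return out[:n]


def write_diameters_csv(path: str | Path, diameters_nm: np.ndarray) -> None:
    """Write a diameter sample as a single-column CSV (``diameter_nm``)."""
    pd.DataFrame({"diameter_nm": np.asarray(diameters_nm)}).to_csv(
        path, index=False
    )


def read_diameters_csv(path: str | Path) -> np.ndarray:
    """Read a diameter sample written by :func:`write_diameters_csv`."""
    df = pd.read_csv(path)
    if "diameter_nm" not in df.columns:
        raise ValueError(f"{path}: expected a 'diameter_nm' column")
    return df["diameter_nm"].to_numpy(dtype=float)
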