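"""Post-mortem deamination: profiling and per-observation consistency.

Ancient DNA carries cytosine deamination concentrated at fragment termini,
read as C→T substitutions at the 5' end and — in double-stranded library
preparations — G→A at the 3' end.  This module measures those positional
misincorporation frequencies from an alignment ("smiley plot" profiles),
summarises them with an exponential-decay fit, and provides the predicate
used by the consensus caller to discount individual damage-consistent
observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io import AlignedRead, SequenceRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_WINDOW = 25  # profiling window, bases from each terminus
DEFAULT_DAMAGE_WINDOW = 5  # consistency window d for the consensus caller


@dataclass(frozen=True)
class DamageParams:
    """Parametric deamination summary: p(i) = delta * exp(-lam * i) + floor.

    ``delta`` is the terminal misincorporation amplitude, ``lam`` the decay
    per base moving into the fragment, ``floor`` a position-independent
    baseline.  Distances ``i`` are 0-based from the relevant terminus.
    """

    delta: float
    lam: float
    floor: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0 and 0.0 <= self.floor <= 1.0):
            raise ValueError("delta and floor must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    def rate(self, dist: int) -> float:
        return min(1.0, self.delta * float(np.exp(-self.lam * dist)) + self.floor)


@dataclass
class DamageProfile:
    """Positional misincorporation frequencies from read termini.

    ``ct5[i]`` is the C→T frequency at molecule-5' distance ``i`` (NaN where
    the denominator is zero); ``ga3`` the G→A frequency from the 3' end.
    """

    window: int
    ct5: np.ndarray
    ga3: np.ndarray
    ct5_denominator: np.ndarray
    ga3_denominator: np.ndarray


def is_damage_consistent(
    ref_base: str, observed_base: str, dist5: int, dist3: int, d: int
) -> bool:
    """True iff the observation matches the canonical deamination pattern.

    Bases are in the molecule's own orientation: C→T within ``d`` bases of
    the 5' terminus, or G→A within ``d`` of the 3' terminus.
    """
    if ref_base == "C" and observed_base == "T" and 0 <= dist5 < d:
        return True
    if ref_base == "G" and observed_base == "A" and 0 <= dist3 < d:
        return True
    return False


def _iter_molecule_observations(read: AlignedRead, reference: str):
    """Yield (ref_base, obs_base, dist5, dist3) in molecule orientation.

    Reference positions with non-ACGT reference characters (N, soft-masked
    lower case) are excluded so opportunity counts are not inflated.
    """
    for k, obs in enumerate(read.bases):
        if obs == "-":
            continue
        ref_pos0 = read.ref_start - 1 + k
        if ref_pos0 >= len(reference):
            continue
        ref = reference[ref_pos0]
        if ref not in "ACGT" or obs not in "ACGT":
            continue
        if read.strand == "-":
            ref, obs = _COMP[ref], _COMP[obs]
        yield ref, obs, read.dist5[k], read.dist3[k]


def compute_damage_profile(
    reads: Iterable[AlignedRead],
    reference: str | SequenceRecord,
    window: int = DEFAULT_WINDOW,
) -> DamageProfile:
    """Measure C→T (5') and G→A (3') frequencies per terminus distance.

    ``ct5[i]`` = (# T observed where the molecule-strand reference is C at
    5'-distance i) / (# molecule-C opportunities at distance i); ``ga3``
    symmetric from the 3' terminus.  Order of reads is irrelevant.
    """
    ref = reference.sequence if isinstance(reference, SequenceRecord) else reference
    num5 = np.zeros(window)
    den5 = np.zeros(window)
    num3 = np.zeros(window)
    den3 = np.zeros(window)
    for read in reads:
        for ref_b, obs_b, d5, d3 in _iter_molecule_observations(read, ref):
            if ref_b == "C" and 0 <= d5 < window:
                den5[d5] += 1
                if obs_b == "T":
                    num5[d5] += 1
            if ref_b == "G" and 0 <= d3 < window:
                den3[d3] += 1
                if obs_b == "A":
                    num3[d3] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(den5 > 0, num5 / np.maximum(den5, 1), np.nan)
        ga3 = np.where(den3 > 0, num3 / np.maximum(den3, 1), np.nan)
    return DamageProfile(window, ct5, ga3, den5, den3)


def fit_exponential(profile: DamageProfile) -> tuple[DamageParams, float]:
    """Least-squares fit of delta*exp(-lam*i)+floor to the 5' C→T curve.

    Returns the fitted parameters and the residual sum of squares.  An
    all-zero (or undefined) profile maps to (0, 0, 0) with zero residual.
    """
    defined = ~np.isnan(profile.ct5)
    x = np.nonzero(defined)[0].astype(float)
    y = profile.ct5[defined]
    if x.size < 3:
        raise ValueError("need at least 3 positions with defined frequency")
    if np.allclose(y, 0.0):
        return DamageParams(0.0, 0.0, 0.0), 0.0

    def model(i, delta, lam, floor):
        return delta * np.exp(-lam * i) + floor

    p0 = (max(float(y[0]) - float(y.min()), 1e-3), 0.3, float(y.min()))
    popt, _ = curve_fit(
        model,
        x,
        y,
        p0=p0,
        bounds=([0.0, 0.0, 0.0], [1.0, 10.0, 1.0]),
        maxfev=20000,
    )
    resid = float(np.sum((model(x, *popt) - y) ** 2))
    return DamageParams(float(popt[0]), float(popt[1]), float(popt[2])), resid


def write_profile_tsv(profile: DamageProfile, path) -> None:
    """Write the profile as TSV: position, ct5, ga3, denominators."""
    with open(path, "w") as fh:
        fh.write("position\tct5\tga3\tct5_denominator\tga3_denominator\n")
        for i in range(profile.window):
            ct = "." if np.isnan(profile.ct5[i]) else f"{profile.ct5[i]:.6f}"
            ga = "." if np.isnan(profile.ga3[i]) else f"{profile.ga3[i]:.6f}"
            fh.write(
                f"{i}\t{ct}\t{ga}\t{int(profile.ct5_denominator[i])}\t"
                f"{int(profile.ga3_denominator[i])}\n"
            )
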