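"""Isotopologue patterns of partially 18O-labeled ions.

Forward model
-------------
A metabolite carrying Z enzymatically inserted oxygens incubated under
18O2 at per-site incorporation probability q produces an isotopologue
distribution that is the convolution of

* the natural-abundance fine structure of the formula over all atoms
  except the Z inserted oxygen sites (13C, 2H, 15N, 17O/18O on the
  remaining oxygens, 33S/34S, ...), and
* Z independent inserted-site distributions, each a mixture
  q x {pure 18O} + (1-q) x {natural oxygen}: a site that did not receive
  the label still drew its oxygen from an isotopically natural pool.
  Summing over sites, k labeled insertions shift the ion by
  k x (M18O - M16O) = k x 2.00425 Da with Binomial(Z, q) weights.

At q = 0 the pattern therefore reduces *exactly* to the natural-abundance
pattern of the formula.  q is bounded above by the reagent enrichment
(92.0% 18O2 by default): even a fully O2-derived oxygen can be heavy
only as often as the gas is.

Inverse model
-------------
:func:`estimate_labeling_degree` inverts the forward model from measured
channel areas A_0..A_Z (the unlabeled and k-shifted extracted features).
Each channel is first corrected for the natural heavy-isotope
contribution of the channels below it (natural 18O on non-inserted
oxygens falls in the same +2.00425 window; 13C2 at +2.0067 is outside a
+/-5 ppm window near m/z 300 and is excluded).  After correction the
channel weights are binomial and the maximum-likelihood estimate is
q_hat = sum(k A'_k) / (Z sum(A'_k)).  For Z=1 this reduces to
q_hat = A18' / (A16 + A18').
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .constants import O18_O16_DELTA, isotope_distribution, monoisotopic
from .formula import IonSpec, MolecularFormula, POSITIVE, ion_mz, monoisotopic_mass

__all__ = [
    "IsotopologuePattern",
    "LabelingEstimate",
    "predict_pattern",
    "natural_m2_fraction",
    "estimate_labeling_degree",
    "channel_areas",
]

DEFAULT_REAGENT_ENRICHMENT = 0.92


@dataclass
class IsotopologuePattern:
    """Normalized (m/z, abundance) list with its generating parameters."""

    entries: list[tuple[float, float]]
    formula: MolecularFormula
    z: int = 0
    q: float = 0.0
    reagent_enrichment: float = DEFAULT_REAGENT_ENRICHMENT

    def mzs(self) -> np.ndarray:
        return np.array([m for m, _ in self.entries])

    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.entries])


@dataclass
class LabelingEstimate:
    """Estimated per-site 18O incorporation with a bootstrap interval."""

    q_hat: float
    ci_low: float
    ci_high: float
    areas_used: tuple[float, ...]
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# natural-abundance fine structure


def _convolve(
    a: dict[float, float], b: dict[float, float], threshold: float
) -> dict[float, float]:
    out: dict[float, float] = {}
    for m1, p1 in a.items():
        for m2, p2 in b.items():
            p = p1 * p2
            if p < threshold:
                continue
            m = round(m1 + m2, 9)
            out[m] = out.get(m, 0.0) + p
    return out


def _element_power(
    element: str, n: int, threshold: float
) -> dict[float, float]:
    """Mass-offset distribution of n atoms of one element (offsets from
    n x monoisotopic), by binary exponentiation of the one-atom
    distribution."""
    mono = monoisotopic(element)
    base = {round(m - mono, 9): ab for m, ab in isotope_distribution(element)}
    result: dict[float, float] = {0.0: 1.0}
    power = base
    while n:
        if n & 1:
            result = _convolve(result, power, threshold)
        n >>= 1
        if n:
            power = _convolve(power, power, threshold)
    return result


def natural_fine_structure(
    counts: dict[str, int], threshold: float = 1e-8
) -> list[tuple[float, float]]:
    """Natural-isotope fine structure as (mass offset from monoisotopic,
    abundance), renormalized after pruning terms below ``threshold``."""
    dist: dict[float, float] = {0.0: 1.0}
    for el, n in counts.items():
        if n > 0:
            dist = _convolve(dist, _element_power(el, n, threshold), threshold)
    total = sum(dist.values())
    return sorted((m, p / total) for m, p in dist.items())


# ---------------------------------------------------------------------------
# forward model


def predict_pattern(
    f: MolecularFormula,
    z: int = 0,
    q: float = 0.0,
    reagent_enrichment: float = DEFAULT_REAGENT_ENRICHMENT,
    ion: IonSpec | None = POSITIVE,
    include_natural: bool = True,
    threshold: float = 1e-7,
) -> IsotopologuePattern:
    """Isotopologue pattern of a Z-oxygen-inserted ion at incorporation q.

    With ``ion=None`` the entries are neutral masses.  With
    ``include_natural=False`` only the Binomial(Z, q) label structure is
    returned (useful for didactic checks).  Oxygens already designated
    heavy on ``f`` (``n_heavy_o``) are fixed 18O, excluded from both the
    natural and binomial parts.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if q > reagent_enrichment:
        raise ValueError(
            f"q={q} exceeds reagent enrichment {reagent_enrichment}"
        )
    n_oxygen = f["O"]
    if z < 0 or z + f.n_heavy_o > n_oxygen:
        raise ValueError(
            f"Z={z} (+{f.n_heavy_o} fixed heavy) exceeds oxygen count {n_oxygen}"
        )

    base_mz = ion_mz(f, ion) if ion is not None else monoisotopic_mass(f)

    if include_natural:
        counts = f.counts
        counts["O"] = n_oxygen - z - f.n_heavy_o  # inserted/fixed sites excluded
        nat = natural_fine_structure(counts, threshold=threshold * 1e-1)
        # one inserted site: label with probability q, otherwise an
        # isotopically natural oxygen
        o16 = monoisotopic("O")
        site: dict[float, float] = {}
        for m_iso, ab in isotope_distribution("O"):
            site[round(m_iso - o16, 9)] = (1.0 - q) * ab
        site[round(O18_O16_DELTA, 9)] = site.get(round(O18_O16_DELTA, 9), 0.0) + q
    else:
        nat = [(0.0, 1.0)]
        site = {0.0: 1.0 - q, round(O18_O16_DELTA, 9): q}

    inserted: dict[float, float] = {0.0: 1.0}
    site_power = dict(site)
    n_sites = z
    while n_sites:
        if n_sites & 1:
            inserted = _convolve(inserted, site_power, threshold * 1e-2)
        n_sites >>= 1
        if n_sites:
            site_power = _convolve(site_power, site_power, threshold * 1e-2)

    acc: dict[float, float] = {}
    for dm_n, p_n in nat:
        for dm_i, p_i in inserted.items():
            p = p_n * p_i
            if p < threshold:
                continue
            m = round(base_mz + dm_n + dm_i, 9)
            acc[m] = acc.get(m, 0.0) + p
    total = sum(acc.values())
    entries = sorted((m, p / total) for m, p in acc.items())
    return IsotopologuePattern(
        entries=entries,
        formula=f,
        z=z,
        q=q,
        reagent_enrichment=reagent_enrichment,
    )


def _window_fractions(
    f: MolecularFormula,
    n_excluded_o: int,
    max_shift: int,
    tol_ppm: float,
    window_da: float | None,
) -> list[float]:
    """Natural-pattern abundance near +j x (18O-16O) for j=0..max_shift,
    relative to the monoisotopic line, with ``n_excluded_o`` oxygens
    removed from the natural pool."""
    counts = f.counts
    if counts.get("O", 0) < n_excluded_o:
        raise ValueError("cannot exclude more oxygens than present")
    if n_excluded_o:
        counts["O"] -= n_excluded_o
    nat = natural_fine_structure(counts, threshold=1e-10)
    base = monoisotopic_mass(MolecularFormula(counts))
    fractions: list[float] = []
    for j in range(max_shift + 1):
        center = base + j * O18_O16_DELTA
        half = window_da if window_da is not None else tol_ppm * 1e-6 * center
        s = sum(p for dm, p in nat if abs(base + dm - center) <= half)
        fractions.append(s)
    mono = fractions[0]
    if mono <= 0:
        raise ValueError("monoisotopic line not found in pattern")
    return [s / mono for s in fractions]


def _window_level(
    f: MolecularFormula, n_labeled: int, z: int, tol_ppm: float
) -> tuple[float, list[float]]:
    """(monoisotopic abundance, [+2j-window fractions]) of the natural
    pattern of ``f`` with ``n_labeled`` oxygens removed (those sites are
    fixed 18O and carry no natural structure)."""
    counts = f.counts
    if counts.get("O", 0) < n_labeled:
        raise ValueError("cannot exclude more oxygens than present")
    if n_labeled:
        counts["O"] -= n_labeled
    nat = natural_fine_structure(counts, threshold=1e-10)
    base = monoisotopic_mass(MolecularFormula(counts))
    sums: list[float] = []
    for j in range(z + 1):
        center = base + j * O18_O16_DELTA
        half = tol_ppm * 1e-6 * center
        sums.append(sum(p for dm, p in nat if abs(base + dm - center) <= half))
    mono = sums[0]
    if mono <= 0:
        raise ValueError("monoisotopic line not found in pattern")
    return mono, [s / mono for s in sums]


def natural_m2_fraction(
    f: MolecularFormula,
    tol_ppm: float = 5.0,
    window_da: float | None = None,
) -> float:
    """Natural isotopologue abundance inside the +2.00425 Da channel,
    relative to the monoisotopic line.

    The window is +/-``tol_ppm`` around the 18O-shifted m/z (or an
    absolute ``window_da`` half-width).  At high resolving power the
    default window admits natural 18O (+2.00425) but not 13C2
    (+2.00671); widening the window to +/-0.01 Da (a low-resolution
    instrument) pulls the 13C2 term in.
    """
    if not f:
        return 0.0
    return _window_fractions(f, 0, 1, tol_ppm, window_da)[1]


# ---------------------------------------------------------------------------
# inverse model


def estimate_labeling_degree(
    areas: Sequence[float],
    f: MolecularFormula,
    z: int,
    natural_correction: bool = True,
    reagent_enrichment: float = DEFAULT_REAGENT_ENRICHMENT,
    tol_ppm: float = 5.0,
    n_boot: int = 500,
    boot_pseudo_n: int = 1000,
    seed: int = 0,
) -> LabelingEstimate:
    """Estimate the 18O incorporation probability from channel areas.

    Parameters
    ----------
    areas
        Channel areas ``(A_0, A_1, ..., A_Z)``: the unlabeled feature
        and each k-shifted feature (missing channels as 0).  For Z=1
        this is the classic ``(A16, A18)`` pair.
    f
        Metabolite formula (inserted oxygens counted in its O total).
    z
        Number of inserted oxygen sites (>= 1).
    natural_correction
        Subtract the predicted natural heavy-isotope contribution of
        each channel from the channels above it before fitting.
    n_boot, boot_pseudo_n, seed
        Parametric bootstrap: channel pseudo-counts are drawn from a
        multinomial at the fitted binomial with ``boot_pseudo_n`` total
        counts; percentile 95% interval.  ``n_boot=0`` disables it.
    """
    if z < 1:
        raise ValueError("Z must be >= 1 for labeling-degree estimation")
    areas = [float(a) for a in areas]
    if len(areas) != z + 1:
        raise ValueError(f"expected {z + 1} channel areas, got {len(areas)}")
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    if sum(areas) == 0:
        raise ValueError("all channel areas are zero")

    warnings: list[str] = []
    # Species with i labeled insertions carries the natural fine structure
    # of the formula minus i oxygens; its +2j natural satellites leak into
    # channel i+j.  Deconvolve channel areas level by level:
    #   A'_k = C_k - sum_j r_{k-j}(j) A'_{k-j},   w_k = A'_k / n_k(0),
    # where r_i(j) is species i's +2j-window fraction relative to its own
    # monoisotopic line and n_i(0) the absolute monoisotopic abundance of
    # its natural pattern.  The w_k are then proportional to the binomial
    # label weights and q_hat = sum(k w_k) / (Z sum(w_k)) is exact.
    if natural_correction:
        levels = [
            _window_level(f, i, z, tol_ppm) for i in range(z + 1)
        ]  # (n_i(0), [r_i(j)])
    else:
        levels = [(1.0, [1.0] + [0.0] * z)] * (z + 1)

    corrected = [0.0] * (z + 1)
    weights = [0.0] * (z + 1)
    for k in range(z + 1):
        c = areas[k]
        for j in range(1, k + 1):
            c -= levels[k - j][1][j] * corrected[k - j]
        if c < 0:
            warnings.append(f"negative_corrected_channel_{k}")
            c = 0.0
        corrected[k] = c
        weights[k] = c / levels[k][0]

    total = sum(weights)
    if total == 0:
        q_hat = 0.0
        warnings.append("all_channels_zero_after_correction")
    else:
        q_hat = sum(k * w for k, w in enumerate(weights)) / (z * total)
    q_hat = min(max(q_hat, 0.0), 1.0)
    if q_hat > reagent_enrichment:
        warnings.append("exceeds_reagent_enrichment")

    if n_boot > 0 and total > 0:
        rng = np.random.default_rng(seed)
        p = np.array(
            [comb(z, k) * q_hat**k * (1.0 - q_hat) ** (z - k) for k in range(z + 1)]
        )
        p /= p.sum()
        draws = rng.multinomial(boot_pseudo_n, p, size=n_boot)
        ks = np.arange(z + 1)
        q_boot = (draws * ks).sum(axis=1) / (z * boot_pseudo_n)
        ci_low = float(np.quantile(q_boot, 0.025))
        ci_high = float(np.quantile(q_boot, 0.975))
        ci_low = min(ci_low, q_hat)
        ci_high = max(ci_high, q_hat)
    else:
        ci_low = ci_high = q_hat

    return LabelingEstimate(
        q_hat=q_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        areas_used=tuple(areas),
        warnings=tuple(warnings),
    )


def channel_areas(
    pattern: IsotopologuePattern,
    z: int | None = None,
    tol_ppm: float = 5.0,
) -> list[float]:
    """Integrate a predicted pattern into its Z+1 label channels.

    Sums abundance within +/-``tol_ppm`` of the monoisotopic m/z shifted
    by k x (18O-16O), k = 0..Z — the same windows the pair finder uses
    on measured data.
    """
    if z is None:
        z = pattern.z
    mzs = pattern.mzs()
    abs_ = pattern.abundances()
    base = float(mzs.min())
    out: list[float] = []
    for k in range(z + 1):
        center = base + k * O18_O16_DELTA
        half = tol_ppm * 1e-6 * center
        mask = np.abs(mzs - center) <= half
        out.append(float(abs_[mask].sum()))
    return out
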