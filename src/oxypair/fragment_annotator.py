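"""MS/MS product-ion annotation and label-shift verification.

Product ions are matched to sub-formula hypotheses built from a
fragment core library (data, not code: the packaged default transcribes
the characteristic bupivacaine cores; users supply their own CSV for
other drugs).  For a candidate metabolite, each core yields the
unmodified hypothesis and — when the candidate class can place its
inserted oxygen(s) on that core — oxygen-augmented hypotheses.

Label-shift verification is the MS/MS-level mirror of the pair screen:
every matched fragment that carries an inserted oxygen must reappear in
the labeled spectrum shifted by n x 2.00425 Da, while oxygen-free
fragments must stay put.  Identification is group-level only; positional
isomers within a class produce near-identical spectra and are not
distinguished.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .biotransform import BiotransformCandidate
from .constants import O18_O16_DELTA
from .formula import MolecularFormula, cation_mz, parse_formula, ppm_diff
from .spectra_io import MsmsSpectrum

__all__ = [
    "FragmentHypothesis",
    "FragmentLibraryEntry",
    "AnnotatedSpectrum",
    "LabelShiftResult",
    "load_fragment_library",
    "default_bupivacaine_library",
    "fragment_library",
    "annotate",
    "verify_label_shift",
    "annotation_to_csv",
]


@dataclass(frozen=True)
class FragmentHypothesis:
    """A candidate product-ion composition (even-electron cation)."""

    formula: MolecularFormula
    theoretical_mz: float
    contains_new_oxygen: bool = False
    n_new_oxygen: int = 0
    base_name: str = ""


@dataclass(frozen=True)
class FragmentLibraryEntry:
    formula: MolecularFormula
    classes: frozenset[str] | None       # None = all classes
    oxygen_site_classes: frozenset[str] | None

    def applies_to(self, class_label: str) -> bool:
        return self.classes is None or class_label in self.classes

    def oxygen_site_for(self, class_label: str) -> bool:
        if self.oxygen_site_classes is None:
            return True
        return class_label in self.oxygen_site_classes


@dataclass
class AnnotatedSpectrum:
    spectrum: MsmsSpectrum
    matches: list[tuple[tuple[float, float], FragmentHypothesis, float]]
    unmatched: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class LabelShiftResult:
    pairs: list[tuple[tuple[float, float], tuple[float, float], float]]
    verdict: str                      # "consistent" | "inconsistent"
    o_free_shifted: list[FragmentHypothesis] = field(default_factory=list)


def _parse_class_set(cell: str) -> frozenset[str] | None:
    cell = cell.strip()
    if cell == "*":
        return None
    if not cell:
        return frozenset()
    return frozenset(s.strip() for s in cell.split(";") if s.strip())


def load_fragment_library(path) -> list[FragmentLibraryEntry]:
    """Read a fragment-core library CSV
    (columns: formula, classes, oxygen_site_classes)."""
    entries: list[FragmentLibraryEntry] = []
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.lstrip().startswith("#")]
    for rec in csv.DictReader(rows):
        entries.append(
            FragmentLibraryEntry(
                formula=parse_formula(rec["formula"]),
                classes=_parse_class_set(rec.get("classes", "*")),
                oxygen_site_classes=_parse_class_set(
                    rec.get("oxygen_site_classes", "") or ""
                ),
            )
        )
    if not entries:
        raise ValueError(f"{path}: empty fragment library")
    return entries


def default_bupivacaine_library() -> list[FragmentLibraryEntry]:
    ref = resources.files("oxypair").joinpath("data/bupivacaine_fragments.csv")
    with resources.as_file(ref) as path:
        return load_fragment_library(path)


def _fits_precursor(frag: MolecularFormula, precursor: MolecularFormula) -> bool:
    # +/-2 H slack for rearrangement during fragmentation
    for el, n in frag.counts.items():
        cap = precursor[el] + (2 if el == "H" else 0)
        if n > cap:
            return False
    return True


def fragment_library(
    candidate: BiotransformCandidate,
    base_fragments: Sequence[FragmentLibraryEntry] | None = None,
    strict: bool = False,
) -> list[FragmentHypothesis]:
    """Build product-ion hypotheses for one candidate metabolite.

    For every applicable core the unmodified hypothesis is emitted;
    when the candidate's class places inserted oxygen on the core,
    +kO-augmented hypotheses (k = 1..Z) are added with
    ``contains_new_oxygen`` set.  Cores exceeding the candidate's
    composition are skipped (``strict=True`` raises instead).
    """
    if base_fragments is None:
        base_fragments = default_bupivacaine_library()
    label = candidate.class_label
    out: list[FragmentHypothesis] = []
    for entry in base_fragments:
        if not entry.applies_to(label):
            continue
        if not _fits_precursor(entry.formula, candidate.formula):
            if strict:
                raise ValueError(
                    f"fragment {entry.formula} larger than precursor "
                    f"{candidate.formula}"
                )
            continue
        out.append(
            FragmentHypothesis(
                formula=entry.formula,
                theoretical_mz=cation_mz(entry.formula),
                contains_new_oxygen=False,
                n_new_oxygen=0,
                base_name=str(entry.formula),
            )
        )
        if candidate.z >= 1 and entry.oxygen_site_for(label):
            for k in range(1, candidate.z + 1):
                aug = entry.formula.apply_delta({"O": k})
                if not _fits_precursor(aug, candidate.formula):
                    break
                out.append(
                    FragmentHypothesis(
                        formula=aug,
                        theoretical_mz=cation_mz(aug),
                        contains_new_oxygen=True,
                        n_new_oxygen=k,
                        base_name=str(entry.formula),
                    )
                )
    return out


def annotate(
    spectrum: MsmsSpectrum,
    hypotheses: Sequence[FragmentHypothesis],
    tol_ppm: float = 10.0,
) -> AnnotatedSpectrum:
    """Match peaks to hypotheses: each peak gets its best-|ppm| hypothesis
    within tolerance; unmatched peaks are retained unannotated.
    Deterministic regardless of input peak order."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    matches = []
    unmatched = []
    order = np.argsort(spectrum.mz, kind="stable")
    for i in order:
        peak = (float(spectrum.mz[i]), float(spectrum.intensity[i]))
        best, best_ppm = None, tol_ppm
        for hyp in hypotheses:
            ppm = ppm_diff(peak[0], hyp.theoretical_mz)
            if abs(ppm) <= best_ppm:
                best, best_ppm = (hyp, ppm), abs(ppm)
        if best is None:
            unmatched.append(peak)
        else:
            matches.append((peak, best[0], best[1]))
    return AnnotatedSpectrum(spectrum=spectrum, matches=matches, unmatched=unmatched)


def _has_peak(spectrum: MsmsSpectrum, mz: float, tol_ppm: float) -> tuple[float, float] | None:
    half = tol_ppm * 1e-6 * mz
    idx = np.where(np.abs(spectrum.mz - mz) <= half)[0]
    if idx.size == 0:
        return None
    best = idx[np.argmax(spectrum.intensity[idx])]
    return float(spectrum.mz[best]), float(spectrum.intensity[best])


def verify_label_shift(
    spec_16: MsmsSpectrum,
    spec_18: MsmsSpectrum,
    annotated: AnnotatedSpectrum,
    tol_ppm: float = 10.0,
) -> LabelShiftResult:
    """Check 18O label propagation into annotated fragments.

    For every matched fragment that carries inserted oxygen, the labeled
    spectrum must show a peak at +n x 2.00425 Da; oxygen-free fragments
    must appear at the *same* m/z in both spectra.  Verdict is
    ``consistent`` when at least one shifted pair is found and no
    oxygen-free fragment shifts (i.e. vanishes from its own m/z while a
    +2 peak appears).
    """
    pairs = []
    o_free_shifted = []
    for peak, hyp, _ in annotated.matches:
        if hyp.contains_new_oxygen:
            target = peak[0] + hyp.n_new_oxygen * O18_O16_DELTA
            found = _has_peak(spec_18, target, tol_ppm)
            if found is not None:
                pairs.append((peak, found, found[0] - peak[0]))
        else:
            same = _has_peak(spec_18, peak[0], tol_ppm)
            shifted = _has_peak(spec_18, peak[0] + O18_O16_DELTA, tol_ppm)
            if same is None and shifted is not None:
                o_free_shifted.append(hyp)
    verdict = "consistent" if pairs and not o_free_shifted else "inconsistent"
    return LabelShiftResult(pairs=pairs, verdict=verdict, o_free_shifted=o_free_shifted)


def annotation_to_csv(annotated: AnnotatedSpectrum, path) -> None:
    """Export annotation as CSV (m/z, intensity, formula, ppm)."""
    import pandas as pd

    rows = [
        {"mz": p[0], "intensity": p[1], "formula": str(h.formula), "ppm": round(ppm, 2)}
        for p, h, ppm in annotated.matches
    ] + [
        {"mz": p[0], "intensity": p[1], "formula": "", "ppm": float("nan")}
        for p in annotated.unmatched
    ]
    pd.DataFrame(rows, columns=["mz", "intensity", "formula", "ppm"]).sort_values(
        "mz"
    ).to_csv(path, index=False)
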