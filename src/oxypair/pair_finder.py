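"""Paired-run metabolite confirmation.

The screen walks every enumerated biotransformation candidate and asks
the labeling question directly of the data: a candidate with Z inserted
oxygens must show a feature at its theoretical m/z in the air run and a
co-eluting feature at m/z + Z x 2.00425 in the 18O2 run, while the air
run stays clean at the shifted m/z (natural M+2 signal within a +/-5 ppm
window is ~0.4% of the parent feature and is ignored via a relative
threshold).  Candidates with Z=0 (pure dealkylation) carry no inserted
oxygen and can never be label-confirmed; when present in both runs they
are reported ``label-unconfirmable``.  Control runs veto features that
the incubation did not produce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from .biotransform import BiotransformCandidate, default_rules, enumerate_candidates
from .constants import O18_O16_DELTA
from .formula import MolecularFormula, POSITIVE, NEGATIVE, ppm_diff
from .isotope_model import (
    DEFAULT_REAGENT_ENRICHMENT,
    LabelingEstimate,
    estimate_labeling_degree,
)
from .spectra_io import Feature, Run, extract_features

logger = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "PairHit", "screen", "control_filter", "score_pair", "report"]

CONFIRMED = "confirmed"
LABEL_UNCONFIRMABLE = "label-unconfirmable"
CANDIDATE_ONLY = "candidate-only"


@dataclass
class ScreenConfig:
    """Tolerances and gates for the paired-run screen."""

    mz_tol_ppm: float = 5.0
    ms2_tol_ppm: float = 10.0
    rt_tol_min: float = 0.1
    min_sn: float = 3.0
    control_ratio_min: float = 5.0
    q_min: float = 0.1
    max_steps: int = 3
    polarity: str = "positive"
    reagent_enrichment: float = DEFAULT_REAGENT_ENRICHMENT
    #: a shifted-channel feature in the *air* run blocks confirmation only
    #: if its area exceeds this fraction of the unlabeled air feature
    #: (natural M+2 in a 5 ppm window is ~0.004, well below).
    air_shift_max_frac: float = 0.05
    n_boot: int = 200

    def __post_init__(self):
        if min(self.mz_tol_ppm, self.ms2_tol_ppm, self.rt_tol_min, self.min_sn,
               self.control_ratio_min) <= 0:
            raise ValueError("all tolerances must be positive")
        if not 0.0 <= self.q_min < 1.0:
            raise ValueError("q_min must lie in [0, 1)")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def ion(self):
        return POSITIVE if self.polarity == "positive" else NEGATIVE

    @classmethod
    def from_file(cls, path) -> "ScreenConfig":
        """Load from a flat ``key = value`` text file; unknown keys are
        rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "polarity":
                kwargs[key] = val
            elif key in ("max_steps", "n_boot"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


@dataclass
class PairHit:
    """One candidate/feature association with its labeling evidence."""

    candidate: BiotransformCandidate
    feature_16: Feature | None
    feature_18: Feature | None
    feature_16_in_18O2run: Feature | None = None
    observed_delta: float = float("nan")
    rt_offset: float = float("nan")
    labeling: LabelingEstimate | None = None
    score: float = 0.0
    status: str = CANDIDATE_ONLY

    @property
    def rt_apex(self) -> float:
        f = self.feature_16 or self.feature_18
        return f.rt_apex if f else float("nan")


def control_filter(
    feature: Feature,
    target_mz: float,
    controls: Sequence[Run],
    cfg: ScreenConfig,
) -> tuple[bool, float]:
    """Check a feature against control runs.

    Fails when any control shows a feature at the same m/z and RT with
    area >= feature.area / control_ratio_min.  With no controls the
    filter passes (with a logged caveat).
    """
    if not controls:
        logger.warning(
            "no control runs supplied; control filtering is a no-op"
        )
        return True, 0.0
    worst = 0.0
    for ctrl in controls:
        for cf in extract_features(ctrl, target_mz, cfg.mz_tol_ppm, cfg.min_sn):
            if abs(cf.rt_apex - feature.rt_apex) <= cfg.rt_tol_min:
                worst = max(worst, cf.area)
    return worst < feature.area / cfg.control_ratio_min, worst


def score_pair(hit: PairHit, cfg: ScreenConfig) -> float:
    """Deterministic 0-1 plausibility score for a two-channel hit.

    Product of a mass-accuracy term exp(-(ppm/tol)^2) on the labeled
    feature, a co-elution term exp(-(rt_offset/rt_tol)^2), and a
    labeling-plausibility term that is 1 inside [q_min, enrichment] and
    decays smoothly outside.
    """
    if hit.feature_16 is None or hit.feature_18 is None:
        raise ValueError("score_pair requires both channels")
    cand = hit.candidate
    theo_shifted = cand.theoretical_mz + cand.z * O18_O16_DELTA
    ppm = ppm_diff(hit.feature_18.mz, theo_shifted)
    mass_term = math.exp(-((ppm / cfg.mz_tol_ppm) ** 2))
    rt_term = math.exp(-((hit.rt_offset / cfg.rt_tol_min) ** 2))
    label_term = 1.0
    if hit.labeling is not None:
        q = hit.labeling.q_hat
        if q < cfg.q_min:
            label_term = math.exp(-(((cfg.q_min - q) / max(cfg.q_min, 1e-6)) ** 2))
        elif q > cfg.reagent_enrichment:
            span = max(1.0 - cfg.reagent_enrichment, 1e-6)
            label_term = math.exp(-(((q - cfg.reagent_enrichment) / span) ** 2))
    return mass_term * rt_term * label_term


def _nearest(features: Sequence[Feature], rt: float, tol: float) -> Feature | None:
    best, best_d = None, tol
    for f in features:
        d = abs(f.rt_apex - rt)
        if d <= best_d:
            best, best_d = f, d
    return best


def screen(
    run_air: Run,
    run_18o2: Run,
    controls: Sequence[Run],
    parent: MolecularFormula,
    cfg: ScreenConfig | None = None,
    rules=None,
    candidates: Sequence[BiotransformCandidate] | None = None,
) -> list[PairHit]:
    """Confirm biotransformation candidates across the paired runs."""
    cfg = cfg or ScreenConfig()
    if run_air.polarity != run_18o2.polarity:
        raise ValueError(
            f"polarity mismatch: air={run_air.polarity}, 18O2={run_18o2.polarity}"
        )
    if not run_air.scans or not run_18o2.scans:
        raise ValueError("both runs must contain MS1 scans")
    if candidates is None:
        candidates = enumerate_candidates(
            parent, rules if rules is not None else default_rules(),
            max_steps=cfg.max_steps, ion=cfg.ion,
        )
    if not candidates:
        raise ValueError("empty candidate set")

    hits: list[PairHit] = []
    for cand in candidates:
        if cand.formula == parent:
            continue
        mz0 = cand.theoretical_mz
        feats_air = extract_features(run_air, mz0, cfg.mz_tol_ppm, cfg.min_sn)
        feats_18_unlab = extract_features(run_18o2, mz0, cfg.mz_tol_ppm, cfg.min_sn)

        if cand.z == 0:
            # no inserted oxygen: the label cannot speak; report presence
            for f16 in feats_air:
                if not control_filter(f16, mz0, controls, cfg)[0]:
                    continue
                mate = _nearest(feats_18_unlab, f16.rt_apex, cfg.rt_tol_min)
                hits.append(
                    PairHit(
                        candidate=cand,
                        feature_16=f16,
                        feature_18=None,
                        feature_16_in_18O2run=mate,
                        rt_offset=(mate.rt_apex - f16.rt_apex) if mate else float("nan"),
                        status=LABEL_UNCONFIRMABLE if mate else CANDIDATE_ONLY,
                    )
                )
            continue

        mz_shift = mz0 + cand.z * O18_O16_DELTA
        feats_18_shift = extract_features(run_18o2, mz_shift, cfg.mz_tol_ppm, cfg.min_sn)
        feats_air_shift = extract_features(run_air, mz_shift, cfg.mz_tol_ppm, cfg.min_sn)

        matched_18: set[int] = set()
        for f16 in feats_air:
            if not control_filter(f16, mz0, controls, cfg)[0]:
                continue
            f18 = _nearest(feats_18_shift, f16.rt_apex, cfg.rt_tol_min)
            if f18 is None:
                hits.append(
                    PairHit(candidate=cand, feature_16=f16, feature_18=None,
                            status=CANDIDATE_ONLY)
                )
                continue
            matched_18.add(id(f18))
            f18_unlab = _nearest(feats_18_unlab, f16.rt_apex, cfg.rt_tol_min)

            # labeling degree from the 18O2-run channel areas
            areas = []
            for k in range(cand.z + 1):
                if k == 0:
                    fk = f18_unlab
                elif k == cand.z:
                    fk = f18
                else:
                    fk = _nearest(
                        extract_features(
                            run_18o2, mz0 + k * O18_O16_DELTA,
                            cfg.mz_tol_ppm, cfg.min_sn,
                        ),
                        f16.rt_apex, cfg.rt_tol_min,
                    )
                areas.append(fk.area if fk else 0.0)
            try:
                labeling = estimate_labeling_degree(
                    areas, cand.formula, cand.z,
                    reagent_enrichment=cfg.reagent_enrichment,
                    tol_ppm=cfg.mz_tol_ppm, n_boot=cfg.n_boot,
                )
            except ValueError:
                labeling = None

            air_shift = _nearest(feats_air_shift, f16.rt_apex, cfg.rt_tol_min)
            air_clean = (
                air_shift is None
                or air_shift.area < cfg.air_shift_max_frac * f16.area
            )
            confirmed = (
                air_clean
                and labeling is not None
                and labeling.q_hat >= cfg.q_min
            )
            hit = PairHit(
                candidate=cand,
                feature_16=f16,
                feature_18=f18,
                feature_16_in_18O2run=f18_unlab,
                observed_delta=f18.mz - f16.mz,
                rt_offset=f18.rt_apex - f16.rt_apex,
                labeling=labeling,
                status=CONFIRMED if confirmed else CANDIDATE_ONLY,
            )
            hit.score = score_pair(hit, cfg)
            hits.append(hit)

        for f18 in feats_18_shift:  # shifted channel without an air mate
            if id(f18) not in matched_18:
                hits.append(
                    PairHit(candidate=cand, feature_16=None, feature_18=f18,
                            status=CANDIDATE_ONLY)
                )

    hits.sort(key=lambda h: (h.candidate.class_label, h.rt_apex))
    return hits


def report(hits: Sequence[PairHit]) -> tuple[pd.DataFrame, dict]:
    """Tabulate hits, one row per (class, theoretical m/z).

    Isomers (same class, different RT) are kept as separate hits and
    their retention times are semicolon-joined in the row, following the
    reporting convention for same-class positional isomers.
    """
    columns = [
        "class", "formula", "Z", "theoretical_mz",
        "rt_list", "n_isomers", "status", "mean_q", "mean_score",
    ]
    groups: dict[tuple[str, float], list[PairHit]] = {}
    for h in hits:
        groups.setdefault(
            (h.candidate.class_label, round(h.candidate.theoretical_mz, 4)), []
        ).append(h)

    rows = []
    detail: dict[str, list[dict]] = {}
    for (label, mz), ghits in sorted(groups.items()):
        ghits = sorted(ghits, key=lambda h: h.rt_apex)
        qs = [h.labeling.q_hat for h in ghits if h.labeling is not None]
        statuses = sorted({h.status for h in ghits})
        rows.append(
            {
                "class": label,
                "formula": str(ghits[0].candidate.formula),
                "Z": ghits[0].candidate.z,
                "theoretical_mz": mz,
                "rt_list": "; ".join(
                    f"{h.rt_apex:.2f}" for h in ghits if not math.isnan(h.rt_apex)
                ),
                "n_isomers": len(ghits),
                "status": "|".join(statuses),
                "mean_q": sum(qs) / len(qs) if qs else float("nan"),
                "mean_score": sum(h.score for h in ghits) / len(ghits),
            }
        )
        detail[f"{label}@{mz}"] = [
            {
                "rt": None if math.isnan(h.rt_apex) else round(h.rt_apex, 3),
                "status": h.status,
                "q_hat": None if h.labeling is None else round(h.labeling.q_hat, 4),
                "q_ci": None if h.labeling is None
                else [round(h.labeling.ci_low, 4), round(h.labeling.ci_high, 4)],
                "observed_delta": None if math.isnan(h.observed_delta)
                else round(h.observed_delta, 5),
                "score": round(h.score, 4),
            }
            for h in ghits
        ]
    df = pd.DataFrame(rows, columns=columns)
    return df, detail
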