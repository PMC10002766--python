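"""Phase-I biotransformation candidate enumeration.

Candidate metabolites of a parent drug are generated by composing
element-count reaction rules (hydroxylation, oxo-formation,
N-dealkylation, ...).  Each candidate carries Z, the number of
enzymatically inserted oxygens — the multiplier in the paired-run mass
shift ΔM = Z x 2.0043 Da — plus a class label derived from the multiset
of applied rules (H, DH, O, HO, DA, DAH, DAO, DADH for the default rule
set on a monoamide anesthetic like bupivacaine).

The default configuration encodes the canonical phase-I pathway map for
this drug family: up to two hydroxylations, at most one oxo-formation,
at most one N-debutylation, and oxo-carrying species with at most one
co-modification (ketone/aldehyde metabolites are observed only as
primary or secondary products).  That reproduces exactly the eight
classes of the established bupivacaine metabolic map, while the rule
schema itself is fully generic (hydrolysis-type rules with
``z_increment=0`` are supported).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formula import IonSpec, MolecularFormula, POSITIVE, ion_mz
from .constants import monoisotopic

__all__ = [
    "ReactionRule",
    "BiotransformCandidate",
    "default_rules",
    "enumerate_candidates",
    "classify_mass_delta",
    "candidates_to_csv",
    "rules_to_file",
    "rules_from_file",
]


@dataclass(frozen=True)
class ReactionRule:
    """One phase-I biotransformation step as a signed element-count delta.

    Attributes
    ----------
    name : str
        Rule identifier (e.g. ``"hydroxylation"``).
    delta : mapping
        Signed element-count change, e.g. ``{"O": +1, "H": -2}``.
    z_increment : int
        Oxygens inserted from molecular O2 by one application (the
        contribution to Z).  Hydrolysis-type rules insert water oxygen
        and carry ``z_increment=0``.
    max_applications : int
        Per-candidate cap on how often this rule may appear.
    labels : tuple of str
        ``labels[k-1]`` is the class-label fragment for k applications
        (e.g. ``("H", "DH")``).
    label_priority : int
        Ordering of label fragments within a composite class label
        (lower = earlier).
    combine_limit : int or None
        If set, a candidate containing this rule may carry at most this
        many total rule applications.
    """

    name: str
    delta: Mapping[str, int]
    z_increment: int = 0
    max_applications: int = 1
    labels: tuple[str, ...] = ()
    label_priority: int = 10
    combine_limit: int | None = None

    def __post_init__(self):
        if self.z_increment < 0:
            raise ValueError("z_increment must be >= 0")
        if self.z_increment > max(0, self.delta.get("O", 0)):
            raise ValueError(
                f"rule {self.name!r}: z_increment exceeds oxygens added by delta"
            )
        if self.max_applications < 1:
            raise ValueError("max_applications must be >= 1")
        object.__setattr__(self, "delta", dict(self.delta))

    @property
    def delta_mass(self) -> float:
        return sum(n * monoisotopic(el) for el, n in self.delta.items())

    def label_for(self, k: int) -> str:
        if 0 < k <= len(self.labels):
            return self.labels[k - 1]
        base = self.labels[0] if self.labels else self.name[:2].upper()
        return f"{k}{base}" if k > 1 else base


@dataclass(frozen=True)
class BiotransformCandidate:
    """A metabolite hypothesis: formula delta + class label + Z + ion m/z."""

    class_label: str
    formula: MolecularFormula
    z: int
    theoretical_mz: float
    rule_trace: tuple[str, ...]
    ion: IonSpec = field(default=POSITIVE, compare=False)

    @property
    def n_steps(self) -> int:
        return len(self.rule_trace)


def default_rules() -> list[ReactionRule]:
    """The three phase-I primitives covering the eight default classes."""
    return [
        ReactionRule(
            name="hydroxylation",
            delta={"O": +1},
            z_increment=1,
            max_applications=2,
            labels=("H", "DH"),
            label_priority=1,
        ),
        ReactionRule(
            name="oxo-formation",
            delta={"O": +1, "H": -2},
            z_increment=1,
            max_applications=1,
            labels=("O",),
            label_priority=2,
            combine_limit=2,
        ),
        ReactionRule(
            name="N-debutylation",
            delta={"C": -4, "H": -8},
            z_increment=0,
            max_applications=1,
            labels=("DA",),
            label_priority=0,
        ),
    ]


def _class_label(rules: Sequence[ReactionRule], multiplicity: Sequence[int]) -> str:
    parts = [
        (r.label_priority, r.label_for(k))
        for r, k in zip(rules, multiplicity)
        if k > 0
    ]
    parts.sort()
    return "".join(p for _, p in parts)


def _iter_multisets(
    rules: Sequence[ReactionRule], max_steps: int
) -> Iterable[tuple[int, ...]]:
    ranges = [range(r.max_applications + 1) for r in rules]
    for combo in itertools.product(*ranges):
        total = sum(combo)
        if total == 0 or total > max_steps:
            continue
        ok = True
        for r, k in zip(rules, combo):
            if k > 0 and r.combine_limit is not None and total > r.combine_limit:
                ok = False
                break
        if ok:
            yield combo


def enumerate_candidates(
    parent: MolecularFormula,
    rules: Sequence[ReactionRule] | None = None,
    max_steps: int = 3,
    ion: IonSpec = POSITIVE,
) -> list[BiotransformCandidate]:
    """Enumerate candidate metabolites as compositions of reaction rules.

    Rule applications commute (they are element-count deltas), so
    candidates are enumerated over multisets of rules — the result is
    independent of rule order.  Compositions that would drive an element
    count negative are skipped.  Candidates are deduplicated by
    (formula, class label) and sorted by step count, then class label.
    """
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("empty rule list")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")

    seen: dict[tuple[MolecularFormula, str], BiotransformCandidate] = {}
    for combo in _iter_multisets(rules, max_steps):
        formula = parent
        try:
            for r, k in zip(rules, combo):
                for _ in range(k):
                    formula = formula.apply_delta(r.delta)
        except ValueError:
            continue  # rule combination not applicable to this parent
        z = sum(r.z_increment * k for r, k in zip(rules, combo))
        label = _class_label(rules, combo)
        trace = tuple(
            name
            for r, k in sorted(
                zip(rules, combo), key=lambda rk: (rk[0].label_priority, rk[0].name)
            )
            for name in [r.name] * k
        )
        key = (formula, label)
        if key not in seen:
            seen[key] = BiotransformCandidate(
                class_label=label,
                formula=formula,
                z=z,
                theoretical_mz=ion_mz(formula, ion),
                rule_trace=trace,
                ion=ion,
            )
    return sorted(seen.values(), key=lambda c: (c.n_steps, c.class_label))


def classify_mass_delta(
    delta_mass: float,
    rules: Sequence[ReactionRule] | None = None,
    tol_ppm: float = 5.0,
    parent_mass: float = 300.0,
    max_steps: int = 3,
) -> list[str]:
    """Inverse lookup: class labels whose neutral-mass delta matches.

    The ppm tolerance is evaluated at the metabolite mass
    (``parent_mass + delta``).  Matches are sorted by absolute ppm
    error, ties broken by fewer rule steps, then alphabetically.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if rules is None:
        rules = default_rules()
    matches: list[tuple[float, int, str]] = []
    for combo in _iter_multisets(rules, max_steps):
        d = sum(r.delta_mass * k for r, k in zip(rules, combo))
        ref = parent_mass + d
        if ref <= 0:
            continue
        ppm = 1e6 * (delta_mass - d) / ref
        if abs(ppm) <= tol_ppm:
            matches.append((abs(ppm), sum(combo), _class_label(rules, combo)))
    matches.sort()
    out: list[str] = []
    for _, _, label in matches:
        if label not in out:
            out.append(label)
    return out


def rules_to_file(rules: Iterable[ReactionRule], path) -> None:
    """Serialize a rule set as plain text.

    One rule per line:
    ``name | delta | z_increment | max_applications | labels | priority | combine_limit``
    with the delta written as comma-separated signed element counts
    (``O:+1,H:-2``).
    """
    with open(path, "w") as fh:
        fh.write("# name | delta | z | max_applications | labels | priority | combine_limit\n")
        for r in rules:
            delta = ",".join(f"{el}:{n:+d}" for el, n in sorted(r.delta.items()))
            labels = ";".join(r.labels)
            limit = "" if r.combine_limit is None else str(r.combine_limit)
            fh.write(
                f"{r.name} | {delta} | {r.z_increment} | {r.max_applications}"
                f" | {labels} | {r.label_priority} | {limit}\n"
            )


def rules_from_file(path) -> list[ReactionRule]:
    """Parse a rule set written by :func:`rules_to_file`."""
    rules: list[ReactionRule] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split("|")]
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 |-separated fields")
            name, delta_s, z_s, maxapp_s, labels_s, prio_s, limit_s = parts
            delta = {}
            for item in delta_s.split(","):
                el, n = item.split(":")
                delta[el.strip()] = int(n)
            rules.append(
                ReactionRule(
                    name=name,
                    delta=delta,
                    z_increment=int(z_s),
                    max_applications=int(maxapp_s),
                    labels=tuple(s for s in labels_s.split(";") if s),
                    label_priority=int(prio_s),
                    combine_limit=int(limit_s) if limit_s else None,
                )
            )
    if not rules:
        raise ValueError(f"{path}: empty rule file")
    return rules


def candidates_to_csv(candidates: Iterable[BiotransformCandidate], path) -> None:
    """Export a candidate list as CSV (class, formula, Z, theoretical m/z)."""
    rows = [
        {
            "class": c.class_label,
            "formula": str(c.formula),
            "Z": c.z,
            "theoretical_mz": round(c.theoretical_mz, 4),
            "rule_trace": ";".join(c.rule_trace),
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows, columns=["class", "formula", "Z", "theoretical_mz", "rule_trace"]
    ).to_csv(path, index=False)
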