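"""Modularity-hypothesis ledger and correlation-model parameterization schemes.

A :class:`ModulePartition` assigns every landmark to exactly one module.
The built-in ledger encodes ten competing hypotheses about flower
modularity (H1-H6 plus the starred variants H2*, H4*, H5*, H6* that move
the two column-foot landmarks into the labellum module), grouped into
"efficiency", "attraction" and "development" categories.

For likelihood model selection each partition is expanded into
parameterization schemes that share or separate the correlation
coefficients (rho) within and between modules:

=======  ==========================  =================================
scheme   within-module rhos          between-module rhos
=======  ==========================  =================================
a        one shared                  one shared
b        separate per module         one shared
c        one shared                  separate per module pair
d        separate per module         separate per module pair
=======  ==========================  =================================

Two-module partitions have a single between-module pair, so schemes c and
d collapse onto a and b and only a, b are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

CATEGORIES = ("efficiency", "attraction", "development", "null")

# organs recognized by the built-in ledger
ORGANS = ("sepal", "petal", "labellum", "column", "column_foot")


@dataclass
class ModulePartition:
    """One modularity hypothesis: a total map landmark -> module."""

    name: str
    category: str
    modules: dict[str, list[str]]  # ordered module label -> landmark labels

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        seen: dict[str, str] = {}
        for mod, lms in self.modules.items():
            if not lms:
                raise ValueError(f"{self.name}: module {mod!r} is empty")
            for lm in lms:
                if lm in seen:
                    raise ValueError(
                        f"{self.name}: landmark {lm!r} assigned to both {seen[lm]!r} and {mod!r}"
                    )
                seen[lm] = mod

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def module_labels(self) -> list[str]:
        return list(self.modules)

    def validate(self, landmark_labels: Sequence[str]) -> None:
        assigned = {lm for lms in self.modules.values() for lm in lms}
        labels = set(landmark_labels)
        missing = sorted(labels - assigned)
        if missing:
            raise ValueError(f"{self.name}: landmarks unassigned to any module: {missing}")
        extra = sorted(assigned - labels)
        if extra:
            raise ValueError(f"{self.name}: unknown landmarks in modules: {extra}")

    def assignment(self, landmark_labels: Sequence[str]) -> list[str]:
        """Module label per landmark, in dataset landmark order."""
        self.validate(landmark_labels)
        lut = {lm: mod for mod, lms in self.modules.items() for lm in lms}
        return [lut[lm] for lm in landmark_labels]

    def module_indices(self, landmark_labels: Sequence[str]) -> dict[str, list[int]]:
        """Landmark indices (dataset order) per module."""
        self.validate(landmark_labels)
        pos = {lm: i for i, lm in enumerate(landmark_labels)}
        return {mod: sorted(pos[lm] for lm in lms) for mod, lms in self.modules.items()}


@dataclass
class ParameterizationScheme:
    """One correlation-model parameterization of a partition.

    ``rho_sets`` partitions all unordered landmark pairs into groups; each
    group carries one free correlation parameter.
    """

    partition: Optional[ModulePartition]
    scheme: str  # "a", "b", "c", "d", or "null"
    rho_sets: dict[str, list[tuple[str, str]]]

    @property
    def scheme_id(self) -> str:
        if self.partition is None:
            return "null"
        return f"{self.partition.name}-{self.scheme}"

    @property
    def k(self) -> int:
        """Free model parameters: one rho per set plus one for the residual scale."""
        return len(self.rho_sets) + 1

    def check_covers_pairs(self, landmark_labels: Sequence[str]) -> None:
        all_pairs = {frozenset(p) for p in combinations(landmark_labels, 2)}
        got: list[frozenset] = []
        for pairs in self.rho_sets.values():
            got.extend(frozenset(p) for p in pairs)
        if len(got) != len(set(got)):
            raise ValueError(f"{self.scheme_id}: rho sets overlap")
        if set(got) != all_pairs:
            raise ValueError(f"{self.scheme_id}: rho sets do not cover all landmark pairs")


def _schemes_for_partition(part: ModulePartition, landmark_labels: Sequence[str]) -> list[ParameterizationScheme]:
    assign = part.assignment(landmark_labels)
    mods = part.module_labels
    within: dict[str, list[tuple[str, str]]] = {m: [] for m in mods}
    between: dict[tuple[str, str], list[tuple[str, str]]] = {
        (a, b): [] for a, b in combinations(mods, 2)
    }
    for (i, li), (j, lj) in combinations(enumerate(landmark_labels), 2):
        mi, mj = assign[i], assign[j]
        if mi == mj:
            within[mi].append((li, lj))
        else:
            key = (mi, mj) if (mi, mj) in between else (mj, mi)
            between[key].append((li, lj))

    all_within = [p for ps in within.values() for p in ps]
    all_between = [p for ps in between.values() for p in ps]

    def named_between() -> dict[str, list[tuple[str, str]]]:
        return {f"between:{a}|{b}": ps for (a, b), ps in between.items()}

    def named_within() -> dict[str, list[tuple[str, str]]]:
        return {f"within:{m}": ps for m, ps in within.items() if ps}

    out = [
        ParameterizationScheme(part, "a", {"within": all_within, "between": all_between}),
        ParameterizationScheme(part, "b", {**named_within(), "between": all_between}),
    ]
    if part.n_modules >= 3:
        out.append(ParameterizationScheme(part, "c", {"within": all_within, **named_between()}))
        out.append(ParameterizationScheme(part, "d", {**named_within(), **named_between()}))
    return out


def enumerate_schemes(ledger: Sequence[ModulePartition], landmark_labels: Sequence[str],
                      include_null: bool = True) -> list[ParameterizationScheme]:
    """Expand a validated hypothesis ledger into parameterization schemes.

    Two schemes (a, b) per 2-module partition, four (a-d) per partition
    with three or more modules, plus — if ``include_null`` — a null scheme
    with a single rho set over every landmark pair.
    """
    out: list[ParameterizationScheme] = []
    if include_null:
        all_pairs = list(combinations(landmark_labels, 2))
        out.append(ParameterizationScheme(None, "null", {"all": all_pairs}))
    for part in ledger:
        part.validate(landmark_labels)
        out.extend(_schemes_for_partition(part, landmark_labels))
    return out


def builtin_ledger(organ_of: dict[str, str],
                   foot_to_labellum: Optional[Sequence[str]] = None) -> list[ModulePartition]:
    """The ten-hypothesis flower-modularity ledger from per-landmark organ annotations.

    ``organ_of`` maps every landmark label to one of ``sepal``, ``petal``,
    ``labellum``, ``column``, ``column_foot``.  The starred variants (H2*,
    H4*, H5*, H6*) reassign the column-foot landmarks (default: all
    landmarks annotated ``column_foot``; override with ``foot_to_labellum``)
    from the column module to the labellum module.

    Hypotheses:

    * H1 (efficiency): sepals + lateral petals vs. labellum + column.
    * H2 (efficiency): sepals + petals vs. labellum vs. column.
    * H3 (efficiency): sepals vs. petals + labellum + column.
    * H4 (attraction): sepals + petals + labellum vs. column.
    * H5 (development): sepals vs. petals + labellum vs. column (whorls).
    * H6 (development): sepals vs. petals vs. labellum vs. column.
    """
    missing = [lm for lm, org in organ_of.items() if org not in ORGANS]
    if missing:
        raise ValueError(f"unknown organ annotation for landmarks: {sorted(missing)}")
    by_organ: dict[str, list[str]] = {o: [] for o in ORGANS}
    for lm, org in organ_of.items():
        by_organ[org].append(lm)
    for org in ("sepal", "petal", "labellum", "column"):
        if not by_organ[org]:
            raise ValueError(f"no landmarks annotated {org!r}")
    foot = list(foot_to_labellum) if foot_to_labellum is not None else list(by_organ["column_foot"])
    bad = sorted(set(foot) - set(organ_of))
    if bad:
        raise ValueError(f"foot_to_labellum landmarks not in annotation: {bad}")

    sep, pet, lab = by_organ["sepal"], by_organ["petal"], by_organ["labellum"]
    col_full = by_organ["column"] + by_organ["column_foot"]  # column incl. foot
    col_part = [lm for lm in col_full if lm not in set(foot)]
    lab_star = lab + foot

    def P(name: str, category: str, modules: dict[str, list[str]]) -> ModulePartition:
        return ModulePartition(name=name, category=category, modules=modules)

    return [
        P("H1", "efficiency", {"M1": sep + pet, "M2": lab + col_full}),
        P("H2", "efficiency", {"M1": sep + pet, "M2": lab, "M3": col_full}),
        P("H2*", "efficiency", {"M1": sep + pet, "M2": lab_star, "M3": col_part}),
        P("H3", "efficiency", {"M1": sep, "M2": pet + lab + col_full}),
        P("H4", "attraction", {"M1": sep + pet + lab, "M2": col_full}),
        P("H4*", "attraction", {"M1": sep + pet + lab_star, "M2": col_part}),
        P("H5", "development", {"M1": sep, "M2": pet + lab, "M3": col_full}),
        P("H5*", "development", {"M1": sep, "M2": pet + lab_star, "M3": col_part}),
        P("H6", "development", {"M1": sep, "M2": pet, "M3": lab, "M4": col_full}),
        P("H6*", "development", {"M1": sep, "M2": pet, "M3": lab_star, "M4": col_part}),
    ]
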