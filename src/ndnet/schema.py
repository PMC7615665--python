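"""Variable schema and canonical pair sets for the 13-node symptom network.

The network always contains, in this fixed order: seven neurodevelopmental
trait scores, an emotional-dysregulation score, two social-environmental
stressor scores, and three depressive-symptom waves.  All matrices produced
anywhere in the package use this column order so that results are comparable
across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import yaml

TRAIT_BLOCK = "trait"
STRESSOR_BLOCK = "stressor_dysregulation"
DEPRESSION_BLOCK = "depression"

BLOCKS = (TRAIT_BLOCK, STRESSOR_BLOCK, DEPRESSION_BLOCK)

#: canonical node order shared by every matrix in the package
CANONICAL_ORDER = (
    "autistic",
    "hyperactive_impulsive",
    "inattentive",
    "general_cognitive",
    "speech_syntax",
    "pragmatic",
    "learning",
    "dysregulation",
    "peer_problems",
    "academic",
    "dep_childhood",
    "dep_adolescence",
    "dep_adulthood",
)

_BLOCK_OF = {
    **{n: TRAIT_BLOCK for n in CANONICAL_ORDER[:7]},
    **{n: STRESSOR_BLOCK for n in CANONICAL_ORDER[7:10]},
    **{n: DEPRESSION_BLOCK for n in CANONICAL_ORDER[10:]},
}

#: covariate column names carried alongside the scored variables
AGE_COLUMNS = ("age_trait", "age_stressor_dysregulation", "age_depression")
SEX_COLUMN = "sex"
FAMILY_COLUMN = "family_id"
COVARIATE_COLUMNS = AGE_COLUMNS + (SEX_COLUMN,)


@dataclass(frozen=True)
class Variable:
    """A single scored variable: bounded scale plus block membership."""

    name: str
    block: str
    score_min: float
    score_max: float
    timepoint: str
    #: direction/degree of marginal skew used by the synthetic generator;
    #: positive = right-skewed, 0 = near-symmetric, negative = left-skewed
    skew_target: float = 0.0

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}; expected one of {BLOCKS}")
        if not self.score_min < self.score_max:
            raise ValueError(
                f"{self.name}: score_min ({self.score_min}) must be < "
                f"score_max ({self.score_max})"
            )


@dataclass(frozen=True)
class VariableSchema:
    """Ordered collection of the 13 scored variables for one cohort."""

    cohort_id: str
    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        if len(self.variables) != 13:
            raise ValueError(f"schema must hold 13 variables, got {len(self.variables)}")
        counts = {b: 0 for b in BLOCKS}
        for v in self.variables:
            counts[v.block] += 1
        if counts != {TRAIT_BLOCK: 7, STRESSOR_BLOCK: 3, DEPRESSION_BLOCK: 3}:
            raise ValueError(f"block counts must be 7/3/3, got {counts}")
        names = tuple(v.name for v in self.variables)
        if names != CANONICAL_ORDER:
            raise ValueError("variables must follow the canonical order")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.block == TRAIT_BLOCK)

    @property
    def stressor_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.block == STRESSOR_BLOCK)

    @property
    def depression_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.block == DEPRESSION_BLOCK)

    def block_of(self, name: str) -> str:
        return _BLOCK_OF[name]

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def age_column(self, name: str) -> str:
        """Covariate column holding age at collection for this variable's block."""
        return f"age_{self.block_of(name)}" if self.block_of(name) != TRAIT_BLOCK else "age_trait"

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {v.name: (v.score_min, v.score_max) for v in self.variables}

    def to_yaml(self, path) -> None:
        payload = {
            "cohort_id": self.cohort_id,
            "variables": [
                {
                    "name": v.name,
                    "block": v.block,
                    "score_min": v.score_min,
                    "score_max": v.score_max,
                    "timepoint": v.timepoint,
                    "skew_target": v.skew_target,
                }
                for v in self.variables
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VariableSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            cohort_id=payload["cohort_id"],
            variables=tuple(Variable(**v) for v in payload["variables"]),
        )


Pair = tuple[str, str]


@dataclass(frozen=True)
class PairSets:
    """The canonical unordered node-pair groupings of the 13-node network."""

    trait_trait: tuple[Pair, ...]
    trait_stressor: tuple[Pair, ...]
    trait_depression: tuple[Pair, ...]
    stressor_depression: tuple[Pair, ...]
    stressor_stressor: tuple[Pair, ...] = field(default=())
    depression_depression: tuple[Pair, ...] = field(default=())
    all_pairs: tuple[Pair, ...] = field(default=())

    def __post_init__(self) -> None:
        expected = {
            "trait_trait": 21,
            "trait_stressor": 21,
            "trait_depression": 21,
            "stressor_depression": 9,
            "stressor_stressor": 3,
            "depression_depression": 3,
            "all_pairs": 78,
        }
        for attr, n in expected.items():
            got = len(getattr(self, attr))
            if got != n:
                raise ValueError(f"{attr}: expected {n} pairs, got {got}")
        union = set(
            self.trait_trait
            + self.trait_stressor
            + self.trait_depression
            + self.stressor_depression
            + self.stressor_stressor
            + self.depression_depression
        )
        if union != set(self.all_pairs):
            raise ValueError("pair-set union does not cover all 78 pairs")

    def by_name(self, name: str) -> tuple[Pair, ...]:
        return getattr(self, name)


def pair_sets(schema: VariableSchema | None = None) -> PairSets:
    """Build the canonical 21/21/21/9 (+3/+3 within-block) pair sets."""
    names = schema.names if schema is not None else CANONICAL_ORDER
    traits = names[:7]
    stressors = names[7:10]
    depression = names[10:]
    cross = lambda a, b: tuple((x, y) for x in a for y in b)  # noqa: E731
    within = lambda a: tuple(combinations(a, 2))  # noqa: E731
    return PairSets(
        trait_trait=within(traits),
        trait_stressor=cross(traits, stressors),
        trait_depression=cross(traits, depression),
        stressor_depression=cross(stressors, depression),
        stressor_stressor=within(stressors),
        depression_depression=within(depression),
        all_pairs=within(names),
    )


def _teds_like() -> VariableSchema:
    v = Variable
    return VariableSchema(
        cohort_id="cohort_A",
        variables=(
            v("autistic", TRAIT_BLOCK, 0, 31, "8y", 2.0),
            v("hyperactive_impulsive", TRAIT_BLOCK, 0, 27, "8y", 1.5),
            v("inattentive", TRAIT_BLOCK, 0, 27, "8y", 1.5),
            v("general_cognitive", TRAIT_BLOCK, -3, 3, "9y", 0.0),
            v("speech_syntax", TRAIT_BLOCK, 0, 16, "9y", -1.0),
            v("pragmatic", TRAIT_BLOCK, 0, 8, "9y", -1.0),
            v("learning", TRAIT_BLOCK, 0, 82, "10y", 0.0),
            v("dysregulation", STRESSOR_BLOCK, 0, 10, "9y", 1.5),
            v("peer_problems", STRESSOR_BLOCK, 0, 10, "9y", 2.0),
            v("academic", STRESSOR_BLOCK, 9, 45, "10y", 0.0),
            v("dep_childhood", DEPRESSION_BLOCK, 0, 26, "12y", 2.0),
            v("dep_adolescence", DEPRESSION_BLOCK, 0, 26, "16y", 1.5),
            v("dep_adulthood", DEPRESSION_BLOCK, 0, 16, "21y", 1.5),
        ),
    )


def _alspac_like() -> VariableSchema:
    v = Variable
    return VariableSchema(
        cohort_id="cohort_B",
        variables=(
            v("autistic", TRAIT_BLOCK, 0, 24, "7.6y", 2.0),
            v("hyperactive_impulsive", TRAIT_BLOCK, 0, 18, "7.6y", 1.5),
            v("inattentive", TRAIT_BLOCK, 0, 18, "7.6y", 1.5),
            v("general_cognitive", TRAIT_BLOCK, 45, 151, "8.5y", 0.0),
            v("speech_syntax", TRAIT_BLOCK, 45, 70, "9.6y", -1.0),
            v("pragmatic", TRAIT_BLOCK, 96, 162, "9.6y", -1.0),
            v("learning", TRAIT_BLOCK, 0, 50, "7.5y", 0.0),
            v("dysregulation", STRESSOR_BLOCK, 0, 10, "9.6y", 1.5),
            v("peer_problems", STRESSOR_BLOCK, 0, 10, "9.6y", 2.0),
            v("academic", STRESSOR_BLOCK, 0, 99, "11y", 0.0),
            v("dep_childhood", DEPRESSION_BLOCK, 0, 26, "12y", 2.0),
            v("dep_adolescence", DEPRESSION_BLOCK, 0, 26, "16y", 1.5),
            v("dep_adulthood", DEPRESSION_BLOCK, 0, 26, "21y", 1.5),
        ),
    )


#: default per-cohort sample sizes used by the named presets
PRESET_N = {"cohort_A": 4407, "cohort_B": 10351}


def cohort_schema(cohort: str) -> VariableSchema:
    """Return the named cohort preset schema (``cohort_A`` or ``cohort_B``)."""
    if cohort == "cohort_A":
        return _teds_like()
    if cohort == "cohort_B":
        return _alspac_like()
    raise ValueError(f"unknown cohort preset {cohort!r}; expected cohort_A or cohort_B")
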