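"""Neuropsychological battery specification and score orientation.

A battery is a list of tests, each belonging to one cognitive domain
(memory, executive, global, language) with a scoring direction.  Tests
scored so that *lower* is better (timed tests, error counts) are negated
during orientation so that, downstream, high values uniformly indicate
better performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DOMAINS = ("memory", "executive", "global", "language")
DIRECTIONS = ("higher_better", "lower_better")

#: Non-test columns a score table may carry alongside the battery columns.
COVARIATE_COLUMNS = ("participant_id", "age", "sex", "education")


@dataclass(frozen=True)
class TestSpec:
    """One test in the battery."""

    name: str
    domain: str
    direction: str = "higher_better"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for test {self.name!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r} for test {self.name!r}"
            )


@dataclass
class BatterySpec:
    """An ordered collection of :class:`TestSpec` with unique names."""

    tests: list[TestSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tests]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate test names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tests]

    def domain_tests(self, domain: str) -> list[str]:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        return [t.name for t in self.tests if t.domain == domain]

    @property
    def memory_tests(self) -> list[str]:
        return self.domain_tests("memory")

    @property
    def executive_tests(self) -> list[str]:
        return self.domain_tests("executive")

    def __len__(self) -> int:
        return len(self.tests)

    def __getitem__(self, name: str) -> TestSpec:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(name)


def default_battery() -> BatterySpec:
    """The default 15-test battery.

    Six memory scores, five executive, two global-cognition and two
    language scores.  Timed tests (TMT-A/B) and error-count tests
    (ADAS-Cog total, ANART) are marked ``lower_better``.
    """
    mk = TestSpec
    return BatterySpec(
        [
            mk("adas_cog", "memory", "lower_better"),
            mk("lm_i", "memory"),
            mk("lm_ii", "memory"),
            mk("ravlt_a15", "memory"),
            mk("ravlt_a6", "memory"),
            mk("ravlt_a7", "memory"),
            mk("category_fluency", "executive"),
            mk("clock_copy", "executive"),
            mk("clock_score", "executive"),
            mk("tmt_a", "executive", "lower_better"),
            mk("tmt_b", "executive", "lower_better"),
            mk("moca", "global"),
            mk("mmse", "global"),
            mk("anart", "language", "lower_better"),
            mk("bnt", "language"),
        ]
    )


def load_battery(path) -> BatterySpec:
    """Load a battery from a 3-column CSV (name, domain, direction)."""
    df = pd.read_csv(path)
    required = {"name", "domain", "direction"}
    if not required.issubset(df.columns):
        raise ValueError(f"battery file {path} must have columns {sorted(required)}")
    return BatterySpec(
        [TestSpec(r.name, r.domain, r.direction) for r in df.itertuples(index=False)]
    )


def save_battery(battery: BatterySpec, path) -> None:
    pd.DataFrame(
        [(t.name, t.domain, t.direction) for t in battery.tests],
        columns=["name", "domain", "direction"],
    ).to_csv(path, index=False)


def orient_scores(raw: pd.DataFrame, battery: BatterySpec) -> pd.DataFrame:
    """Re-orient raw scores so high values uniformly mean better performance.

    ``lower_better`` test columns are negated; ``higher_better`` columns and
    covariate columns pass through unchanged.  Missing cells are preserved.

    Raises
    ------
    KeyError
        If the table contains a scored column not declared in the battery.
    """
    known = set(battery.names) | set(COVARIATE_COLUMNS)
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        raise KeyError(f"unknown test column(s) not in battery: {unknown}")
    out = raw.copy()
    for t in battery.tests:
        if t.name in out.columns and t.direction == "lower_better":
            out[t.name] = -out[t.name]
    return out
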