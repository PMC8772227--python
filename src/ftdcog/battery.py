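"""Neuropsychological test battery definition.

The default battery is the 19-measure GENFI battery spanning six cognitive
domains: language, attention and mental processing speed, executive function,
visuoconstruction, memory, and social cognition.  Two flags drive special
handling downstream:

* ``timed`` — reaction-time measures (Trail Making Test parts A/B and the
  three D-KEFS Colour-Word Interference conditions) where a *higher* raw
  score means *worse* performance; their z-scores are sign-inverted so that
  lower z = worse holds for every test.
* ``language_dependent`` — measures whose stimuli differ between test
  languages (the four FCSRT scores and phonemic/letter fluency); their
  normative models carry per-language intercept offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

DOMAIN_LANGUAGE = "language"
DOMAIN_ATTENTION = "attention/processing speed"
DOMAIN_EXECUTIVE = "executive function"
DOMAIN_VISUOCONSTRUCTION = "visuoconstruction"
DOMAIN_MEMORY = "memory"
DOMAIN_SOCIAL = "social cognition"

DOMAINS = (
    DOMAIN_LANGUAGE,
    DOMAIN_ATTENTION,
    DOMAIN_EXECUTIVE,
    DOMAIN_VISUOCONSTRUCTION,
    DOMAIN_MEMORY,
    DOMAIN_SOCIAL,
)


@dataclass(frozen=True)
class TestDescriptor:
    """One scored neuropsychological measure."""

    id: str
    name: str
    domain: str
    timed: bool = False
    language_dependent: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown cognitive domain {self.domain!r} for test {self.id!r}")


class TestBattery:
    """Ordered collection of :class:`TestDescriptor` with unique ids."""

    def __init__(self, tests: list[TestDescriptor]):
        ids = [t.id for t in tests]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate test ids in battery: {dupes}")
        self._tests = tuple(tests)
        self._by_id = {t.id: t for t in tests}

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self._tests]

    @property
    def tests(self) -> tuple[TestDescriptor, ...]:
        return self._tests

    def __iter__(self) -> Iterator[TestDescriptor]:
        return iter(self._tests)

    def __len__(self) -> int:
        return len(self._tests)

    def __contains__(self, test_id: str) -> bool:
        return test_id in self._by_id

    def __getitem__(self, test_id: str) -> TestDescriptor:
        try:
            return self._by_id[test_id]
        except KeyError:
            raise KeyError(f"test {test_id!r} not in battery") from None

    @property
    def timed_ids(self) -> list[str]:
        return [t.id for t in self._tests if t.timed]

    @property
    def language_dependent_ids(self) -> list[str]:
        return [t.id for t in self._tests if t.language_dependent]

    def domain_of(self, test_id: str) -> str:
        return self[test_id].domain


def default_battery() -> TestBattery:
    """The 19-measure battery, in presentation order."""
    return TestBattery(
        [
            TestDescriptor("camel_cactus", "Camel and Cactus Test", DOMAIN_LANGUAGE),
            TestDescriptor("boston_naming", "Boston Naming Test", DOMAIN_LANGUAGE),
            TestDescriptor("category_fluency", "Category fluency", DOMAIN_LANGUAGE),
            TestDescriptor("digit_span_forward", "Digit span forward", DOMAIN_ATTENTION),
            TestDescriptor("tmt_a", "Trail Making Test - part A", DOMAIN_ATTENTION, timed=True),
            TestDescriptor("digit_symbol", "Digit symbol", DOMAIN_ATTENTION),
            TestDescriptor("cwit_colour", "D-KEFS CWIT - colour naming", DOMAIN_ATTENTION, timed=True),
            TestDescriptor("cwit_word", "D-KEFS CWIT - word naming", DOMAIN_ATTENTION, timed=True),
            TestDescriptor("digit_span_backward", "Digit span backward", DOMAIN_EXECUTIVE),
            TestDescriptor("tmt_b", "Trail Making Test - part B", DOMAIN_EXECUTIVE, timed=True),
            TestDescriptor("cwit_ink", "D-KEFS CWIT - ink naming", DOMAIN_EXECUTIVE, timed=True),
            TestDescriptor(
                "phonemic_fluency", "Phonemic fluency", DOMAIN_EXECUTIVE, language_dependent=True
            ),
            TestDescriptor("benson_copy", "Benson figure copy", DOMAIN_VISUOCONSTRUCTION),
            TestDescriptor("benson_recall", "Benson figure recall", DOMAIN_MEMORY),
            TestDescriptor(
                "fcsrt_free", "FCSRT free recall", DOMAIN_MEMORY, language_dependent=True
            ),
            TestDescriptor(
                "fcsrt_total", "FCSRT total recall", DOMAIN_MEMORY, language_dependent=True
            ),
            TestDescriptor(
                "fcsrt_delayed_free",
                "FCSRT delayed free recall",
                DOMAIN_MEMORY,
                language_dependent=True,
            ),
            TestDescriptor(
                "fcsrt_delayed_total",
                "FCSRT delayed total recall",
                DOMAIN_MEMORY,
                language_dependent=True,
            ),
            TestDescriptor(
                "facial_emotion", "Facial Emotion Recognition Test", DOMAIN_SOCIAL
            ),
        ]
    )


DEFAULT_BATTERY = default_battery()
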