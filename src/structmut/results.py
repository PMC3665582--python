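"""Result containers shared by all analyses."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

ANALYSIS_NAMES = (
    "interface", "binding", "sprotft", "clash", "void", "cisproline",
    "glycine", "proline", "hbond", "corephilic", "surfacephobic",
    "buriedcharge", "ssgeometry", "impact",
)


@dataclass
class AnalysisResult:
    """Outcome of one structural analysis: a continuous score plus a
    Boolean damage call.  `extras` carries secondary continuous values
    (feature extraction reads them)."""
    analysis_name: str
    applicable: bool
    flagged: bool
    score: Optional[float] = None
    detail: str = ""
    units: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.analysis_name not in ANALYSIS_NAMES:
            raise ValueError(f"unknown analysis {self.analysis_name!r}")
        self.applicable = bool(self.applicable)
        self.flagged = bool(self.flagged)
        if self.score is not None:
            self.score = float(self.score)
        if self.flagged and not self.applicable:
            raise ValueError("flagged result must be applicable")

    @classmethod
    def not_applicable(cls, name: str, detail: str = ""):
        return cls(analysis_name=name, applicable=False, flagged=False,
                   score=None, detail=detail)


@dataclass
class AnalysisReport:
    """All fourteen analysis outcomes for one mutation."""
    mutation: object          # MutationSpec
    results: list = field(default_factory=list)

    def __post_init__(self):
        names = [r.analysis_name for r in self.results]
        if sorted(names) != sorted(ANALYSIS_NAMES):
            raise ValueError(
                f"report must contain exactly one result per analysis; got {names}")

    @property
    def explained(self) -> bool:
        return any(r.flagged for r in self.results)

    def result(self, name: str) -> AnalysisResult:
        for r in self.results:
            if r.analysis_name == name:
                return r
        raise KeyError(name)
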