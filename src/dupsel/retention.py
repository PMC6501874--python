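"""Duplicate-gene retention-mode classification.

After a gene duplication, stable retention of both daughter copies can
follow several routes distinguished by where positive selection acts and
which functions the copies carry:

- NF  (neofunctionalization): one copy under positive selection for a
  novel function, the other without evidence of positive selection and
  retaining the ancestral function.
- EAC (escape from adaptive conflict): both copies under positive
  selection, one improving the ancestral function, the other a novel one.
- CN  (concerted neofunctionalization): both copies under positive
  selection and both selected for novel functions.
- SF-or-ambiguous: anything else, including subfunctionalization (an
  essentially neutral process) and patterns degraded by unknown
  annotations.

Selection evidence comes from upstream branch-site or MK tests; function
states are user annotations (they derive from functional assays, not from
sequence), so the classifier is a pure decision table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_FUNCTIONS = ("ancestral", "novel", "novel-variant", "unknown")
MODES = ("NF", "EAC", "CN", "SF-or-ambiguous")


@dataclass(frozen=True)
class BranchEvidence:
    """Selection evidence on one branch.

    ``selection_call`` is "positive" only when the adjusted p-value meets
    the significance level; otherwise "no-positive-evidence" (the package
    never affirms purifying selection from a failed positive-selection
    test).
    """

    branch_id: str
    p_adjusted: float
    source: str = "branch_site"  # branch_site | mk | both
    omega2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p_adjusted must lie in [0, 1]")
        if self.source not in ("branch_site", "mk", "both"):
            raise ValueError(f"unknown evidence source {self.source!r}")

    def is_positive(self, alpha: float) -> bool:
        return self.p_adjusted <= alpha


@dataclass(frozen=True)
class FunctionAnnotation:
    """User-supplied functional state of one gene copy."""

    copy_id: str
    function_state: str

    def __post_init__(self) -> None:
        if self.function_state not in VALID_FUNCTIONS:
            raise ValueError(f"function_state must be one of {VALID_FUNCTIONS}")

    @property
    def is_novel(self) -> bool:
        return self.function_state in ("novel", "novel-variant")


@dataclass
class RetentionCall:
    """Verdict of the retention-mode decision table with its evidence trail."""

    mode: str
    evidence: dict = field(default_factory=dict)
    caveats: list[str] = field(default_factory=list)


def classify_retention(daughter_a: tuple[BranchEvidence, FunctionAnnotation],
                       daughter_b: tuple[BranchEvidence, FunctionAnnotation],
                       pre_duplication: Optional[BranchEvidence] = None,
                       alpha: float = 0.05) -> RetentionCall:
    """Map per-daughter selection evidence and function states to a mode.

    NF requires exactly one positively selected daughter with the other
    retaining the ancestral function; EAC requires both daughters positive
    with one ancestral function; CN requires both positive and both
    novel.  Unknown function states degrade the call to SF-or-ambiguous
    with explicit caveats.  Symmetric in the daughter order.
    """
    if daughter_a is None or daughter_b is None:
        raise ValueError("both daughter copies are required")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    (ev_a, fn_a), (ev_b, fn_b) = daughter_a, daughter_b

    caveats: list[str] = []
    for fn in (fn_a, fn_b):
        if fn.function_state == "unknown":
            caveats.append(f"function of {fn.copy_id} is unknown")
    pos_a, pos_b = ev_a.is_positive(alpha), ev_b.is_positive(alpha)

    evidence = {
        fn_a.copy_id: {"positive_selection": pos_a, "p_adjusted": ev_a.p_adjusted,
                       "source": ev_a.source, "function": fn_a.function_state},
        fn_b.copy_id: {"positive_selection": pos_b, "p_adjusted": ev_b.p_adjusted,
                       "source": ev_b.source, "function": fn_b.function_state},
    }
    if pre_duplication is not None:
        evidence["pre_duplication"] = {
            "positive_selection": pre_duplication.is_positive(alpha),
            "p_adjusted": pre_duplication.p_adjusted,
            "source": pre_duplication.source,
        }

    if caveats:
        return RetentionCall(mode="SF-or-ambiguous", evidence=evidence, caveats=caveats)

    mode = "SF-or-ambiguous"
    if pos_a != pos_b:
        # exactly one daughter positive: NF if the quiet copy keeps the
        # ancestral function (and the selected copy carries the novelty)
        quiet_fn = fn_b if pos_a else fn_a
        selected_fn = fn_a if pos_a else fn_b
        if quiet_fn.function_state == "ancestral" and selected_fn.is_novel:
            mode = "NF"
    elif pos_a and pos_b:
        novel_a, novel_b = fn_a.is_novel, fn_b.is_novel
        if novel_a and novel_b:
            mode = "CN"
        elif novel_a != novel_b and "ancestral" in (fn_a.function_state,
                                                    fn_b.function_state):
            mode = "EAC"
    if mode == "SF-or-ambiguous" and not caveats:
        caveats = ["pattern matches no positive-selection retention model"]
    return RetentionCall(mode=mode, evidence=evidence, caveats=caveats)
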