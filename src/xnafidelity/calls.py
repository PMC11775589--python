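"""Watermark validation and mutation calling on aligned clones.

A clone only reports on polymerase fidelity if it demonstrably passed through
the XNA intermediate: both engineered watermark dinucleotides must read as
their converted state (AA->TT in the 5' PBS, TT->AA in the 3' PBS), with no
gap in either.  Clones retaining the template state are carryover DNA and are
excluded; a no-RT control run turns the same filter into a contamination
check.

Mutation events are called only over the analysis region between the primer
binding sites — PBS and watermark bases are primer-dictated and say nothing
about the polymerase.  Columns where the clone reads N are skipped entirely
(neither an error nor an opportunity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import Alignment, DEFAULT_SCORING, ScoringScheme, align_global, left_normalize_indels, orient_clone
from .design import DNA_BASES, AssayDesign, CloneRecord

__all__ = [
    "WatermarkResult",
    "MutationEvent",
    "ContaminationSummary",
    "check_watermarks",
    "call_mutations",
    "detect_no_rt_contamination",
]


@dataclass(frozen=True)
class MutationEvent:
    """One substitution, insertion, or deletion in template coordinates.

    For an insertion, ``template_pos`` is the template position after which
    the inserted bases sit and ``to_base`` holds the inserted bases; for a
    deletion, ``from_base`` holds the deleted template bases.  ``length`` is
    the number of nucleotides involved (always 1 for substitutions).
    """

    kind: str  # substitution | insertion | deletion
    template_pos: int
    from_base: str
    to_base: str
    length: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "substitution":
            if (
                self.from_base == self.to_base
                or self.from_base not in DNA_BASES
                or self.to_base not in DNA_BASES
            ):
                raise ValueError(
                    f"substitution must change one ACGT base into another, "
                    f"got {self.from_base!r}->{self.to_base!r}"
                )
        if self.length < 1:
            raise ValueError("event length must be >= 1")


@dataclass(frozen=True)
class WatermarkResult:
    """Outcome of the watermark filter for one clone."""

    clone_id: str
    observed5: str
    observed3: str
    passed: bool
    failure_reason: str  # none | watermark5_unconverted | watermark3_unconverted
    #                    | both_unconverted | gap_in_watermark | low_identity


def _clone_chars_at(alignment: Alignment, positions: Iterable[int]) -> str:
    """Clone characters aligned to the given template positions ('-' for gaps)."""
    wanted = {p: "-" for p in positions}
    for col, tpos in enumerate(alignment.column_map):
        if tpos in wanted:
            wanted[tpos] = alignment.aligned_clone[col]
    return "".join(wanted[p] for p in wanted)


def check_watermarks(
    alignment: Alignment, design: AssayDesign, clone_id: str = ""
) -> WatermarkResult:
    """Classify a clone by what it shows at the two watermark dinucleotides.

    Passing requires exact equality with the converted state at both
    watermarks and no gap at any of the four positions; a gap makes the
    conversion unverifiable and fails the clone.
    """
    obs5 = _clone_chars_at(alignment, design.watermark5.positions)
    obs3 = _clone_chars_at(alignment, design.watermark3.positions)
    ok5 = obs5 == design.watermark5.converted_state
    ok3 = obs3 == design.watermark3.converted_state
    if "-" in obs5 or "-" in obs3:
        reason = "gap_in_watermark"
    elif ok5 and ok3:
        reason = "none"
    elif not ok5 and not ok3:
        reason = "both_unconverted"
    elif not ok5:
        reason = "watermark5_unconverted"
    else:
        reason = "watermark3_unconverted"
    return WatermarkResult(
        clone_id=clone_id,
        observed5=obs5,
        observed3=obs3,
        passed=(ok5 and ok3),
        failure_reason=reason,
    )


def call_mutations(alignment: Alignment, design: AssayDesign) -> list[MutationEvent]:
    """Convert an alignment into mutation events within the analysis region.

    The alignment should be left-normalized first so that indel coordinates
    in homopolymers are reproducible.  Mismatched base/base columns become
    substitutions; each maximal run of clone gaps becomes one deletion event
    and each maximal run of template gaps one insertion event, with length
    equal to the run length.  Columns where the clone reads N are skipped.
    Insertions are anchored to the preceding template position and counted
    when that anchor lies in the analysis region.
    """
    a_lo, a_hi = design.analysis_span
    events: list[MutationEvent] = []
    t_row = alignment.aligned_template
    c_row = alignment.aligned_clone
    ncols = len(t_row)

    col = 0
    last_tpos = -1
    while col < ncols:
        tpos = alignment.column_map[col]
        if tpos == -1:  # insertion run
            run_start = col
            while col < ncols and alignment.column_map[col] == -1:
                col += 1
            inserted = c_row[run_start:col]
            if a_lo <= last_tpos < a_hi and "N" not in inserted:
                events.append(
                    MutationEvent(
                        kind="insertion",
                        template_pos=last_tpos,
                        from_base="",
                        to_base=inserted,
                        length=len(inserted),
                    )
                )
            continue
        if c_row[col] == "-":  # deletion run
            run_start_pos = tpos
            deleted = []
            while col < ncols and alignment.column_map[col] != -1 and c_row[col] == "-":
                p = alignment.column_map[col]
                if a_lo <= p < a_hi:
                    deleted.append(t_row[col])
                last_tpos = p
                col += 1
            if deleted:
                first_in_span = max(run_start_pos, a_lo)
                events.append(
                    MutationEvent(
                        kind="deletion",
                        template_pos=first_in_span,
                        from_base="".join(deleted),
                        to_base="",
                        length=len(deleted),
                    )
                )
            continue
        if a_lo <= tpos < a_hi and c_row[col] != "N" and c_row[col] != t_row[col]:
            events.append(
                MutationEvent(
                    kind="substitution",
                    template_pos=tpos,
                    from_base=t_row[col],
                    to_base=c_row[col],
                )
            )
        last_tpos = tpos
        col += 1
    return events


@dataclass(frozen=True)
class ContaminationSummary:
    """Watermark pass rate of a (no-RT) control dataset."""

    n_clones: int
    n_passed: int
    pass_fraction: float
    contaminated: bool


def detect_no_rt_contamination(
    control_clones: Sequence[CloneRecord],
    design: AssayDesign,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> ContaminationSummary:
    """Fraction of no-RT control clones that pass the watermark filter.

    A no-RT reaction cannot produce watermark-converted product, so any
    passing clone flags DNA contamination arising during PCR.
    """
    if not control_clones:
        raise ValueError("control dataset is empty")
    n_passed = 0
    for rec in control_clones:
        oriented, _ = orient_clone(rec.sequence, design.template, scoring)
        aln = left_normalize_indels(align_global(design.template, oriented, scoring))
        if check_watermarks(aln, design, rec.id).passed:
            n_passed += 1
    frac = n_passed / len(control_clones)
    return ContaminationSummary(
        n_clones=len(control_clones),
        n_passed=n_passed,
        pass_fraction=frac,
        contaminated=frac > 0.0,
    )
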