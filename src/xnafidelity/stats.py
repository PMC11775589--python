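"""Mutation spectrum, per-type error rates, and the aggregate fidelity score.

The error rate of a substitution type is

    mu[exp -> obs] = (#observed / #expected) * 1000

where #observed counts calls of that type over all watermark-validated clones
and #expected counts the analyzed template positions carrying the source base
(per-opportunity denominator).  The total error rate sums mu over the 12
substitution types.  The aggregate fidelity score is the percentage of
correctly replicated positions over a full replication cycle, counting
substitutions and every inserted or deleted base as errors:

    fidelity% = (1 - (substitutions + inserted + deleted bases)
                     / analyzed positions) * 100

Rates are reported uncorrected for reverse-transcription and PCR background,
i.e. they describe the composite replication cycle, not the XNA polymerase in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .align import Alignment
from .calls import MutationEvent
from .design import DNA_BASES, AssayDesign

__all__ = [
    "SUBSTITUTION_TYPES",
    "SpectrumTable",
    "FidelityReport",
    "UndefinedRateError",
    "error_rate",
    "build_spectrum",
    "summarize",
    "rate_interval",
]

#: The 12 ordered substitution types (source base -> observed base).
SUBSTITUTION_TYPES: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in DNA_BASES for b in DNA_BASES if a != b
)


class UndefinedRateError(ZeroDivisionError):
    """No opportunities for this type: the rate is not estimable (never 0)."""


def error_rate(observed_count: int, expected_count: int) -> float:
    """Errors per 1000 opportunities: (#observed / #expected) * 1000."""
    if expected_count <= 0:
        raise UndefinedRateError(
            "expected_count is 0: the rate is not estimable from this data"
        )
    if not 0 <= observed_count <= expected_count:
        raise ValueError(
            f"observed_count must lie in [0, expected_count], "
            f"got {observed_count}/{expected_count}"
        )
    return observed_count / expected_count * 1000.0


def rate_interval(
    observed_count: int, expected_count: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact Poisson (Garwood) confidence interval on a per-1000 rate.

    The interval is computed on the event count via chi-square quantiles and
    scaled by 1000/expected.  The lower bound is 0 when no events were seen.
    """
    if expected_count <= 0:
        raise UndefinedRateError("expected_count is 0: no interval is estimable")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    alpha = 1.0 - level
    k = observed_count
    low = 0.0 if k == 0 else sps.chi2.ppf(alpha / 2, 2 * k) / 2.0
    high = sps.chi2.ppf(1 - alpha / 2, 2 * (k + 1)) / 2.0
    scale = 1000.0 / expected_count
    return (low * scale, high * scale)


@dataclass
class SpectrumTable:
    """Observed substitution counts and per-base opportunity counts.

    ``expected[X]`` is the number of analyzed template positions carrying
    base X summed over passing clones; positions aligned to N or deleted in
    the clone offer no substitution opportunity and are excluded.
    """

    observed: dict[tuple[str, str], int]
    expected: dict[str, int]
    ins_count: int
    del_count: int
    total_positions: int
    n_clones_passed: int
    n_clones_failed: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.observed.values()) or any(
            v < 0 for v in self.expected.values()
        ):
            raise ValueError("spectrum counts must be non-negative")
        if sum(self.expected.values()) != self.total_positions:
            raise ValueError("expected counts must sum to total_positions")
        for (src, dst), n_obs in self.observed.items():
            if n_obs > self.expected[src]:
                raise ValueError(
                    f"observed[{src}->{dst}] exceeds opportunities for {src}"
                )

    def to_frame(self) -> pd.DataFrame:
        """Spectrum as a tidy table (12 substitution rows + insertion/deletion)."""
        rows = []
        for src, dst in SUBSTITUTION_TYPES:
            exp = self.expected[src]
            rows.append(
                {
                    "type": f"{src}>{dst}",
                    "observed": self.observed[(src, dst)],
                    "expected": exp,
                    "rate_per_1000": (
                        self.observed[(src, dst)] / exp * 1000.0 if exp else float("nan")
                    ),
                }
            )
        for label, count in (("insertion", self.ins_count), ("deletion", self.del_count)):
            rows.append(
                {
                    "type": label,
                    "observed": count,
                    "expected": self.total_positions,
                    "rate_per_1000": (
                        count / self.total_positions * 1000.0
                        if self.total_positions
                        else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows, columns=["type", "observed", "expected", "rate_per_1000"])


def build_spectrum(
    events: Mapping[str, Sequence[MutationEvent]],
    alignments: Mapping[str, Alignment],
    design: AssayDesign,
    n_clones_failed: int = 0,
) -> SpectrumTable:
    """Tally events and opportunities over the passing clones.

    ``events`` and ``alignments`` are keyed by clone id and must cover the
    same (watermark-validated) clones.
    """
    if set(events) != set(alignments):
        raise ValueError("events and alignments must cover the same clone ids")
    a_lo, a_hi = design.analysis_span
    observed = {t: 0 for t in SUBSTITUTION_TYPES}
    expected = {b: 0 for b in DNA_BASES}
    ins_count = del_count = 0

    for clone_id, aln in alignments.items():
        for col, tpos in enumerate(aln.column_map):
            if not a_lo <= tpos < a_hi or tpos == -1:
                continue
            c = aln.aligned_clone[col]
            if c == "-" or c == "N":
                continue  # no substitution opportunity at this position
            expected[aln.aligned_template[col]] += 1
        for ev in events[clone_id]:
            if not a_lo <= ev.template_pos < a_hi:
                raise ValueError(
                    f"event at {ev.template_pos} in clone {clone_id} lies "
                    f"outside the analysis region {design.analysis_span}"
                )
            if ev.kind == "substitution":
                observed[(ev.from_base, ev.to_base)] += 1
            elif ev.kind == "insertion":
                ins_count += ev.length
            else:
                del_count += ev.length

    return SpectrumTable(
        observed=observed,
        expected=expected,
        ins_count=ins_count,
        del_count=del_count,
        total_positions=sum(expected.values()),
        n_clones_passed=len(alignments),
        n_clones_failed=n_clones_failed,
    )


@dataclass
class FidelityReport:
    """Per-type error rates, total error rate, and the aggregate fidelity score.

    ``mu`` holds the per-1000 rate for each substitution type (None when the
    source base offered no opportunities); ``mu_total`` sums the estimable
    types.  ``aggregate_fidelity_pct`` is rounded to one decimal
    (round-half-even); ``aggregate_fidelity_raw`` keeps full precision.
    ``low_coverage`` flags reports built from fewer than 1000 analyzed
    positions, the assay's stated minimum sequencing depth.
    """

    mu: dict[tuple[str, str], Optional[float]]
    mu_total: float
    indel_rate: float
    aggregate_fidelity_pct: float
    aggregate_fidelity_raw: float
    ci: dict[tuple[str, str], Optional[tuple[float, float]]]
    n_errors: int
    total_positions: int
    n_clones_passed: int
    n_clones_failed: int
    low_coverage: bool
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready dictionary (full precision; tuple keys flattened)."""
        return {
            "mu_per_1000": {f"{a}>{b}": v for (a, b), v in self.mu.items()},
            "mu_total_per_1000": self.mu_total,
            "indel_rate_per_1000": self.indel_rate,
            "aggregate_fidelity_pct": self.aggregate_fidelity_pct,
            "aggregate_fidelity_raw": self.aggregate_fidelity_raw,
            "ci_per_1000": {
                f"{a}>{b}": (list(v) if v is not None else None)
                for (a, b), v in self.ci.items()
            },
            "n_errors": self.n_errors,
            "total_positions": self.total_positions,
            "n_clones_passed": self.n_clones_passed,
            "n_clones_failed": self.n_clones_failed,
            "low_coverage": self.low_coverage,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def summarize(
    spectrum: SpectrumTable, level: float = 0.95, metadata: Optional[dict] = None
) -> FidelityReport:
    """Reduce a spectrum to rates and the aggregate fidelity score.

    mu_total sums only the 12 substitution rates (the error-rate formula is
    defined per substitution type); the aggregate fidelity score additionally
    counts every inserted and deleted base as an error.  The two are reported
    separately.
    """
    if spectrum.total_positions < 1:
        raise UndefinedRateError("no analyzed positions: nothing to summarize")
    mu: dict[tuple[str, str], Optional[float]] = {}
    ci: dict[tuple[str, str], Optional[tuple[float, float]]] = {}
    for src, dst in SUBSTITUTION_TYPES:
        exp = spectrum.expected[src]
        obs = spectrum.observed[(src, dst)]
        if exp == 0:
            mu[(src, dst)] = None
            ci[(src, dst)] = None
        else:
            mu[(src, dst)] = error_rate(obs, exp)
            ci[(src, dst)] = rate_interval(obs, exp, level)
    mu_total = sum(v for v in mu.values() if v is not None)
    n_sub = sum(spectrum.observed.values())
    n_errors = n_sub + spectrum.ins_count + spectrum.del_count
    raw = (1.0 - n_errors / spectrum.total_positions) * 100.0
    # one-decimal report, round-half-even on the exact rational (exact ties
    # like 99.95 go to the even tenth, immune to binary-float drift)
    rounded = float(
        (Decimal(100) * (1 - Decimal(n_errors) / Decimal(spectrum.total_positions)))
        .quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN)
    )
    return FidelityReport(
        mu=mu,
        mu_total=mu_total,
        indel_rate=(spectrum.ins_count + spectrum.del_count)
        / spectrum.total_positions
        * 1000.0,
        aggregate_fidelity_pct=rounded,
        aggregate_fidelity_raw=raw,
        ci=ci,
        n_errors=n_errors,
        total_positions=spectrum.total_positions,
        n_clones_passed=spectrum.n_clones_passed,
        n_clones_failed=spectrum.n_clones_failed,
        low_coverage=spectrum.total_positions < 1000,
        metadata=metadata or {},
    )
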