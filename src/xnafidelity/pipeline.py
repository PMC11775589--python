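"""End-to-end pipeline: orient, align, filter, call, summarize, report.

Each clone flows through orientation, affine-gap global alignment to the
template, indel left-normalization, an identity filter (failed sequencing
reads), the watermark filter, and mutation calling; passing clones feed the
spectrum and the fidelity report.  Individual clone failures never abort a
run — every exclusion is tallied with its reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .align import DEFAULT_SCORING, ScoringScheme, align_global, left_normalize_indels, orient_clone
from .calls import MutationEvent, WatermarkResult, call_mutations, check_watermarks
from .design import AssayDesign, CloneRecord, default_design, load_design, read_fasta
from .simulate import ErrorModel, simulate_dataset, uniform_model
from .stats import FidelityReport, build_spectrum, summarize

logger = logging.getLogger("xnafidelity")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "NoPassingClonesError",
    "analyze_clones",
    "run_pipeline",
    "load_config",
]

DEFAULT_IDENTITY_THRESHOLD = 0.7


class NoPassingClonesError(RuntimeError):
    """The dataset contains no watermark-validated sequences."""


@dataclass
class SimulationSpec:
    """Simulation block of a pipeline config."""

    n: int
    p_sub: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    contaminant_fraction: float = 0.0
    flip_fraction: float = 0.0
    seed: int = 0

    def model(self) -> ErrorModel:
        return uniform_model(self.p_sub, self.ins_rate, self.del_rate)


@dataclass
class PipelineConfig:
    """What to analyze and how; exactly one of input_fasta / simulation."""

    design_path: Optional[str] = None
    input_fasta: Optional[str] = None
    simulation: Optional[SimulationSpec] = None
    scoring: ScoringScheme = DEFAULT_SCORING
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.input_fasta is None) == (self.simulation is None):
            raise ValueError(
                "config must provide exactly one of input_fasta / simulation"
            )
        if self.input_fasta is not None and not Path(self.input_fasta).exists():
            raise FileNotFoundError(self.input_fasta)
        if self.design_path is not None and not Path(self.design_path).exists():
            raise FileNotFoundError(self.design_path)

    def design(self) -> AssayDesign:
        return load_design(self.design_path) if self.design_path else default_design()


@dataclass
class PipelineResult:
    """Everything a run produced, keyed by clone id where applicable."""

    report: FidelityReport
    watermark_results: list[WatermarkResult]
    events: dict[str, list[MutationEvent]]
    strands: dict[str, str]
    counts: dict[str, int]


def analyze_clones(
    clones: Sequence[CloneRecord],
    design: AssayDesign,
    scoring: ScoringScheme = DEFAULT_SCORING,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    metadata: Optional[dict] = None,
) -> PipelineResult:
    """Run the analysis stages on in-memory clones and summarize fidelity."""
    if not clones:
        raise ValueError("no clones to analyze")
    template = design.template
    watermark_results: list[WatermarkResult] = []
    strands: dict[str, str] = {}
    passing_alignments = {}
    passing_events: dict[str, list[MutationEvent]] = {}
    n_low_identity = 0

    for rec in clones:
        oriented, strand = orient_clone(rec.sequence, template, scoring)
        strands[rec.id] = strand
        aln = left_normalize_indels(align_global(template, oriented, scoring))
        if aln.identity < identity_threshold:
            n_low_identity += 1
            watermark_results.append(
                WatermarkResult(
                    clone_id=rec.id,
                    observed5="",
                    observed3="",
                    passed=False,
                    failure_reason="low_identity",
                )
            )
            continue
        wm = check_watermarks(aln, design, rec.id)
        watermark_results.append(wm)
        if wm.passed:
            passing_alignments[rec.id] = aln
            passing_events[rec.id] = call_mutations(aln, design)

    n_failed = len(clones) - len(passing_alignments)
    logger.info(
        "clones=%d oriented=%d low_identity=%d watermark_passed=%d failed=%d",
        len(clones), len(clones), n_low_identity, len(passing_alignments), n_failed,
    )
    if not passing_alignments:
        raise NoPassingClonesError(
            "no watermark-validated sequences: nothing to measure fidelity on"
        )
    spectrum = build_spectrum(passing_events, passing_alignments, design, n_failed)
    n_events = sum(len(v) for v in passing_events.values())
    logger.info(
        "events_called=%d analyzed_positions=%d", n_events, spectrum.total_positions
    )
    report = summarize(spectrum, metadata=metadata)
    if report.low_coverage:
        logger.warning(
            "only %d analyzed positions (< 1000): fidelity estimate is "
            "below the assay's stated sequencing depth", spectrum.total_positions,
        )
    counts = {
        "clones_read": len(clones),
        "low_identity": n_low_identity,
        "watermark_passed": len(passing_alignments),
        "watermark_failed": n_failed - n_low_identity,
        "events_called": n_events,
    }
    return PipelineResult(
        report=report,
        watermark_results=watermark_results,
        events=passing_events,
        strands=strands,
        counts=counts,
    )


def _write_artifacts(result: PipelineResult, spectrum_design: AssayDesign, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "clone_id": cid,
                "kind": ev.kind,
                "template_pos": ev.template_pos,
                "from_base": ev.from_base,
                "to_base": ev.to_base,
                "length": ev.length,
            }
            for cid, evs in result.events.items()
            for ev in evs
        ],
        columns=["clone_id", "kind", "template_pos", "from_base", "to_base", "length"],
    ).to_csv(outdir / "events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "clone_id": w.clone_id,
                "observed5": w.observed5,
                "observed3": w.observed3,
                "passed": w.passed,
                "failure_reason": w.failure_reason,
            }
            for w in result.watermark_results
        ]
    ).to_csv(outdir / "watermarks.tsv", sep="\t", index=False)
    result.report.to_json(outdir / "report.json")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured run and (if ``outdir`` is set) write artifacts.

    Writes ``events.tsv``, ``watermarks.tsv``, ``spectrum.tsv``,
    ``report.json`` into ``outdir``.  Reports are deterministic given the
    config (no timestamps).
    """
    design = config.design()
    metadata: dict = {
        "design": design.name,
        "identity_threshold": config.identity_threshold,
        "scoring": {
            "match": config.scoring.match,
            "mismatch": config.scoring.mismatch,
            "gap_open": config.scoring.gap_open,
            "gap_extend": config.scoring.gap_extend,
        },
        "version": __version__,
    }
    if config.simulation is not None:
        sim = config.simulation
        logger.info(
            "simulating n=%d p_sub=%g ins=%g del=%g contaminants=%g seed=%d",
            sim.n, sim.p_sub, sim.ins_rate, sim.del_rate,
            sim.contaminant_fraction, sim.seed,
        )
        clones, _truth = simulate_dataset(
            design,
            sim.model(),
            n=sim.n,
            contaminant_fraction=sim.contaminant_fraction,
            flip_fraction=sim.flip_fraction,
            seed=sim.seed,
        )
        metadata["simulation"] = {
            "n": sim.n, "p_sub": sim.p_sub, "ins_rate": sim.ins_rate,
            "del_rate": sim.del_rate,
            "contaminant_fraction": sim.contaminant_fraction,
            "flip_fraction": sim.flip_fraction, "seed": sim.seed,
        }
    else:
        clones = read_fasta(config.input_fasta)
        metadata["input_fasta"] = str(config.input_fasta)
    result = analyze_clones(
        clones,
        design,
        scoring=config.scoring,
        identity_threshold=config.identity_threshold,
        metadata=metadata,
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        _write_artifacts(result, design, outdir)
        # spectrum in the 12-type layout used for mutational profiles
        _spectrum_frame(result, design).to_csv(
            outdir / "spectrum.tsv", sep="\t", index=False
        )
        logger.info("artifacts written to %s", outdir)
    return result


def _spectrum_frame(result: PipelineResult, design: AssayDesign) -> pd.DataFrame:
    from .stats import SUBSTITUTION_TYPES

    report = result.report
    rows = []
    for src, dst in SUBSTITUTION_TYPES:
        mu = report.mu[(src, dst)]
        ci = report.ci[(src, dst)]
        rows.append(
            {
                "type": f"{src}>{dst}",
                "rate_per_1000": mu if mu is not None else float("nan"),
                "ci_low": ci[0] if ci else float("nan"),
                "ci_high": ci[1] if ci else float("nan"),
            }
        )
    rows.append(
        {
            "type": "indel",
            "rate_per_1000": report.indel_rate,
            "ci_low": float("nan"),
            "ci_high": float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["type", "rate_per_1000", "ci_low", "ci_high"])


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML.

    Top-level keys: ``design`` (path, optional — bundled stand-in design if
    absent), exactly one of ``input_fasta`` / ``simulation``, optional
    ``scoring`` overrides, ``identity_threshold``, ``outdir``.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    scoring = DEFAULT_SCORING
    if "scoring" in cfg:
        s = cfg["scoring"]
        scoring = ScoringScheme(
            match=int(s.get("match", DEFAULT_SCORING.match)),
            mismatch=int(s.get("mismatch", DEFAULT_SCORING.mismatch)),
            gap_open=int(s.get("gap_open", DEFAULT_SCORING.gap_open)),
            gap_extend=int(s.get("gap_extend", DEFAULT_SCORING.gap_extend)),
        )
    sim = None
    if "simulation" in cfg:
        sim = SimulationSpec(**cfg["simulation"])
    base = path.parent

    def _resolve(p):
        if p is None:
            return None
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    return PipelineConfig(
        design_path=_resolve(cfg.get("design")),
        input_fasta=_resolve(cfg.get("input_fasta")),
        simulation=sim,
        scoring=scoring,
        identity_threshold=float(cfg.get("identity_threshold", DEFAULT_IDENTITY_THRESHOLD)),
        outdir=_resolve(cfg.get("outdir")),
    )
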