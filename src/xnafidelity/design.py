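"""Assay design model and sequence I/O.

The fidelity assay replicates a DNA template of defined sequence through an
XNA intermediate (DNA -> XNA -> DNA) and sequences TOPO-cloned amplicons of
the recovered cDNA.  The template carries two engineered dinucleotide
mismatches ("watermarks") inside its primer-binding sites (PBS): the 5' PBS
holds an AA that a genuine replication cycle converts to TT, and the 3' PBS a
TT converted to AA.  Polymerase errors are only counted over the analysis
region between the two PBS spans; watermark and PBS bases are dictated by the
primers, not by the polymerase.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "AssayDesign",
    "WatermarkSpec",
    "CloneRecord",
    "DesignError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "load_design",
    "default_design",
]


class DesignError(ValueError):
    """An assay design violates one of its structural invariants."""


class FastaParseError(ValueError):
    """Input FASTA is malformed; the message names the offending line."""


@dataclass(frozen=True)
class WatermarkSpec:
    """An engineered dinucleotide conversion inside a primer-binding site.

    ``template_state`` is the dinucleotide present in the starting DNA
    template; ``converted_state`` is what a product that truly passed through
    the XNA intermediate must show at the same positions.
    """

    start: int
    template_state: str
    converted_state: str

    def __post_init__(self) -> None:
        for name in ("template_state", "converted_state"):
            mer = getattr(self, name)
            if len(mer) != 2 or any(b not in DNA_BASES for b in mer):
                raise DesignError(f"{name} must be a 2-mer over ACGT, got {mer!r}")
        if self.template_state == self.converted_state:
            raise DesignError(
                "watermark template_state equals converted_state; "
                "the conversion would be unobservable"
            )

    @property
    def positions(self) -> tuple[int, int]:
        return (self.start, self.start + 1)


@dataclass(frozen=True)
class AssayDesign:
    """Reference template plus the spans and watermarks the pipeline needs.

    Invariants (checked on construction): the two PBS spans are disjoint, the
    analysis span lies strictly between them and overlaps neither, each
    watermark dinucleotide falls inside its own PBS, and the template is pure
    A/C/G/T (design oligos carry no ambiguity codes).
    """

    template: str
    pbs5_span: tuple[int, int]
    pbs3_span: tuple[int, int]
    analysis_span: tuple[int, int]
    watermark5: WatermarkSpec
    watermark3: WatermarkSpec
    name: str = "design"

    def __post_init__(self) -> None:
        tmpl = self.template
        if not tmpl:
            raise DesignError("template is empty")
        bad = set(tmpl) - set(DNA_BASES)
        if bad:
            raise DesignError(
                f"template contains non-ACGT characters: {sorted(bad)}"
            )
        n = len(tmpl)
        for label, (lo, hi) in (
            ("pbs5", self.pbs5_span),
            ("pbs3", self.pbs3_span),
            ("analysis", self.analysis_span),
        ):
            if not (0 <= lo < hi <= n):
                raise DesignError(f"{label} span {lo, hi} out of template bounds")
        if self.pbs5_span[1] > self.pbs3_span[0]:
            raise DesignError("pbs5 and pbs3 spans overlap or are out of order")
        a_lo, a_hi = self.analysis_span
        if not (self.pbs5_span[1] <= a_lo and a_hi <= self.pbs3_span[0]):
            raise DesignError(
                "analysis span must lie strictly between pbs5 and pbs3"
            )
        for label, wm, span in (
            ("watermark5", self.watermark5, self.pbs5_span),
            ("watermark3", self.watermark3, self.pbs3_span),
        ):
            if not (span[0] <= wm.start and wm.start + 2 <= span[1]):
                raise DesignError(f"{label} dinucleotide falls outside its PBS")
            observed = tmpl[wm.start : wm.start + 2]
            if observed != wm.template_state:
                raise DesignError(
                    f"{label} template_state {wm.template_state!r} does not "
                    f"match template bases {observed!r} at {wm.start}"
                )

    @property
    def analysis_length(self) -> int:
        return self.analysis_span[1] - self.analysis_span[0]

    def converted_template(self) -> str:
        """Template with both watermarks set to their converted state —
        the expected sequence of an error-free genuine replication product."""
        seq = list(self.template)
        for wm in (self.watermark5, self.watermark3):
            seq[wm.start : wm.start + 2] = wm.converted_state
        return "".join(seq)


@dataclass
class CloneRecord:
    """One sequenced clone (a base-called read of a TOPO-cloned amplicon)."""

    id: str
    sequence: str
    source: str = "observed"  # observed | synthetic_genuine | synthetic_contaminant

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.id!r} has an empty sequence")


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (N maps to N)."""
    unknown = set(seq) - set("ACGTN")
    if unknown:
        raise ValueError(f"cannot reverse-complement characters {sorted(unknown)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _precheck_fasta(path: Path) -> None:
    # SeqIO silently skips junk before the first '>'; report it with a line no.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise FastaParseError(
                f"{path}: line {lineno}: expected FASTA header starting "
                f"with '>', got {stripped[:30]!r}"
            )
    raise FastaParseError(f"{path}: file contains no FASTA records")


def read_fasta(path: str | Path, source: str = "observed") -> list[CloneRecord]:
    """Read clone sequences from FASTA.

    Sequences are uppercased and U is mapped to T (all sequenced material is
    cDNA-derived, so the pipeline works in DNA space).  Record order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_fasta(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(CloneRecord(id=rec.id, sequence=seq, source=source))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FastaParseError(f"{path}: duplicate record id {dup!r}")
    return records


def write_fasta(records: Sequence[CloneRecord], path: str | Path) -> None:
    """Write records as standard FASTA with 70-column line wrapping."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seqrecords)


def _as_span(value, label: str) -> tuple[int, int]:
    try:
        lo, hi = value
        return (int(lo), int(hi))
    except (TypeError, ValueError):
        raise DesignError(f"{label}: expected a [start, stop] pair, got {value!r}")


def load_design(config_path: str | Path) -> AssayDesign:
    """Load and validate an :class:`AssayDesign` from a YAML config.

    Expected keys: ``template``, ``pbs5``, ``pbs3``, ``analysis`` (each span a
    ``[start, stop]`` pair, 0-based half-open) and ``watermark5`` /
    ``watermark3`` mappings with ``start``, ``from``, ``to``.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DesignError(f"{config_path}: design config must be a mapping")
    missing = {"template", "pbs5", "pbs3", "analysis", "watermark5", "watermark3"} - set(cfg)
    if missing:
        raise DesignError(f"{config_path}: missing keys {sorted(missing)}")

    def wm(key: str) -> WatermarkSpec:
        block = cfg[key]
        if not isinstance(block, dict) or not {"start", "from", "to"} <= set(block):
            raise DesignError(f"{key}: expected mapping with start/from/to")
        return WatermarkSpec(
            start=int(block["start"]),
            template_state=str(block["from"]).upper(),
            converted_state=str(block["to"]).upper(),
        )

    return AssayDesign(
        template=str(cfg["template"]).upper(),
        pbs5_span=_as_span(cfg["pbs5"], "pbs5"),
        pbs3_span=_as_span(cfg["pbs3"], "pbs3"),
        analysis_span=_as_span(cfg["analysis"], "analysis"),
        watermark5=wm("watermark5"),
        watermark3=wm("watermark3"),
        name=str(cfg.get("name", config_path.stem)),
    )


def save_design(design: AssayDesign, path: str | Path) -> None:
    """Write a design back to the YAML layout accepted by :func:`load_design`."""
    cfg = {
        "name": design.name,
        "template": design.template,
        "pbs5": list(design.pbs5_span),
        "pbs3": list(design.pbs3_span),
        "analysis": list(design.analysis_span),
        "watermark5": {
            "start": design.watermark5.start,
            "from": design.watermark5.template_state,
            "to": design.watermark5.converted_state,
        },
        "watermark3": {
            "start": design.watermark3.start,
            "from": design.watermark3.template_state,
            "to": design.watermark3.converted_state,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# Bundled stand-in design: the real PBS7/8/9 primer sequences are not public,
# so this template is a synthetic design with the same structure — 20-nt PBS
# spans flanking a 56-nt analysis region with a balanced base composition
# (14 of each base), AA->TT at 5'-PBS positions 2-3 and TT->AA at 3'-PBS
# positions 78-79.
_PBS5 = "GTAACTGCAGTCGATCCGAT"
_ANALYSIS = "GTAGACCTGGGCCCGCAGTAACCTGGATGAAGTGAAATTTTATACCCGTGCCATTC"
_PBS3 = "GATTCGCAGTCAGGCTAGCA"


def default_design() -> AssayDesign:
    """The bundled stand-in assay design (96-nt template, 56-nt analysis region)."""
    template = _PBS5 + _ANALYSIS + _PBS3
    return AssayDesign(
        template=template,
        pbs5_span=(0, 20),
        pbs3_span=(76, 96),
        analysis_span=(20, 76),
        watermark5=WatermarkSpec(start=2, template_state="AA", converted_state="TT"),
        watermark3=WatermarkSpec(start=78, template_state="TT", converted_state="AA"),
        name="bundled-standin",
    )
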