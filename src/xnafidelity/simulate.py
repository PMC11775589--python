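"""Synthetic clone-dataset generator emulating the fidelity assay.

A genuine replication product is the template with both watermarks converted
(watermark bases are primer-dictated, hence exempt from the error model) and
per-site errors drawn independently over the analysis region.  The error model
is a 4x4 row-stochastic base-transition matrix plus per-site insertion and
deletion rates; models for sequential replication steps (XNA transcription,
then reverse transcription) compose by matrix product, matching the assay's
uncorrected, composite error process.

Contaminant clones emulate template carryover surviving PCR: exact template
copies that retain the unconverted watermark states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DNA_BASES, AssayDesign, CloneRecord, revcomp
from .calls import MutationEvent

__all__ = [
    "ErrorModel",
    "TruthTable",
    "uniform_model",
    "identity_model",
    "compose_models",
    "simulate_clone",
    "simulate_dataset",
]

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass(frozen=True)
class ErrorModel:
    """Per-site base-transition probabilities plus indel rates.

    ``sub_matrix[i, j]`` is P(observe base j | template base i) for one
    replication step, rows/columns ordered A, C, G, T; the diagonal is the
    no-change probability.  ``ins_rate`` / ``del_rate`` are per-site
    probabilities of a single-base insertion (in the gap after the site) and
    of the site being deleted.
    """

    sub_matrix: np.ndarray
    ins_rate: float = 0.0
    del_rate: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.sub_matrix, dtype=float)
        object.__setattr__(self, "sub_matrix", m)
        if m.shape != (4, 4):
            raise ValueError(f"sub_matrix must be 4x4, got {m.shape}")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("sub_matrix entries must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValueError("sub_matrix rows must each sum to 1 (within 1e-12)")
        for name in ("ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.ins_rate + self.del_rate >= 1.0 and (self.ins_rate + self.del_rate) != 1.0:
            raise ValueError("ins_rate + del_rate must be < 1")


def uniform_model(p_sub: float, ins_rate: float = 0.0, del_rate: float = 0.0) -> ErrorModel:
    """Error model with equal probability ``p_sub/3`` for each off-diagonal change."""
    if not 0.0 <= p_sub < 1.0:
        raise ValueError(f"p_sub must lie in [0, 1), got {p_sub}")
    m = np.full((4, 4), p_sub / 3.0)
    np.fill_diagonal(m, 1.0 - p_sub)
    return ErrorModel(sub_matrix=m, ins_rate=ins_rate, del_rate=del_rate)


def identity_model() -> ErrorModel:
    """Error-free model: identity substitution matrix, zero indel rates."""
    return ErrorModel(sub_matrix=np.eye(4))


def compose_models(first: ErrorModel, second: ErrorModel) -> ErrorModel:
    """Model of two replication steps applied sequentially (first, then second).

    combined[a -> b] = sum over intermediate bases x of
    first[a -> x] * second[x -> b]; per-site indel probabilities combine as
    1 - (1 - r1)(1 - r2).
    """
    return ErrorModel(
        sub_matrix=first.sub_matrix @ second.sub_matrix,
        ins_rate=1.0 - (1.0 - first.ins_rate) * (1.0 - second.ins_rate),
        del_rate=1.0 - (1.0 - first.del_rate) * (1.0 - second.del_rate),
    )


@dataclass
class TruthTable:
    """Ground truth for a simulated dataset: planted events and clone labels."""

    events: dict[str, list[MutationEvent]]
    sources: dict[str, str]
    flipped: dict[str, bool]
    seed: int
    params: dict

    def n_by_source(self, source: str) -> int:
        return sum(1 for s in self.sources.values() if s == source)

    def write_tsv(self, path: str | Path) -> None:
        """TSV with one row per planted event (clones with none get no rows)."""
        import pandas as pd

        rows = [
            {
                "clone_id": cid,
                "source": self.sources[cid],
                "event_kind": ev.kind,
                "template_pos": ev.template_pos,
                "from_base": ev.from_base,
                "to_base": ev.to_base,
            }
            for cid, evs in self.events.items()
            for ev in evs
        ]
        pd.DataFrame(
            rows,
            columns=["clone_id", "source", "event_kind", "template_pos", "from_base", "to_base"],
        ).to_csv(path, sep="\t", index=False)

    def write_params_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, **self.params}, fh, indent=2, sort_keys=True)


def simulate_clone(
    design: AssayDesign,
    model: ErrorModel,
    rng: np.random.Generator,
) -> tuple[str, list[MutationEvent]]:
    """Draw one genuine clone sequence and its planted events.

    The clone starts as the watermark-converted template; each analysis-region
    site is then independently deleted (prob ``del_rate``) or replaced by a
    draw from its substitution row, and a single uniform-random base is
    inserted in the gap after the site with prob ``ins_rate``.  At most one of
    substitution/deletion occurs per site, and events are recorded in template
    coordinates.
    """
    a_lo, a_hi = design.analysis_span
    length = a_hi - a_lo
    base_seq = design.converted_template()

    src_idx = np.fromiter(
        (_BASE_INDEX[b] for b in base_seq[a_lo:a_hi]), dtype=np.int64, count=length
    )
    u_del = rng.random(length)
    # base drawn per site from its substitution row via inverse CDF
    cdf = np.cumsum(model.sub_matrix, axis=1)
    cdf[:, -1] = 1.0
    u_sub = rng.random(length)
    new_idx = (u_sub[:, None] > cdf[src_idx]).sum(axis=1)
    u_ins = rng.random(length)
    ins_bases = rng.integers(0, 4, size=length)

    events: list[MutationEvent] = []
    pieces: list[str] = [base_seq[:a_lo]]
    for k in range(length):
        pos = a_lo + k
        src = base_seq[pos]
        if u_del[k] < model.del_rate:
            events.append(
                MutationEvent(kind="deletion", template_pos=pos, from_base=src, to_base="")
            )
        else:
            obs = DNA_BASES[new_idx[k]]
            pieces.append(obs)
            if obs != src:
                events.append(
                    MutationEvent(
                        kind="substitution", template_pos=pos, from_base=src, to_base=obs
                    )
                )
        if u_ins[k] < model.ins_rate:
            ins = DNA_BASES[ins_bases[k]]
            pieces.append(ins)
            events.append(
                MutationEvent(kind="insertion", template_pos=pos, from_base="", to_base=ins)
            )
    pieces.append(base_seq[a_hi:])
    return "".join(pieces), events


def simulate_dataset(
    design: AssayDesign,
    model: ErrorModel,
    n: int,
    contaminant_fraction: float = 0.0,
    flip_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[CloneRecord], TruthTable]:
    """Simulate a clone dataset with planted ground truth.

    The first ``ceil(contaminant_fraction * n)`` clones are exact template
    copies retaining the unconverted watermark states (template carryover);
    the rest are genuine replication products drawn through ``model``.  Each
    clone is emitted reverse-complemented with probability ``flip_fraction``
    (TOPO-TA inserts ligate in either orientation).  Per-clone random streams
    are keyed by (seed, clone index), so any subset of clone indices is stable
    under changes to ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, frac in (("contaminant_fraction", contaminant_fraction),
                       ("flip_fraction", flip_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")

    n_contaminant = math.ceil(contaminant_fraction * n)
    width = max(5, len(str(n)))
    records: list[CloneRecord] = []
    events: dict[str, list[MutationEvent]] = {}
    sources: dict[str, str] = {}
    flipped: dict[str, bool] = {}

    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        clone_id = f"clone{i:0{width}d}"
        if i < n_contaminant:
            seq, planted, source = design.template, [], "synthetic_contaminant"
        else:
            seq, planted = simulate_clone(design, model, rng)
            source = "synthetic_genuine"
        flip = bool(rng.random() < flip_fraction)
        if flip:
            seq = revcomp(seq)
        records.append(CloneRecord(id=clone_id, sequence=seq, source=source))
        events[clone_id] = planted
        sources[clone_id] = source
        flipped[clone_id] = flip

    truth = TruthTable(
        events=events,
        sources=sources,
        flipped=flipped,
        seed=seed,
        params={
            "n": n,
            "contaminant_fraction": contaminant_fraction,
            "flip_fraction": flip_fraction,
            "sub_matrix": np.asarray(model.sub_matrix).tolist(),
            "ins_rate": model.ins_rate,
            "del_rate": model.del_rate,
            "design": design.name,
        },
    )
    return records, truth
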