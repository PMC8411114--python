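"""From phosphosite rows to phospho-events.

A *phospho-event* is the unit of all downstream statistics: one
(protein, position, residue, multiplicity) combination carrying a
per-sample intensity vector.  Site rows are first cleaned of decoy and
contaminant hits, restricted to class-I localization (probability strictly
above 0.75 by default), and then expanded so that each populated
multiplicity slot of a row becomes its own event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MULTIPLICITY_SLOTS, SampleDesign, SiteRecord

logger = logging.getLogger(__name__)

EventKey = tuple[str, int, str, int]  # (protein, position, residue, multiplicity)

CLASS1_THRESHOLD = 0.75


@dataclass
class PhosphoEvent:
    """One (protein, position, residue, multiplicity) quantification unit."""

    protein: str
    position: int
    residue: str
    multiplicity: int
    gene_name: str
    localization_prob: float
    #: sample_id -> raw intensity (log2 is applied downstream); absent == missing
    intensity: dict[str, float]
    source_row: int = -1

    @property
    def key(self) -> EventKey:
        return (self.protein, self.position, self.residue, self.multiplicity)


@dataclass
class FilterReport:
    """Counts removed / retained by the record-level filters."""

    n_in: int = 0
    n_out: int = 0
    n_reverse: int = 0
    n_contaminant: int = 0
    n_class1: int = 0
    n_class2: int = 0
    n_class3: int = 0
    extra: dict = field(default_factory=dict)


def filter_quality(records: list[SiteRecord]) -> tuple[list[SiteRecord], FilterReport]:
    """Drop decoy (reverse) and contaminant rows.

    A row carrying both flags is removed once but counted under each
    category.
    """
    report = FilterReport(n_in=len(records))
    kept = []
    for r in records:
        if r.reverse_flag:
            report.n_reverse += 1
        if r.contaminant_flag:
            report.n_contaminant += 1
        if not (r.reverse_flag or r.contaminant_flag):
            kept.append(r)
    report.n_out = len(kept)
    return kept, report


def filter_class1(
    records: list[SiteRecord], threshold: float = CLASS1_THRESHOLD
) -> tuple[list[SiteRecord], FilterReport]:
    """Keep sites whose localization probability is strictly greater than
    ``threshold`` (class I).  Class II (0.5-0.75) and class III (<0.5)
    tallies are reported for the localization-quality breakdown."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    report = FilterReport(n_in=len(records))
    kept = []
    for r in records:
        if r.localization_prob > threshold:
            report.n_class1 += 1
            kept.append(r)
        elif r.localization_prob >= 0.5:
            report.n_class2 += 1
        else:
            report.n_class3 += 1
    report.n_out = len(kept)
    return kept, report


def expand_multiplicity(records: list[SiteRecord]) -> list[PhosphoEvent]:
    """Expand each site row into one event per populated multiplicity slot.

    A slot is populated when at least one sample has a quantified intensity
    in it; never-quantified slots produce no event.  Duplicate resulting
    keys (redundant source rows) are kept, with a warning.
    """
    events: list[PhosphoEvent] = []
    seen: set[EventKey] = set()
    for r in records:
        for k in MULTIPLICITY_SLOTS:
            intensity = {
                sid: val for (sid, slot), val in r.intensities.items() if slot == k
            }
            if not intensity:
                continue
            ev = PhosphoEvent(
                protein=r.protein,
                position=r.position,
                residue=r.residue,
                multiplicity=k,
                gene_name=r.gene_name,
                localization_prob=r.localization_prob,
                intensity=intensity,
                source_row=r.source_row,
            )
            if ev.key in seen:
                logger.warning("duplicate phospho-event key %s (redundant source rows)", ev.key)
            seen.add(ev.key)
            events.append(ev)
    return events


def events_to_frame(events: list[PhosphoEvent], design: list[SampleDesign]) -> pd.DataFrame:
    """The canonical event table: rows = event keys, columns = sample ids,
    values = raw intensity (NaN for missing)."""
    sample_order = [d.sample_id for d in design]
    index = pd.MultiIndex.from_tuples(
        [e.key for e in events], names=["protein", "position", "residue", "multiplicity"]
    )
    mat = np.full((len(events), len(sample_order)), np.nan)
    col_pos = {sid: j for j, sid in enumerate(sample_order)}
    for i, e in enumerate(events):
        for sid, val in e.intensity.items():
            j = col_pos.get(sid)
            if j is not None:
                mat[i, j] = val
    return pd.DataFrame(mat, index=index, columns=sample_order)


def event_genes(events: list[PhosphoEvent]) -> pd.Series:
    """Gene symbol per event key (for kinase-substrate and gene-set joins)."""
    index = pd.MultiIndex.from_tuples(
        [e.key for e in events], names=["protein", "position", "residue", "multiplicity"]
    )
    return pd.Series([e.gene_name for e in events], index=index, name="gene_name")
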