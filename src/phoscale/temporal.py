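"""Temporal and reciprocity classification of regulated phospho-events.

Per treatment, each event gets a *significance signature* — the boolean
triple of regulated flags at 5 min, 15 min and 24 h — which is mapped to a
temporal class:

* ``persistent``: significant at all three time points;
* ``early``: signatures confined to (or anchored at) the early time
  points — (1,0,0), (0,1,0), (1,1,0);
* ``late``: (0,0,1), (0,1,1), (1,0,1);
* ``none``: never significant.

The mapping is fully configurable; the shipped ``expanded_persistent``
preset moves (0,1,1) into the persistent class (events regulated at 15 min
and 24 h but not 5 min).  Events that are in the same temporal phase under
both opposing treatments form the cross-treatment overlap; an overlap
event is *reciprocal* when its fold-change direction differs between the
treatments (up in one, down in the other, neither mixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError
from .io import TIMEPOINTS

Signature = tuple[int, int, int]

DEFAULT_MAPPING: dict[Signature, str] = {
    (0, 0, 0): "none",
    (1, 0, 0): "early",
    (0, 1, 0): "early",
    (1, 1, 0): "early",
    (0, 0, 1): "late",
    (0, 1, 1): "late",
    (1, 0, 1): "late",
    (1, 1, 1): "persistent",
}

#: signature -> class presets; "expanded_persistent" treats events regulated
#: at 15 min and 24 h (but not 5 min) as persistent.
PRESETS: dict[str, dict[Signature, str]] = {
    "default": DEFAULT_MAPPING,
    "expanded_persistent": {**DEFAULT_MAPPING, (0, 1, 1): "persistent"},
}

PHASES = ("early", "late", "persistent")


@dataclass
class ReciprocitySummary:
    phase: str
    n_overlap: int
    n_reciprocal: int

    @property
    def pct_reciprocal(self) -> float:
        return 100.0 * self.n_reciprocal / self.n_overlap if self.n_overlap else float("nan")


def _validate_mapping(mapping: dict[Signature, str]) -> None:
    need = {(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)}
    if set(mapping) != need:
        missing = need - set(mapping)
        raise ConfigError(f"signature mapping is not total; missing {sorted(missing)}")
    if mapping[(1, 1, 1)] != "persistent" or mapping[(0, 0, 0)] != "none":
        raise ConfigError("mapping must send (1,1,1) to 'persistent' and (0,0,0) to 'none'")


def significance_signature(
    diff_tables: dict[tuple[str, str], pd.DataFrame], treatment: str
) -> pd.DataFrame:
    """Per-event signature over the treatment's three time points.

    ``diff_tables`` maps (treatment, timepoint) to a differential table.
    An event absent from (or untestable at) a timepoint gets signature bit
    0 there, with the corresponding ``untested_*`` annotation set.
    """
    tables = {}
    for tp in TIMEPOINTS:
        if (treatment, tp) not in diff_tables:
            raise ConfigError(f"missing differential table for ({treatment}, {tp})")
        tables[tp] = diff_tables[(treatment, tp)]
    all_keys = sorted(set().union(*(set(t.index) for t in tables.values())))
    index = pd.MultiIndex.from_tuples(all_keys, names=tables[TIMEPOINTS[0]].index.names)
    out = pd.DataFrame(index=index)
    for i, tp in enumerate(TIMEPOINTS):
        t = tables[tp]
        tested = t.index[~t["untestable"]]
        regulated = t.index[t["regulated"].astype(bool)]
        out[f"sig_{tp}"] = out.index.isin(regulated).astype(int)
        out[f"untested_{tp}"] = ~out.index.isin(tested)
        out[f"log2fc_{tp}"] = t["log2fc"].reindex(out.index)
    return out


def classify_temporal(signature: Signature, mapping: dict[Signature, str] | str = "default") -> str:
    """Map one signature to its temporal class."""
    if isinstance(mapping, str):
        try:
            mapping = PRESETS[mapping]
        except KeyError:
            raise ConfigError(f"unknown temporal preset {mapping!r}") from None
    _validate_mapping(mapping)
    return mapping[tuple(int(bool(b)) for b in signature)]


def _direction(log2fcs: list[float]) -> str:
    """Common sign of the significant timepoints' fold changes."""
    signs = {1 if x >= 0 else -1 for x in log2fcs}
    if signs == {1}:
        return "up"
    if signs == {-1}:
        return "down"
    return "mixed"


def temporal_calls(
    diff_tables: dict[tuple[str, str], pd.DataFrame],
    treatment: str,
    mapping: dict[Signature, str] | str = "default",
) -> pd.DataFrame:
    """Signature, temporal class and direction for every event of one
    treatment."""
    if isinstance(mapping, str):
        try:
            mapping = PRESETS[mapping]
        except KeyError:
            raise ConfigError(f"unknown temporal preset {mapping!r}") from None
    _validate_mapping(mapping)
    sig = significance_signature(diff_tables, treatment)
    classes = []
    directions = []
    for _, row in sig.iterrows():
        s = tuple(int(row[f"sig_{tp}"]) for tp in TIMEPOINTS)
        classes.append(mapping[s])
        fcs = [row[f"log2fc_{tp}"] for i, tp in enumerate(TIMEPOINTS) if s[i]]
        directions.append(_direction(fcs) if fcs else "NA")
    sig = sig.copy()
    sig["treatment"] = treatment
    sig["temporal_class"] = classes
    sig["direction"] = directions
    return sig


def overlap_reciprocity(
    calls_bic: pd.DataFrame, calls_ttx: pd.DataFrame
) -> tuple[pd.DataFrame, list[ReciprocitySummary]]:
    """Cross-treatment overlap per phase and reciprocity of each overlap
    event.

    Returns the per-event table (phase, directions, reciprocal flag) and
    per-phase summaries (overlap count, reciprocal count / percentage).
    """
    rows = []
    summaries = []
    for phase in PHASES:
        keys_b = set(calls_bic.index[calls_bic["temporal_class"] == phase])
        keys_t = set(calls_ttx.index[calls_ttx["temporal_class"] == phase])
        overlap = sorted(keys_b & keys_t)
        n_rec = 0
        for key in overlap:
            db = calls_bic.loc[key, "direction"]
            dt = calls_ttx.loc[key, "direction"]
            reciprocal = (
                db in ("up", "down") and dt in ("up", "down") and db != dt
            )
            n_rec += reciprocal
            rows.append(
                {
                    "key": key,
                    "phase": phase,
                    "direction_bic": db,
                    "direction_ttx": dt,
                    "reciprocal": reciprocal,
                }
            )
        summaries.append(ReciprocitySummary(phase=phase, n_overlap=len(overlap), n_reciprocal=n_rec))
    table = pd.DataFrame(rows, columns=["key", "phase", "direction_bic", "direction_ttx", "reciprocal"])
    return table, summaries


def select_k_of_6(
    diff_tables: dict[tuple[str, str], pd.DataFrame], k: int = 4
) -> list:
    """Events regulated in at least ``k`` of the six treated conditions."""
    if not 1 <= k <= 6:
        raise ConfigError(f"k must be in 1..6, got {k}")
    if len(diff_tables) != 6:
        raise ConfigError(f"expected 6 condition tables, got {len(diff_tables)}")
    counts: dict[tuple, int] = {}
    for table in diff_tables.values():
        for key in table.index[table["regulated"].astype(bool)]:
            counts[key] = counts.get(key, 0) + 1
    return sorted(key for key, n in counts.items() if n >= k)


def phospho_protein_overlap(
    phospho_diff: pd.DataFrame, protein_diff: pd.DataFrame
) -> float:
    """Fraction of regulated phospho-events whose protein is also regulated
    at the abundance level in the same condition.

    ``phospho_diff`` is indexed by event keys whose first level is the
    protein accession; ``protein_diff`` by protein accession.
    """
    reg_events = phospho_diff.index[phospho_diff["regulated"].astype(bool)]
    if len(reg_events) == 0:
        return 0.0
    reg_proteins = set(protein_diff.index[protein_diff["regulated"].astype(bool)])
    hits = sum(1 for key in reg_events if key[0] in reg_proteins)
    return hits / len(reg_events)
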