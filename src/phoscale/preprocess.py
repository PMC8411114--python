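"""Normalization, pairwise treatment-control matrices, valid-value
filtering and exclusive-event detection.

The quantitative comparison for a condition ``(treatment, timepoint)`` is
performed on the *pairwise data matrix*: the event-by-sample grid holding
the treated samples of that condition plus the control samples at the same
timepoint (up to 4 biological x 3 technical x 2 arms = 24 columns).

Events enter the statistical test only if they are quantified in every
biological replicate of both arms (in at least one technical replicate)
and if at least half of the designed cells of their row are observed.
Events reliably quantified in exactly one condition and nowhere else are
*exclusive*: reported, never tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, NormalizationError
from .io import TIMEPOINTS, SampleDesign

Condition = tuple[str, str]  # (treatment in {bic, ttx}, timepoint)

#: the six treated conditions of the study design
CONDITIONS: tuple[Condition, ...] = tuple(
    (trt, tp) for trt in ("bic", "ttx") for tp in TIMEPOINTS
)


@dataclass
class PairMatrix:
    """Event x sample grid for one treatment-control comparison."""

    condition: Condition
    #: log2 intensities; rows = event keys, columns = sample ids
    frame: pd.DataFrame
    #: per-column design: arm in {treated, control}, bio_rep, tech_rep
    columns: pd.DataFrame

    @property
    def arms(self) -> np.ndarray:
        return self.columns["arm"].to_numpy()

    @property
    def bio_reps(self) -> np.ndarray:
        return self.columns["bio_rep"].to_numpy()


@dataclass
class ValidValueReport:
    condition: Condition
    n_in: int = 0
    n_out: int = 0
    n_fail_bio_coverage: int = 0  # clause (a): a bio rep x arm with no value
    n_fail_half_valid: int = 0  # clause (b): < 50% of designed cells observed
    n_fail_both: int = 0
    extra: dict = field(default_factory=dict)


def log2_median_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Log2-transform and median-normalize per sample.

    Each sample's median (over its non-missing events) is shifted to the
    grand median (the median of the per-sample medians), so the intensity
    scale is preserved while every sample's median becomes identical.
    """
    if (frame.to_numpy() <= 0).any():
        raise NormalizationError("raw intensities must be strictly positive where present")
    log2 = np.log2(frame)
    medians = log2.median(axis=0, skipna=True)
    empty = medians.index[medians.isna()]
    if len(empty):
        raise NormalizationError(f"samples with zero non-missing values: {list(empty)}")
    grand = float(np.median(medians.to_numpy()))
    return log2 - medians + grand


def build_pair_matrix(
    frame: pd.DataFrame, design: list[SampleDesign], condition: Condition
) -> PairMatrix:
    """Assemble the treatment-control pairwise matrix for one condition.

    Columns are ordered lexicographically by (arm, bio_rep, tech_rep); the
    event (row) order of ``frame`` is preserved.
    """
    treatment, timepoint = condition
    cols = []
    for d in design:
        if d.timepoint != timepoint:
            continue
        if d.treatment == treatment:
            cols.append(("treated", d.bio_rep, d.tech_rep, d.sample_id))
        elif d.treatment == "control":
            cols.append(("control", d.bio_rep, d.tech_rep, d.sample_id))
    if not any(c[0] == "control" for c in cols):
        raise DesignError(f"no control samples at timepoint {timepoint!r}")
    if not any(c[0] == "treated" for c in cols):
        raise DesignError(f"no {treatment!r} samples at timepoint {timepoint!r}")
    cols.sort(key=lambda c: (c[0], c[1], c[2]))
    sample_order = [c[3] for c in cols]
    columns = pd.DataFrame(
        {
            "arm": [c[0] for c in cols],
            "bio_rep": [c[1] for c in cols],
            "tech_rep": [c[2] for c in cols],
        },
        index=pd.Index(sample_order, name="sample_id"),
    )
    return PairMatrix(condition=condition, frame=frame[sample_order], columns=columns)


def _bio_coverage_ok(values: np.ndarray, arm: np.ndarray, bio: np.ndarray) -> np.ndarray:
    """Boolean per event: every (arm, bio rep) group of the matrix has at
    least one observed technical replicate."""
    obs = ~np.isnan(values)
    ok = np.ones(values.shape[0], dtype=bool)
    for a in np.unique(arm):
        for b in np.unique(bio[arm == a]):
            group = (arm == a) & (bio == b)
            ok &= obs[:, group].any(axis=1)
    return ok


def valid_value_filter(matrix: PairMatrix) -> tuple[PairMatrix, ValidValueReport]:
    """Apply the two-stage valid-value filter to a pairwise matrix.

    (a) each biological replicate must carry >= 1 observed technical
        replicate in the treated arm AND in the control arm;
    (b) >= 50% of the event's designed cells must be observed.
    """
    values = matrix.frame.to_numpy()
    arm = matrix.arms
    bio = matrix.bio_reps
    ok_a = _bio_coverage_ok(values, arm, bio)
    frac = (~np.isnan(values)).sum(axis=1) / values.shape[1]
    ok_b = frac >= 0.5
    keep = ok_a & ok_b
    report = ValidValueReport(
        condition=matrix.condition,
        n_in=values.shape[0],
        n_out=int(keep.sum()),
        n_fail_bio_coverage=int((~ok_a).sum()),
        n_fail_half_valid=int((~ok_b).sum()),
        n_fail_both=int((~ok_a & ~ok_b).sum()),
    )
    return (
        PairMatrix(condition=matrix.condition, frame=matrix.frame.loc[keep], columns=matrix.columns),
        report,
    )


def _group_columns(design: list[SampleDesign]) -> dict[tuple[str, str], list[SampleDesign]]:
    groups: dict[tuple[str, str], list[SampleDesign]] = {}
    for d in design:
        groups.setdefault((d.treatment, d.timepoint), []).append(d)
    return groups


def detect_exclusive(
    frame: pd.DataFrame, design: list[SampleDesign], strict: bool = False
) -> list[tuple[tuple, Condition]]:
    """Find events reliably quantified in exactly one treated condition.

    An event is *exclusive* to condition ``c`` iff it is observed in every
    biological replicate of ``c``'s treated samples (>= 1 technical
    replicate each) while every other sample group — the other treated
    conditions and all control groups — fails that all-replicates
    criterion.  With ``strict=True`` the event must additionally have zero
    observations outside ``c``.

    Returns ``(event key, condition)`` pairs.  Exclusive events are meant
    to be excluded from statistical testing and reported separately.
    """
    groups = _group_columns(design)
    obs = ~frame.isna()

    reliable: dict[tuple[str, str], np.ndarray] = {}
    any_obs: dict[tuple[str, str], np.ndarray] = {}
    for g, members in groups.items():
        ok = np.ones(len(frame), dtype=bool)
        bio_reps = sorted({d.bio_rep for d in members})
        for b in bio_reps:
            cols = [d.sample_id for d in members if d.bio_rep == b]
            ok &= obs[cols].any(axis=1).to_numpy()
        reliable[g] = ok
        any_obs[g] = obs[[d.sample_id for d in members]].any(axis=1).to_numpy()

    out: list[tuple[tuple, Condition]] = []
    treated = [g for g in groups if g[0] != "control"]
    for c in treated:
        others = [g for g in groups if g != c]
        elsewhere_reliable = np.zeros(len(frame), dtype=bool)
        elsewhere_any = np.zeros(len(frame), dtype=bool)
        for g in others:
            elsewhere_reliable |= reliable[g]
            elsewhere_any |= any_obs[g]
        if strict:
            mask = reliable[c] & ~elsewhere_any
        else:
            mask = reliable[c] & ~elsewhere_reliable
        for key in frame.index[mask]:
            out.append((key, c))
    return out
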