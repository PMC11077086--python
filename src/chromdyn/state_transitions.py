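"""Combinatorial chromatin-state calling and transition-group assignment.

Each region at each time point receives exactly one of eight states from the
four histone marks on the normalized (z of log2 RPKM+1) layer:

========  =================  =============================================
label     name               mark pattern
========  =================  =============================================
Ea        active enhancer    H3K4me1 >= Q1, H3K27ac >= Q1, H3K27me3 < Q1
Ep        primed enhancer    H3K4me1 >= Q1, H3K27ac < Q1, H3K27me3 < Q1
Er        repressed enh.     H3K4me1 >= Q1, H3K27me3 >= Q1, H3K27ac < Q1
Epr       poised enhancer    H3K4me1 >= Q1, H3K27ac >= Q1, H3K27me3 >= Q1
Pa        active promoter    H3K4me3 > 1, H3K27me3 < Q1
BiV       bivalent promoter  H3K4me3 > 1, H3K27me3 >= Q1
Ps        silent promoter    H3K4me1 < Q1, H3K27me3 >= Q1, H3K27ac < Q1
U         unmarked           everything below threshold
========  =================  =============================================

The promoter branch (H3K4me3 > 1) takes precedence regardless of H3K4me1,
which commonly flanks promoters.  Q1 thresholds are the 25th percentile of
each mark's values pooled over all regions and time points; the H3K4me3
border is fixed at 1.0 normalized units.  Transition groups compare the
state at the first time point with a reference time point: A = {Ea, Pa},
Ia = {Ep, Er, Epr, BiV, Ps}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .peak_annotation import EnrichmentMatrix

STATES = ("Ea", "Ep", "Er", "Epr", "Pa", "BiV", "Ps", "U")
ACTIVE_STATES = frozenset({"Ea", "Pa"})
INACTIVE_STATES = frozenset({"Ep", "Er", "Epr", "BiV", "Ps"})
TRANSITION_GROUPS = ("A_Ia", "Ia_A", "U_Ea", "U_Ia", "U_Pa", "static")

H3K4ME3_BORDER = 1.0
Q1_MARKS = ("H3K4me1", "H3K27ac", "H3K27me3")


@dataclass(frozen=True)
class StateThresholds:
    """Per-mark Q1 thresholds on the normalized layer plus the fixed
    H3K4me3 border.  ``degenerate`` lists marks whose pooled values were
    all equal (threshold meaningless)."""

    q1: Mapping[str, float]
    h3k4me3_border: float = H3K4ME3_BORDER
    degenerate: tuple[str, ...] = ()


def compute_thresholds(enrichment: EnrichmentMatrix) -> StateThresholds:
    """Q1 = 25th percentile (linear interpolation) of each Q1-mark's values
    pooled across all regions and time points."""
    if enrichment.norm.empty:
        raise ValueError("empty enrichment matrix")
    q1: dict[str, float] = {}
    degenerate: list[str] = []
    for mark in Q1_MARKS:
        pool = enrichment.mark_profile(mark).to_numpy().ravel()
        pool = pool[np.isfinite(pool)]
        if pool.size == 0:
            raise ValueError(f"no finite values for mark {mark}")
        q1[mark] = float(np.quantile(pool, 0.25))
        if np.ptp(pool) == 0.0:
            degenerate.append(mark)
    return StateThresholds(q1=q1, degenerate=tuple(degenerate))


def call_state(z: Mapping[str, float], thresholds: StateThresholds) -> str:
    """Decision table mapping the four mark z-scores to one state label.

    Total and deterministic: marked means value >= Q1, unmarked means
    value < Q1; the promoter branch triggers on H3K4me3 > border.  The one
    corner not fixed by the published rules (no H3K4me1, H3K27ac >= Q1,
    H3K4me3 <= border) is resolved to U — acetylation without H3K4me1 or
    H3K4me3 does not define an element here.  Kept in one function so the
    taxonomy can be amended in a single place.
    """
    for mark in ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3"):
        if mark not in z or z[mark] is None or not np.isfinite(z[mark]):
            raise ValueError(f"missing or non-finite value for mark {mark}")
    k4me1 = z["H3K4me1"] >= thresholds.q1["H3K4me1"]
    k27ac = z["H3K27ac"] >= thresholds.q1["H3K27ac"]
    k27me3 = z["H3K27me3"] >= thresholds.q1["H3K27me3"]
    promoter = z["H3K4me3"] > thresholds.h3k4me3_border
    if promoter:
        return "BiV" if k27me3 else "Pa"
    if k4me1:
        if k27ac and k27me3:
            return "Epr"
        if k27ac:
            return "Ea"
        if k27me3:
            return "Er"
        return "Ep"
    if k27me3 and not k27ac:
        return "Ps"
    return "U"


def call_states(
    enrichment: EnrichmentMatrix, thresholds: StateThresholds | None = None
) -> pd.DataFrame:
    """State label per region (rows) per time point (columns)."""
    if thresholds is None:
        thresholds = compute_thresholds(enrichment)
    profiles = {m: enrichment.mark_profile(m) for m in enrichment.marks}
    q1 = thresholds.q1
    out = {}
    for tp in enrichment.timepoints:
        k4me1 = profiles["H3K4me1"][tp].to_numpy() >= q1["H3K4me1"]
        k27ac = profiles["H3K27ac"][tp].to_numpy() >= q1["H3K27ac"]
        k27me3 = profiles["H3K27me3"][tp].to_numpy() >= q1["H3K27me3"]
        promoter = profiles["H3K4me3"][tp].to_numpy() > thresholds.h3k4me3_border
        labels = np.full(len(enrichment.region_ids), "U", dtype=object)
        labels[k4me1 & ~k27ac & ~k27me3] = "Ep"
        labels[k4me1 & k27ac & ~k27me3] = "Ea"
        labels[k4me1 & ~k27ac & k27me3] = "Er"
        labels[k4me1 & k27ac & k27me3] = "Epr"
        labels[~k4me1 & ~k27ac & k27me3] = "Ps"
        labels[promoter & ~k27me3] = "Pa"
        labels[promoter & k27me3] = "BiV"
        out[tp] = labels
    df = pd.DataFrame(out, index=enrichment.region_ids)
    df.index.name = "region_id"
    return df


def assign_transition_group(state_t0: str, state_ref: str) -> str:
    """Map a (baseline state, reference state) pair to its transition group."""
    for s in (state_t0, state_ref):
        if s not in STATES:
            raise ValueError(f"unknown state {s!r}")
    if state_t0 in ACTIVE_STATES and state_ref in INACTIVE_STATES:
        return "A_Ia"
    if state_t0 in INACTIVE_STATES and state_ref in ACTIVE_STATES:
        return "Ia_A"
    if state_t0 == "U":
        if state_ref == "Ea":
            return "U_Ea"
        if state_ref == "Pa":
            return "U_Pa"
        if state_ref in INACTIVE_STATES:
            return "U_Ia"
    return "static"


def assign_transition_groups(
    states: pd.DataFrame, reference_timepoint: int
) -> pd.DataFrame:
    """Per-region transition record relative to ``reference_timepoint``.

    The baseline is the first (leftmost) time point column.
    """
    timepoints = list(states.columns)
    if reference_timepoint not in timepoints:
        raise ValueError(
            f"reference timepoint {reference_timepoint} not in {timepoints}"
        )
    t0 = timepoints[0]
    s0 = states[t0]
    sref = states[reference_timepoint]
    groups = [assign_transition_group(a, b) for a, b in zip(s0, sref)]
    return pd.DataFrame(
        {
            "reference_timepoint": reference_timepoint,
            "state_t0": s0,
            "state_ref": sref,
            "group": groups,
        },
        index=states.index,
    )


def transition_frequency_table(
    states: pd.DataFrame, reference_timepoints: list[int] | None = None
) -> pd.DataFrame:
    """Group × reference-timepoint count table (alluvial-plot input).

    Counts in each column sum to the number of regions.
    """
    timepoints = list(states.columns)
    if reference_timepoints is None:
        reference_timepoints = timepoints[1:]
    table = {}
    for ref in reference_timepoints:
        records = assign_transition_groups(states, ref)
        counts = records["group"].value_counts()
        table[ref] = [int(counts.get(g, 0)) for g in TRANSITION_GROUPS]
    out = pd.DataFrame(table, index=list(TRANSITION_GROUPS))
    out.index.name = "group"
    return out
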