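"""Synthetic fixtures with the statistical structure the pipeline assumes.

The state-scenario generator plants a chromatin state per region per time
point, emits RPKM-scale enrichment whose normalized layer carries the
states as well-separated high/low modes, and guarantees that the adaptive
Q1 thresholds land between those modes.  Because Q1 is the pooled 25th
percentile, this requires each Q1-mark's background (low) share of the pool
to sit just below 25%; the generator balances the static-region state mix
to achieve that, which deliberately makes threshold estimation part of the
tested path.  Ideal levels sit 1.5 normalized units either side of the
operative threshold (0 for Q1 marks, 1 for the fixed H3K4me3 border).

All generators take an explicit seed and draw from a single
``numpy.random.default_rng`` stream; identical seeds give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, rankdata

from .io_genomics import MARKS, GenomicInterval, Peak
from .peak_annotation import EnrichmentMatrix

DEFAULT_TIMEPOINTS = (0, 1, 4, 14, 45)
DEFAULT_TRANSITION_SPEC = {
    "A_Ia": 0.05,
    "Ia_A": 0.05,
    "U_Ea": 0.03,
    "U_Ia": 0.03,
    "U_Pa": 0.04,
}

HIGH, LOW = 1.5, -1.5
K4ME3_HIGH, K4ME3_LOW = 2.5, -0.5  # border 1.0 +/- 1.5

# ideal normalized level per state and mark (order: H3K4me1, H3K4me3, H3K27me3, H3K27ac)
STATE_LEVELS: dict[str, dict[str, float]] = {
    "Ea":  {"H3K4me1": HIGH, "H3K4me3": K4ME3_LOW, "H3K27me3": LOW,  "H3K27ac": HIGH},
    "Ep":  {"H3K4me1": HIGH, "H3K4me3": K4ME3_LOW, "H3K27me3": LOW,  "H3K27ac": LOW},
    "Er":  {"H3K4me1": HIGH, "H3K4me3": K4ME3_LOW, "H3K27me3": HIGH, "H3K27ac": LOW},
    "Epr": {"H3K4me1": HIGH, "H3K4me3": K4ME3_LOW, "H3K27me3": HIGH, "H3K27ac": HIGH},
    "Pa":  {"H3K4me1": HIGH, "H3K4me3": K4ME3_HIGH, "H3K27me3": LOW, "H3K27ac": HIGH},
    "BiV": {"H3K4me1": HIGH, "H3K4me3": K4ME3_HIGH, "H3K27me3": HIGH, "H3K27ac": LOW},
    "Ps":  {"H3K4me1": LOW,  "H3K4me3": K4ME3_LOW, "H3K27me3": HIGH, "H3K27ac": LOW},
    "U":   {"H3K4me1": LOW,  "H3K4me3": K4ME3_LOW, "H3K27me3": LOW,  "H3K27ac": LOW},
}

# representative (baseline, reference) state pairs per transition group;
# inactive endpoints lean on Epr so the mark pools stay signal-dominated
TRANSITION_REPRESENTATIVES: dict[str, tuple[tuple[str, str], ...]] = {
    "A_Ia": (("Ea", "Epr"), ("Pa", "Epr")),
    "Ia_A": (("Epr", "Ea"), ("Epr", "Pa")),
    "U_Ea": (("U", "Ea"),),
    "U_Ia": (("U", "Epr"), ("U", "Ps")),
    "U_Pa": (("U", "Pa"),),
}

TARGET_LOW_FRACTION = 0.2475  # per Q1 mark, just under the 25th percentile
TARGET_H3K4ME3_HIGH = 0.15

LOG2_SLOPE, LOG2_OFFSET = 1.5, 4.0  # log2(RPKM+1) = slope*z + offset


@dataclass(frozen=True)
class StateScenario:
    """Specification of a planted chromatin-state time course."""

    n_regions: int = 1000
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    reference_timepoint: int = 1
    transition_spec: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_SPEC)
    )
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        unknown = set(self.transition_spec) - set(TRANSITION_REPRESENTATIVES)
        if unknown:
            raise ValueError(f"unknown transition group(s): {sorted(unknown)}")
        total = sum(self.transition_spec.values())
        if total > 1.0 + 1e-12:
            raise ValueError(f"transition fractions sum to {total} > 1")
        if any(f < 0 for f in self.transition_spec.values()):
            raise ValueError("transition fractions must be >= 0")
        if self.reference_timepoint not in self.timepoints[1:]:
            raise ValueError("reference timepoint must be a non-baseline timepoint")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class StateScenarioResult:
    enrichment: EnrichmentMatrix
    true_states: pd.DataFrame  # region × timepoint
    true_groups: pd.Series  # region → transition group
    regions: dict[str, GenomicInterval]
    peaks: dict[tuple[str, int], list[Peak]]
    spec: StateScenario


@dataclass(frozen=True)
class EnsembleSpec:
    """Planted co-occurring motif ensembles in a region × motif hit matrix."""

    n_regions: int
    n_motifs: int
    ensembles: tuple[tuple[tuple[int, ...], tuple[int, ...], float], ...]
    p_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_motifs <= 0:
            raise ValueError("n_motifs must be > 0")
        if self.n_regions <= 0:
            raise ValueError("n_regions must be > 0")
        if not (0.0 <= self.p_out <= 1.0):
            raise ValueError("p_out must be in [0, 1]")
        for motifs, regions, p_in in self.ensembles:
            if not motifs or not regions:
                raise ValueError("ensemble motif/region subsets must be non-empty")
            if p_in <= self.p_out:
                raise ValueError(f"p_in={p_in} must exceed p_out={self.p_out}")


def _largest_remainder_counts(fractions: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = int(round(sum(raw))) - sum(counts)
    order = np.argsort([-(r - c) for r, c in zip(raw, counts)], kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return counts


def _plan_states(spec: StateScenario) -> tuple[list[tuple[str, str]], list[str]]:
    """Per-region (baseline, reference) state pair and true group labels.

    Transition regions get representative pairs; the static remainder is a
    solved mix of constant states (Epr / U / Ps / Ea / Pa) that places each
    Q1 mark's pooled low fraction at TARGET_LOW_FRACTION and the H3K4me3-high
    fraction near TARGET_H3K4ME3_HIGH, then a trim pass converts surplus
    low-contributing regions to Epr so no Q1 mark reaches 25% low.
    """
    n, T = spec.n_regions, len(spec.timepoints)
    ref_idx = spec.timepoints.index(spec.reference_timepoint)
    groups = list(TRANSITION_REPRESENTATIVES)
    counts = _largest_remainder_counts(
        [spec.transition_spec.get(g, 0.0) for g in groups], n
    )
    pairs: list[tuple[str, str]] = []
    labels: list[str] = []
    for g, c in zip(groups, counts):
        reps = TRANSITION_REPRESENTATIVES[g]
        per = _largest_remainder_counts([1 / len(reps)] * len(reps), c)
        for rep, k in zip(reps, per):
            pairs.extend([rep] * k)
        labels.extend([g] * c)
    n_static = n - len(pairs)

    # minority-state flavour so every state occurs somewhere in larger runs
    flavour: list[tuple[str, str]] = []
    if n_static >= 60:
        flavour = [("Er", "Er")] * 2 + [("Ep", "Ep")] * 2 + [("BiV", "BiV")] * 2
    n_fill = n_static - len(flavour)

    def low_counts(pairs_list: list[tuple[str, str]]) -> np.ndarray:
        """Entries below threshold per mark [K4me1, K27ac, K27me3] + K4me3-high."""
        out = np.zeros(4)
        for s0, s1 in pairs_list:
            for t in range(T):
                s = s0 if t < ref_idx else s1
                lv = STATE_LEVELS[s]
                out[0] += lv["H3K4me1"] < 0
                out[1] += lv["H3K27ac"] < 0
                out[2] += lv["H3K27me3"] < 0
                out[3] += lv["H3K4me3"] > 1
        return out

    committed = low_counts(pairs + flavour)
    n_entries = n * T
    t1, t2, t3 = (TARGET_LOW_FRACTION * n_entries - committed[i] for i in range(3))
    t4 = TARGET_H3K4ME3_HIGH * n_entries - committed[3]

    n_pa = int(np.clip(round(t4 / T), 0, n_fill))
    # Pa is also K3K27me3-low; cap it so the K27me3 budget is not overshot
    l3_budget = int(np.clip(round(t3 / T), 0, None))
    n_pa = min(n_pa, l3_budget)
    s_low = int(np.clip(round(min(t1, t2) / T), 0, n_fill - n_pa))
    want_l3 = int(np.clip(l3_budget - n_pa, 0, None))
    n_u = min(s_low, want_l3)
    n_ps = s_low - n_u
    n_ea = int(np.clip(want_l3 - n_u, 0, n_fill - n_pa - s_low))
    n_epr = n_fill - n_pa - s_low - n_ea
    if n_epr < 0:  # infeasible request; shed in fixed order (best effort)
        deficit = -n_epr
        for _ in range(1):
            take = min(deficit, n_ea); n_ea -= take; deficit -= take
            take = min(deficit, n_ps); n_ps -= take; deficit -= take
            take = min(deficit, n_u); n_u -= take; deficit -= take
            take = min(deficit, n_pa); n_pa -= take; deficit -= take
        n_epr = max(n_fill - n_pa - n_u - n_ps - n_ea, 0)

    static_pairs = (
        [("Epr", "Epr")] * n_epr
        + [("U", "U")] * n_u
        + [("Ps", "Ps")] * n_ps
        + [("Ea", "Ea")] * n_ea
        + [("Pa", "Pa")] * n_pa
    )
    all_pairs = pairs + flavour + static_pairs
    all_labels = labels + ["static"] * (len(flavour) + len(static_pairs))

    # trim: no Q1 mark may reach a 25% low share of the pool.  Convert one
    # static region that carries the offending mark low to Epr per pass.
    limit = TARGET_LOW_FRACTION * n_entries + 1e-9
    donors_by_mark = {
        0: (("U", "U"), ("Ps", "Ps")),          # H3K4me1 low
        1: (("U", "U"), ("Ps", "Ps")),          # H3K27ac low
        2: (("Ea", "Ea"), ("U", "U"), ("Pa", "Pa")),  # H3K27me3 low
    }
    for _ in range(n):
        lows = low_counts(all_pairs)
        over = [m for m in range(3) if lows[m] > limit]
        if not over:
            break
        swapped = False
        for donor in donors_by_mark[over[0]]:
            for idx in range(len(all_pairs) - 1, -1, -1):
                if all_pairs[idx] == donor and all_labels[idx] == "static":
                    all_pairs[idx] = ("Epr", "Epr")
                    swapped = True
                    break
            if swapped:
                break
        if not swapped:
            break
    return all_pairs, all_labels


def generate_state_scenario(spec: StateScenario) -> StateScenarioResult:
    """Materialize a planted scenario: enrichment, truth and per-mark peaks."""
    rng = np.random.default_rng(spec.seed)
    n, tps = spec.n_regions, spec.timepoints
    ref_idx = tps.index(spec.reference_timepoint)
    pairs, labels = _plan_states(spec)

    region_ids = [f"region_{i:05d}" for i in range(n)]
    state_matrix = pd.DataFrame(
        [[s0 if t < ref_idx else s1 for t in range(len(tps))] for s0, s1 in pairs],
        index=region_ids,
        columns=list(tps),
    )
    state_matrix.index.name = "region_id"

    raw_cols: dict[str, np.ndarray] = {}
    for mark in MARKS:
        for tp in tps:
            ideal = np.array(
                [STATE_LEVELS[s][mark] for s in state_matrix[tp]], dtype=float
            )
            z = ideal + rng.normal(0.0, spec.noise_sigma, size=n) if spec.noise_sigma > 0 else ideal
            raw = np.maximum(np.exp2(LOG2_SLOPE * z + LOG2_OFFSET) - 1.0, 0.0)
            raw_cols[f"{mark}_{tp}"] = raw
    raw_df = pd.DataFrame(raw_cols, index=region_ids)
    raw_df.index.name = "region_id"
    enrichment = EnrichmentMatrix.from_raw(raw_df, MARKS, tps)

    widths = generate_peak_widths(n, broad_fraction=0.5, seed=int(rng.integers(2**31)))
    regions: dict[str, GenomicInterval] = {}
    pos = 10_000
    for rid, w in zip(region_ids, widths):
        regions[rid] = GenomicInterval("chrS", pos, pos + int(w))
        pos += int(w) + 20_000

    peaks: dict[tuple[str, int], list[Peak]] = {}
    for mark in MARKS:
        threshold = 1.0 if mark == "H3K4me3" else 0.0
        for tp in tps:
            lst = [
                Peak(regions[rid], mark, tp, name=rid)
                for rid in region_ids
                if STATE_LEVELS[state_matrix.at[rid, tp]][mark] > threshold
            ]
            peaks[(mark, tp)] = lst

    return StateScenarioResult(
        enrichment=enrichment,
        true_states=state_matrix,
        true_groups=pd.Series(labels, index=region_ids, name="group"),
        regions=regions,
        peaks=peaks,
        spec=spec,
    )


def generate_expression(
    result: StateScenarioResult | EnrichmentMatrix,
    rho_target: float,
    seed: int,
    mark: str = "H3K27ac",
    correlated_mask: pd.Series | None = None,
    uncorrelated_mode: str = "noise",
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression across time points rank-coupled to one mark's profile.

    Correlated regions are generated through a Gaussian copula on the mark's
    within-region rank profile.  The Pearson coupling r is calibrated so the
    *expected sample* Spearman coefficient at this time-course length equals
    ``rho_target``, using the small-sample expectation for bivariate normal
    data, E[r_s] = 6/(pi (n+1)) [arcsin r + (n-2) arcsin(r/2)] — at n = 5
    the naive population coupling would visibly undershoot the target.
    ``rho_target = +/-1`` reproduces/reverses the mark's ranks exactly.
    Regions outside ``correlated_mask`` (default: all correlated) get
    independent profiles (``uncorrelated_mode='noise'``) or flat profiles
    whose rank correlation is undefined (``'constant'`` — useful for
    noiseless fixed-point checks where the uncorrelated class must be
    deterministic).  Returns (RPKM-scale expression, true class).
    """
    if abs(rho_target) > 1:
        raise ValueError("|rho_target| must be <= 1")
    enrichment = result.enrichment if isinstance(result, StateScenarioResult) else result
    profile = enrichment.mark_profile(mark)
    rng = np.random.default_rng(seed)
    n, T = profile.shape
    if correlated_mask is None:
        mask = np.ones(n, dtype=bool)
    else:
        mask = correlated_mask.reindex(profile.index).fillna(False).to_numpy(dtype=bool)
    if rho_target == 0:
        r = 0.0
    elif abs(rho_target) == 1.0:
        r = float(np.sign(rho_target))  # exact limit: pure rank copy/reversal
    else:
        def expected_sample_spearman(r_: float) -> float:
            return (
                6.0 / (np.pi * (T + 1))
                * (np.arcsin(r_) + (T - 2) * np.arcsin(r_ / 2.0))
            )

        r = float(
            np.sign(rho_target)
            * brentq(
                lambda r_: expected_sample_spearman(r_) - abs(rho_target),
                0.0,
                1.0 - 1e-12,
            )
        )

    x = profile.to_numpy(dtype=float)
    ranks = np.vstack([rankdata(row) for row in x])
    nscores = norm.ppf(ranks / (T + 1))
    eps = rng.standard_normal((n, T))
    if uncorrelated_mode == "constant":
        background = np.zeros((n, T))
    elif uncorrelated_mode == "noise":
        background = eps
    else:
        raise ValueError(f"unknown uncorrelated_mode {uncorrelated_mode!r}")
    y = np.where(
        mask[:, None],
        r * nscores + np.sqrt(max(0.0, 1.0 - r * r)) * eps,
        background,
    )
    expr = np.exp2(LOG2_SLOPE * y + LOG2_OFFSET)
    expr_df = pd.DataFrame(expr, index=profile.index, columns=profile.columns)
    cls = np.where(
        ~mask, "none", "positive" if rho_target >= 0.3 else ("negative" if rho_target <= -0.3 else "none")
    )
    return expr_df, pd.Series(cls, index=profile.index, name="true_class")


def generate_motif_matrix(spec: EnsembleSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Bernoulli region × motif hit matrix with planted co-occurrence blocks.

    p_in inside each (ensemble regions × ensemble motifs) block, p_out
    elsewhere.  Returns the binary matrix and per-region true ensemble label
    (-1 for background regions).
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.full((spec.n_regions, spec.n_motifs), spec.p_out)
    labels = np.full(spec.n_regions, -1)
    for k, (motifs, regions, p_in) in enumerate(spec.ensembles):
        motifs_a, regions_a = np.asarray(motifs), np.asarray(regions)
        if motifs_a.max() >= spec.n_motifs or regions_a.max() >= spec.n_regions:
            raise ValueError("ensemble indices out of range")
        probs[np.ix_(regions_a, motifs_a)] = p_in
        labels[regions_a] = k
    hits = (rng.random(probs.shape) < probs).astype(int)
    region_ids = [f"region_{i:05d}" for i in range(spec.n_regions)]
    motif_ids = [f"MOTIF{j:03d}" for j in range(spec.n_motifs)]
    matrix = pd.DataFrame(hits, index=region_ids, columns=motif_ids)
    matrix.index.name = "region_id"
    return matrix, pd.Series(labels, index=region_ids, name="true_ensemble")


def make_ensemble_spec(
    n_ensembles: int = 3,
    regions_per_ensemble: int = 50,
    motifs_per_ensemble: int = 8,
    n_background_regions: int = 0,
    n_background_motifs: int = 16,
    p_in: float = 0.9,
    p_out: float = 0.05,
    seed: int = 0,
) -> EnsembleSpec:
    """Convenience builder for block-structured ensemble scenarios."""
    n_regions = n_ensembles * regions_per_ensemble + n_background_regions
    n_motifs = n_ensembles * motifs_per_ensemble + n_background_motifs
    ensembles = []
    for k in range(n_ensembles):
        motifs = tuple(range(k * motifs_per_ensemble, (k + 1) * motifs_per_ensemble))
        regions = tuple(
            range(k * regions_per_ensemble, (k + 1) * regions_per_ensemble)
        )
        ensembles.append((motifs, regions, p_in))
    return EnsembleSpec(
        n_regions=n_regions,
        n_motifs=n_motifs,
        ensembles=tuple(ensembles),
        p_out=p_out,
        seed=seed,
    )


def generate_peak_widths(
    n: int, broad_fraction: float, seed: int
) -> np.ndarray:
    """Two-component peak-width mixture straddling the 500 bp broad/narrow
    boundary: narrow uniform on [100, 480] bp, broad 520 bp + exponential
    (mean 600 bp).  Exactly round(n * broad_fraction) broad widths, order
    shuffled."""
    if not (0.0 <= broad_fraction <= 1.0):
        raise ValueError("broad_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_broad = int(round(n * broad_fraction))
    broad = 520.0 + rng.exponential(600.0, size=n_broad)
    narrow = rng.uniform(100.0, 480.0, size=n - n_broad)
    widths = np.concatenate([broad, narrow])
    rng.shuffle(widths)
    return np.round(widths).astype(int)


__all__ = [
    "StateScenario",
    "StateScenarioResult",
    "EnsembleSpec",
    "DEFAULT_TIMEPOINTS",
    "DEFAULT_TRANSITION_SPEC",
    "STATE_LEVELS",
    "generate_state_scenario",
    "generate_expression",
    "generate_motif_matrix",
    "make_ensemble_spec",
    "generate_peak_widths",
]
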