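"""ROSE-style super-enhancer identification.

H3K27ac peaks from one time point are stitched when their gaps are at most
12.5 kb, the stitched regions are ranked by total signal, and the ranked
curve — both axes scaled to [0, 1] — is split where its slope reaches 1
(the tangent point): regions with signal above the cutoff are
super-enhancers (SE), the rest typical enhancers (TYE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genomics import GenomicInterval

STITCH_DISTANCE = 12_500
TSS_EXCLUSION = 0  # ROSE default settings: no promoter exclusion


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: tuple[str, ...]
    signal: float
    rank: int = 0
    is_super: bool = False


def stitch_enhancers(
    peaks: dict[str, GenomicInterval] | list[GenomicInterval],
    signals: pd.Series | None = None,
    stitch_distance: int = STITCH_DISTANCE,
) -> list[StitchedEnhancer]:
    """Chain peaks whose gaps are <= ``stitch_distance`` into stitched
    enhancers; signal is the sum over constituents (0 when no signal table
    given).  Idempotent: re-stitching stitched output changes nothing."""
    if isinstance(peaks, dict):
        items = list(peaks.items())
    else:
        items = [(f"peak_{i}", p) for i, p in enumerate(peaks)]
    items.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end))
    out: list[StitchedEnhancer] = []
    cur: list[tuple[str, GenomicInterval]] = []

    def flush() -> None:
        if not cur:
            return
        ids = tuple(pid for pid, _ in cur)
        chrom = cur[0][1].chrom
        start = min(iv.start for _, iv in cur)
        end = max(iv.end for _, iv in cur)
        signal = float(signals.reindex(list(ids)).fillna(0.0).sum()) if signals is not None else 0.0
        out.append(StitchedEnhancer(GenomicInterval(chrom, start, end), ids, signal))

    for pid, iv in items:
        if cur and iv.chrom == cur[-1][1].chrom and iv.start - max(
            e.end for _, e in cur
        ) <= stitch_distance:
            cur.append((pid, iv))
        else:
            flush()
            cur = [(pid, iv)]
    flush()
    return out


def find_se_cutoff(signals: np.ndarray | pd.Series) -> float:
    """Tangent cutoff on the ascending scaled signal curve.

    Signals are sorted ascending; x = rank scaled to [0, 1], y = signal
    scaled to [0, 1].  The slope is estimated by centered finite differences
    and the cutoff is the y-value at the rightmost point whose slope is
    still <= 1; regions with signal strictly above the cutoff are SE.
    Degenerate inputs (constant or linear curve, slope <= 1 everywhere)
    yield cutoff = max signal, i.e. zero SE.
    """
    vals = np.sort(np.asarray(signals, dtype=float))
    n = vals.size
    if n < 3:
        raise ValueError("need >= 3 stitched regions")
    vmax = vals[-1]
    if vmax <= 0 or np.ptp(vals) == 0.0:
        return float(vmax)  # degenerate: zero SE
    x = np.arange(n) / (n - 1)
    y = vals / vmax
    slope = np.gradient(y, x)
    below = np.nonzero(slope <= 1.0 + 1e-12)[0]
    if below.size == 0:
        return float(vals[0])  # whole curve steeper than 1: all but min are SE
    return float(vals[below[-1]])


def rank_enhancers(stitched: list[StitchedEnhancer]) -> pd.DataFrame:
    """Rank stitched enhancers by signal (1 = highest) and split SE/TYE at
    the tangent cutoff.  SE minimum signal >= TYE maximum by construction."""
    signals = np.array([s.signal for s in stitched])
    cutoff = find_se_cutoff(signals)
    order = np.argsort(-signals, kind="stable")
    rows = []
    for rank, i in enumerate(order, start=1):
        s = stitched[i]
        s.rank = rank
        s.is_super = bool(s.signal > cutoff)
        rows.append(
            {
                "enhancer_id": f"stitched_{i:05d}",
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "n_constituents": len(s.constituents),
                "constituents": ",".join(s.constituents),
                "signal": s.signal,
                "rank": rank,
                "is_super": s.is_super,
            }
        )
    df = pd.DataFrame(rows).set_index("enhancer_id")
    df.attrs["cutoff"] = cutoff
    return df


def se_fraction_per_cluster(
    assignments: pd.Series, se_calls: pd.Series
) -> pd.DataFrame:
    """SE vs TYE fraction per k-means cluster.

    Both inputs are keyed by region id; regions without an SE call are
    excluded from the fractions and reported in ``n_uncalled``.
    """
    joined = pd.DataFrame({"cluster_id": assignments}).join(
        se_calls.rename("is_super"), how="left"
    )
    rows = []
    for cid, sub in joined.groupby("cluster_id"):
        called = sub["is_super"].dropna()
        n = len(called)
        frac_se = float(called.astype(bool).mean()) if n else np.nan
        rows.append(
            {
                "cluster_id": cid,
                "n_called": n,
                "n_uncalled": int(sub["is_super"].isna().sum()),
                "frac_se": frac_se,
                "frac_tye": 1.0 - frac_se if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")
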