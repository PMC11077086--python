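"""TF motif-ensemble discovery from motif co-occurrence (TFinZONE-style).

Regions (typically one chromatin-state transition group) are embedded by
PCA of their binary region × motif hit matrix, connected in a shared-
nearest-neighbor (SNN) graph whose edge weights are Jaccard indices of
k-nearest-neighbor sets, and partitioned by seeded Louvain modularity
optimization (resolution 0.5 by default).  Marker motifs per cluster are
called cluster-vs-rest with a zero-inflated ("bimod") likelihood-ratio
test and detection-rate / fold-change filters; hub TFs are ranked by
weighted degree in a protein-interaction edge list restricted to markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .io_genomics import GenomicInterval

RESOLUTION = 0.5
N_PCS = 10
K_NEIGHBORS = 30
SNN_PRUNE = 1.0 / 15.0
MIN_PCT = 0.10
LOGFC_THRESHOLD = 0.09

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix of base probabilities (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray  # 4 × L
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: matrix must be 4 × L with L >= 4")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """5 × L log2(p/background); the extra row is the N base (0)."""
        lo = np.log2(self.matrix / self.background[:, None])
        return np.vstack([lo, np.zeros(self.length)])

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])


def read_pwms(path: str | Path) -> list[PWM]:
    """Read JASPAR-style PWM text: ``>motif_id`` then four rows A/C/G/T of
    counts or probabilities (brackets optional); counts are normalized."""
    pwms: list[PWM] = []
    name, rows = None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                pwms.append(_pwm_from_rows(name, rows))
            name, rows = line[1:].split()[0], []
        else:
            payload = line.split("[")[-1].rstrip("]").replace("]", "")
            if line[0] in "ACGT" and not line[1].isdigit():
                payload = payload.lstrip("ACGT").strip()
            rows.append([float(x) for x in payload.split()])
    if name is not None:
        pwms.append(_pwm_from_rows(name, rows))
    return pwms


def _pwm_from_rows(name: str, rows: list[list[float]]) -> PWM:
    m = np.asarray(rows, dtype=float)
    if m.shape[0] != 4:
        raise ValueError(f"{name}: expected 4 base rows, got {m.shape[0]}")
    m = m / m.sum(axis=0, keepdims=True)
    return PWM(name, m)


def scan_pwm(
    sequence: str, pwm: PWM, threshold: float
) -> list[tuple[int, str, float]]:
    """Scan both strands; hit when the summed log2 odds >= threshold.

    Positions are 0-based window starts on the forward strand; N bases
    contribute 0 to the score.  A motif longer than the sequence yields no
    hits.
    """
    seq = sequence.upper()
    L = pwm.length
    if L > len(seq):
        return []
    idx = np.fromiter((_BASE_INDEX.get(b, 4) for b in seq), dtype=np.intp, count=len(seq))
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    hits: list[tuple[int, str, float]] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = mat.log_odds()
        scores = lo[windows, np.arange(L)].sum(axis=1)
        for pos in np.nonzero(scores >= threshold)[0]:
            hits.append((int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def scan_regions(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold: float,
) -> pd.DataFrame:
    """Scan all sequences with all PWMs; one row per hit."""
    rows = []
    for rid, seq in sequences.items():
        for pwm in pwms:
            for pos, strand, score in scan_pwm(seq, pwm, threshold):
                rows.append(
                    {"region_id": rid, "motif_id": pwm.motif_id,
                     "position": pos, "strand": strand, "score": score}
                )
    return pd.DataFrame(rows, columns=["region_id", "motif_id", "position", "strand", "score"])


def region_windows(
    regions: Mapping[str, GenomicInterval], size: int = 500
) -> dict[str, GenomicInterval]:
    """Fixed-size windows centered on each region (motif-scanning footprint)."""
    out = {}
    half = size // 2
    for rid, iv in regions.items():
        center = (iv.start + iv.end) // 2
        start = max(0, center - half)
        out[rid] = GenomicInterval(iv.chrom, start, start + size, iv.strand)
    return out


def build_region_motif_matrix(
    hits: pd.DataFrame,
    region_ids: Iterable[str] | None = None,
    motif_ids: Iterable[str] | None = None,
    binary: bool = True,
) -> pd.DataFrame:
    """Region × motif matrix from a hit table (region_id, motif_id, ...).

    Binary presence/absence by default; ``binary=False`` keeps hit counts.
    Supplying ``region_ids`` restricts rows to a transition-group subset
    (rows without hits become all-zero).
    """
    if not {"region_id", "motif_id"} <= set(hits.columns):
        raise ValueError("hits must have region_id and motif_id columns")
    counts = hits.groupby(["region_id", "motif_id"]).size().unstack(fill_value=0)
    if region_ids is not None:
        counts = counts.reindex(list(region_ids), fill_value=0)
    if motif_ids is not None:
        counts = counts.reindex(columns=list(motif_ids), fill_value=0)
    counts.index.name = "region_id"
    if binary:
        counts = (counts > 0).astype(int)
    return counts


# ---------------------------------------------------------------------------
# SNN graph + Louvain
# ---------------------------------------------------------------------------

def embed_and_graph(
    matrix: pd.DataFrame,
    n_pcs: int = N_PCS,
    k_neighbors: int = K_NEIGHBORS,
    prune: float = SNN_PRUNE,
) -> nx.Graph:
    """Shared-nearest-neighbor graph in PCA space.

    The centered matrix is reduced to ``n_pcs`` principal components
    (deterministic full SVD), neighbors are the ``k_neighbors`` nearest
    points including self, and edge weights are Jaccard indices of neighbor
    sets; edges with weight below ``prune`` (default 1/15) are removed.
    """
    n = matrix.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n regions={n}")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    n_pcs = min(n_pcs, min(Xc.shape) - 1) or 1
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    emb = Xc @ vt[:n_pcs].T
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(emb)
    _, nbrs = nn.kneighbors(emb)
    member = np.zeros((n, n), dtype=bool)
    member[np.arange(n)[:, None], nbrs] = True
    inter = member.astype(np.int32) @ member.astype(np.int32).T
    union = 2 * k_neighbors - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jaccard = inter / union
    graph = nx.Graph()
    graph.add_nodes_from(matrix.index)
    ids = list(matrix.index)
    ii, jj = np.nonzero(np.triu(jaccard >= prune, k=1))
    for i, j in zip(ii, jj):
        graph.add_edge(ids[i], ids[j], weight=float(jaccard[i, j]))
    return graph


def louvain_cluster(
    graph: nx.Graph,
    resolution: float = RESOLUTION,
    seed: int = 1,
    n_restarts: int = 10,
) -> pd.Series:
    """Seeded Louvain partition, best modularity over ``n_restarts`` node-
    order shuffles; cluster ids 1..k by descending community size."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    best_part: list[set] | None = None
    best_q = -np.inf
    for _ in range(max(1, n_restarts)):
        sub_seed = int(rng.integers(2**31))
        communities = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=sub_seed
        )
        q = nx.community.modularity(
            graph, communities, weight="weight", resolution=resolution
        )
        if q > best_q:
            best_q = q
            best_part = [set(c) for c in communities]
    assert best_part is not None
    best_part.sort(key=lambda c: (-len(c), sorted(str(x) for x in c)[0]))
    labels = {}
    for cid, comm in enumerate(best_part, start=1):
        for node in comm:
            labels[node] = cid
    out = pd.Series(labels, name="cluster_id").sort_index()
    out.attrs["modularity"] = best_q
    return out


# ---------------------------------------------------------------------------
# bimod likelihood-ratio test and markers
# ---------------------------------------------------------------------------

def _bimod_loglik(x: np.ndarray, xmin: float = 0.0) -> float:
    """Log-likelihood of the zero-inflated model: point mass at/below xmin
    plus a normal for detected values (sd 1 when fewer than two detected or
    degenerate)."""
    x = np.asarray(x, dtype=float)
    detected = x > xmin
    n, n1 = x.size, int(detected.sum())
    alpha = min(max(n1 / n, 1e-5), 1 - 1e-5)
    ll = (n - n1) * np.log(1.0 - alpha) + n1 * np.log(alpha)
    if n1 > 0:
        vals = x[detected]
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n1 >= 2 else 1.0
        if not np.isfinite(sd) or sd == 0.0:
            sd = 1.0
        ll += float(stats.norm.logpdf(vals, mu, sd).sum())
    return float(ll)


def bimod_lr_test(
    values_in: np.ndarray, values_out: np.ndarray, xmin: float = 0.0
) -> tuple[float, float]:
    """Likelihood-ratio test for differential detection/level between two
    groups under the zero-inflated normal model.

    LR = 2 (ll_in + ll_out - ll_pooled) compared to chi-square with 3
    degrees of freedom (detection proportion, mean and sd of the detected
    component).  Identical groups give LR = 0 and p = 1.
    """
    values_in = np.asarray(values_in, dtype=float)
    values_out = np.asarray(values_out, dtype=float)
    if values_in.size == 0 or values_out.size == 0:
        raise ValueError("both groups must be non-empty")
    lr = 2.0 * (
        _bimod_loglik(values_in, xmin)
        + _bimod_loglik(values_out, xmin)
        - _bimod_loglik(np.concatenate([values_in, values_out]), xmin)
    )
    lr = max(lr, 0.0)
    return lr, float(stats.chi2.sf(lr, df=3))


def find_cluster_markers(
    matrix: pd.DataFrame,
    partition: pd.Series,
    min_pct: float = MIN_PCT,
    logfc_threshold: float = LOGFC_THRESHOLD,
    only_pos: bool = True,
    adjust: str = "bonferroni",
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Marker motifs per cluster (cluster-vs-rest bimod test).

    A motif is kept when detected in >= ``min_pct`` of cluster regions and
    its natural-log detection-rate fold change (with pseudocount) is >=
    ``logfc_threshold`` (positive direction when ``only_pos``).  Raw and
    adjusted p-values are both reported (Bonferroni over motifs by default,
    ``adjust='BH'`` for Benjamini-Hochberg).  Singleton clusters are tested
    but flagged ``low_power``.
    """
    partition = partition.reindex(matrix.index).dropna()
    matrix = matrix.loc[partition.index]
    n_motifs = matrix.shape[1]
    rows = []
    for cid in sorted(partition.unique()):
        members = partition.index[partition == cid]
        rest = partition.index[partition != cid]
        low_power = len(members) < 2 or len(rest) < 2
        sub_in = matrix.loc[members]
        sub_out = matrix.loc[rest] if len(rest) else None
        for motif in matrix.columns:
            x_in = sub_in[motif].to_numpy(dtype=float)
            pct_in = float((x_in > 0).mean())
            if pct_in < min_pct:
                continue
            if sub_out is None:
                continue
            x_out = sub_out[motif].to_numpy(dtype=float)
            pct_out = float((x_out > 0).mean())
            log_fc = float(
                np.log((x_in.mean() + pseudocount) / (x_out.mean() + pseudocount))
            )
            if only_pos and log_fc < logfc_threshold:
                continue
            if not only_pos and abs(log_fc) < logfc_threshold:
                continue
            lr, p = bimod_lr_test(x_in, x_out)
            rows.append(
                {
                    "cluster_id": cid,
                    "motif_id": motif,
                    "lr_stat": lr,
                    "p": p,
                    "log_fc": log_fc,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "low_power": low_power,
                }
            )
    markers = pd.DataFrame(
        rows,
        columns=["cluster_id", "motif_id", "lr_stat", "p", "log_fc",
                 "pct_in", "pct_out", "low_power"],
    )
    if len(markers):
        if adjust == "bonferroni":
            markers["p_adj"] = np.minimum(markers["p"] * n_motifs, 1.0)
        elif adjust == "BH":
            markers["p_adj"] = markers.groupby("cluster_id")["p"].transform(
                lambda p: stats.false_discovery_control(p, method="bh")
            )
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        markers = markers.sort_values(
            ["cluster_id", "p", "log_fc"], ascending=[True, True, False]
        ).reset_index(drop=True)
    else:
        markers["p_adj"] = pd.Series(dtype=float)
    return markers


def rank_network_hubs(
    edges: pd.DataFrame,
    marker_tfs: Iterable[str],
    top_fraction: float = 0.1,
    min_weight: float = 0.0,
) -> pd.DataFrame:
    """Rank marker TFs by (weighted) degree in a protein-interaction edge
    list (columns tf_a, tf_b and optional weight; edges outside the marker
    set or below ``min_weight`` are dropped).  Ties break by name; the top
    ``top_fraction`` of TFs with non-zero degree are flagged central."""
    markers = sorted(set(marker_tfs))
    degree = {tf: 0.0 for tf in markers}
    n_int = {tf: 0 for tf in markers}
    if len(edges):
        if not {"tf_a", "tf_b"} <= set(edges.columns):
            raise ValueError("edges must have tf_a and tf_b columns")
        w = edges["weight"] if "weight" in edges.columns else pd.Series(1.0, index=edges.index)
        for (a, b, wt) in zip(edges["tf_a"], edges["tf_b"], w):
            if wt < min_weight or a == b:
                continue
            if a in degree and b in degree:
                degree[a] += float(wt)
                degree[b] += float(wt)
                n_int[a] += 1
                n_int[b] += 1
    out = pd.DataFrame(
        {
            "tf": markers,
            "weighted_degree": [degree[t] for t in markers],
            "n_interactions": [n_int[t] for t in markers],
        }
    ).sort_values(["weighted_degree", "tf"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    n_central = max(1, int(round(top_fraction * len(out)))) if len(out) else 0
    out["central"] = (out["rank"] <= n_central) & (out["weighted_degree"] > 0)
    return out.set_index("tf")


def discover_ensembles(
    matrix: pd.DataFrame,
    n_pcs: int = N_PCS,
    k_neighbors: int = K_NEIGHBORS,
    resolution: float = RESOLUTION,
    seed: int = 1,
    min_pct: float = MIN_PCT,
    logfc_threshold: float = LOGFC_THRESHOLD,
) -> tuple[pd.Series, pd.DataFrame]:
    """End-to-end ensemble discovery: SNN graph, Louvain partition, markers."""
    graph = embed_and_graph(matrix, n_pcs=n_pcs, k_neighbors=k_neighbors)
    partition = louvain_cluster(graph, resolution=resolution, seed=seed)
    markers = find_cluster_markers(
        matrix, partition, min_pct=min_pct, logfc_threshold=logfc_threshold
    )
    return partition, markers
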