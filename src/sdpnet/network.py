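"""Clade-determining positions, corrected mutual information, SDP networks.

Two plug-in mutual-information statistics drive the analysis, both in bits:

* ``clade_mi`` — MI between the residue at one column (gap kept as its own
  symbol, so clade-specific deletions count as signal) and the clade label.
  Columns whose association with the clade partition beats a clade-label
  permutation null after Benjamini-Hochberg correction are
  clade-determining positions (CDPs).
* ``pairwise_mi`` — MI between two columns, background-corrected by the
  average product correction (APC) and standardized against a null in which
  every column's rows are permuted independently (column compositions kept,
  covariation destroyed). Pairs with permutation z-score at or above a
  threshold (default 6.5) form the MI network.

A CDP that is a node of the MI network is a putative specificity-determining
position (pSDP). pSDPs that reach another pSDP through at most ``max_link``
intervening non-pSDP nodes are grouped into specificity-determining
sub-networks (SDNs) and reported as SDPs; a pSDP with no such partner stays
putative, in its own singleton SDN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .clades import CladeAssignment
from .errors import CladeError, SdpnetError
from .msa import AA20, GAP, AlignmentMatrix

DEFAULT_Z_CUT = 6.5
DEFAULT_ALPHA = 0.05
DEFAULT_CDP_PERMUTATIONS = 1000
DEFAULT_Z_PERMUTATIONS = 50
DEFAULT_MAX_LINK = 1

#: symbol codes: 20 amino acids, then gap, then X
_CODE = {aa: i for i, aa in enumerate(AA20)}
_CODE[GAP] = 20
_CODE["X"] = 21
N_SYMBOLS = 22


def encode(msa: AlignmentMatrix, ids: list[str] | None = None) -> np.ndarray:
    """Integer-encode the alignment (rows × columns, codes 0..21)."""
    sub = msa if ids is None else msa.subset(ids)
    lut = np.zeros(128, dtype=np.int64)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    raw = sub.array.view(np.uint32).reshape(sub.n_rows, sub.n_cols)
    return lut[raw]


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in bits from a 2-D contingency table of counts/weights."""
    total = joint.sum()
    if total <= 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * (np.log2(p) - np.log2(px) - np.log2(py))
    return float(np.nansum(t))


# ---------------------------------------------------------------------------
# CDPs: column vs clade label
# ---------------------------------------------------------------------------

def _clade_setup(msa: AlignmentMatrix, clades: CladeAssignment):
    labels = clades.labels
    if len(labels) < 2:
        raise CladeError("CDP analysis needs at least 2 clades")
    ids, y = [], []
    label_index = {lab: i for i, lab in enumerate(labels)}
    for sid in msa.ids:
        lab = clades.assignment.get(sid)
        if lab is not None:
            ids.append(sid)
            y.append(label_index[lab])
    y = np.asarray(y)
    for lab, idx in label_index.items():
        if np.sum(y == idx) < 2:
            raise CladeError(f"clade {lab!r} has fewer than 2 assigned sequences")
    X = encode(msa, ids)
    return X, y, len(labels)


def _clade_mi_all(X: np.ndarray, y: np.ndarray, n_clades: int) -> np.ndarray:
    """MI of every column with the clade label, vectorized (bits)."""
    n, m = X.shape
    joint = np.zeros((m, N_SYMBOLS, n_clades))
    # accumulate contingency tables for all columns at once
    cols = np.broadcast_to(np.arange(m), (n, m))
    ys = np.broadcast_to(y[:, None], (n, m))
    np.add.at(joint, (cols.ravel(), X.ravel(), ys.ravel()), 1.0)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * (np.log2(p) - np.log2(px) - np.log2(py))
    return np.nansum(t, axis=(1, 2))


def clade_mi(msa: AlignmentMatrix, clades: CladeAssignment, col: int) -> float:
    """MI (bits) between the residues at ``col`` and the clade label."""
    msa.check_col(col)
    X, y, g = _clade_setup(msa, clades)
    x = X[:, col - 1]
    joint = np.zeros((N_SYMBOLS, g))
    np.add.at(joint, (x, y), 1.0)
    return _mi_from_joint(joint)


def identify_cdps(
    msa: AlignmentMatrix,
    clades: CladeAssignment,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_CDP_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for clade association of every column.

    p = (1 + #{label permutations with MI >= observed}) / (1 + n_perm),
    Benjamini-Hochberg corrected across columns; is_cdp means q <= alpha.
    Deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 for CDP calling, got {n_perm}")
    X, y, g = _clade_setup(msa, clades)
    n, m = X.shape
    # one-hot encodings let each permutation reduce to one small matmul
    B = np.zeros((n, m * N_SYMBOLS), dtype=np.float32)
    B[np.arange(n)[:, None], X + np.arange(m) * N_SYMBOLS] = 1.0

    def mi_for_labels(yv: np.ndarray) -> np.ndarray:
        L = np.zeros((n, g), dtype=np.float32)
        L[np.arange(n), yv] = 1.0
        joint = (B.T @ L).reshape(m, N_SYMBOLS, g).astype(np.float64) / n
        px = joint.sum(axis=2, keepdims=True)
        py = joint.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = joint * (np.log2(joint) - np.log2(px) - np.log2(py))
        return np.nansum(t, axis=(1, 2))

    observed = mi_for_labels(y)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(m)
    for _ in range(n_perm):
        exceed += mi_for_labels(rng.permutation(y)) >= observed - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = false_discovery_control(p, method="bh")
    return pd.DataFrame({
        "column": np.arange(1, m + 1),
        "clade_mi": observed,
        "p_value": p,
        "q_value": q,
        "is_cdp": q <= alpha,
    })


# ---------------------------------------------------------------------------
# Pairwise MI, APC correction, permutation z-scores
# ---------------------------------------------------------------------------

@dataclass
class MIMatrix:
    """All-pairs column MI: raw, APC-corrected, and permutation z-scores."""

    columns: np.ndarray            # 1-based column numbers, length m
    mi_raw: np.ndarray             # (m, m), symmetric, diagonal 0
    mi_apc: np.ndarray | None = None
    z: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # bool (m, m): zero null sd pairs

    def pair_frame(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.columns), k=1)
        data = {
            "col_i": self.columns[iu],
            "col_j": self.columns[ju],
            "mi_raw": self.mi_raw[iu, ju],
        }
        if self.mi_apc is not None:
            data["mi_apc"] = self.mi_apc[iu, ju]
        if self.z is not None:
            data["z"] = self.z[iu, ju]
        return pd.DataFrame(data)


def _resolve_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per sequence")
    return w


def identity_weights(msa: AlignmentMatrix, identity_cut: float = 0.62) -> np.ndarray:
    """1 / cluster-size weights: rows within ``identity_cut`` pairwise identity
    (over mutually non-gap columns) count as one effective sequence."""
    X = encode(msa)
    n = X.shape[0]
    counts = np.ones(n)
    for i in range(n):
        same = (X == X[i]).sum(axis=1) / X.shape[1]
        counts[i] = np.sum(same >= identity_cut)
    return 1.0 / counts


def _pair_mi_upper(
    X: np.ndarray, weights: np.ndarray, pseudocount: float
) -> np.ndarray:
    """MI (bits) for every unordered column pair; returns (n_pairs,) in
    upper-triangle order. One-hot + matmul gives every joint table at once."""
    n, m = X.shape
    k = N_SYMBOLS
    B = np.zeros((n, m * k), dtype=np.float32)
    B[np.arange(n)[:, None], X + np.arange(m) * k] = 1.0
    Bw = B * weights[:, None].astype(np.float32)
    C = (B.T @ Bw).reshape(m, k, m, k)
    iu, ju = np.triu_indices(m, k=1)
    J = C[iu, :, ju, :].astype(np.float64)  # (n_pairs, k, k)
    if pseudocount:
        J = J + pseudocount
    tot = J.sum(axis=(1, 2), keepdims=True)
    P = J / tot
    Px = P.sum(axis=2)
    Py = P.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = P * (np.log2(P) - np.log2(Px)[:, :, None] - np.log2(Py)[:, None, :])
    return np.nansum(t, axis=(1, 2))


def _upper_to_full(m: int, upper: np.ndarray) -> np.ndarray:
    out = np.zeros((m, m))
    iu, ju = np.triu_indices(m, k=1)
    out[iu, ju] = upper
    out[ju, iu] = upper
    return out


def pairwise_mi(
    msa: AlignmentMatrix,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.0,
    ids: list[str] | None = None,
) -> MIMatrix:
    """Weighted plug-in MI for every column pair (bits), gap as 21st symbol."""
    if msa.n_cols < 2:
        raise SdpnetError("pairwise MI needs at least 2 columns")
    X = encode(msa, ids)
    w = _resolve_weights(X.shape[0], weights)
    upper = _pair_mi_upper(X, w, pseudocount)
    return MIMatrix(
        columns=np.arange(1, msa.n_cols + 1),
        mi_raw=_upper_to_full(msa.n_cols, upper),
    )


def _apc_of(mi: np.ndarray) -> np.ndarray:
    m = mi.shape[0]
    mean_i = mi.sum(axis=1) / (m - 1)
    mean_all = mi[np.triu_indices(m, k=1)].mean()
    if mean_all == 0:
        correction = np.zeros_like(mi)
    else:
        correction = np.outer(mean_i, mean_i) / mean_all
    apc = mi - correction
    np.fill_diagonal(apc, 0.0)
    return apc


def apc_correct(mim: MIMatrix) -> MIMatrix:
    """Average product correction:
    mi_apc(i,j) = mi_raw(i,j) - mean_i * mean_j / mean_all."""
    m = len(mim.columns)
    if m < 3:
        raise SdpnetError("APC correction needs at least 3 columns")
    return MIMatrix(columns=mim.columns, mi_raw=mim.mi_raw, mi_apc=_apc_of(mim.mi_raw))


def mi_zscores(
    msa: AlignmentMatrix,
    n_perm: int = DEFAULT_Z_PERMUTATIONS,
    seed: int = 0,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.0,
    ids: list[str] | None = None,
) -> MIMatrix:
    """APC-corrected MI standardized against a column-shuffle null.

    Each null replicate permutes the rows of every column independently,
    preserving per-column composition while destroying covariation; the same
    APC correction is applied to each replicate. Pairs with zero null
    standard deviation (constant columns) get z = 0 and are flagged in
    ``degenerate``. Deterministic for a given seed.
    """
    if n_perm < 50:
        raise ValueError(f"n_perm must be >= 50 for z-scores, got {n_perm}")
    X = encode(msa, ids)
    n, m = X.shape
    if m < 3:
        raise SdpnetError("z-scores need at least 3 columns")
    w = _resolve_weights(n, weights)
    iu, ju = np.triu_indices(m, k=1)

    obs_raw = _pair_mi_upper(X, w, pseudocount)
    obs_apc = _apc_of(_upper_to_full(m, obs_raw))[iu, ju]

    rng = np.random.default_rng(seed)
    s1 = np.zeros(len(iu))
    s2 = np.zeros(len(iu))
    for _ in range(n_perm):
        Xp = rng.permuted(X, axis=0)
        null_apc = _apc_of(_upper_to_full(m, _pair_mi_upper(Xp, w, pseudocount)))[iu, ju]
        s1 += null_apc
        s2 += null_apc ** 2
    mean = s1 / n_perm
    var = np.maximum(0.0, (s2 - s1 ** 2 / n_perm) / (n_perm - 1))
    sd = np.sqrt(var)
    degenerate_u = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        z_u = np.where(degenerate_u, 0.0, (obs_apc - mean) / np.where(sd > 0, sd, 1.0))

    z = _upper_to_full(m, z_u)
    degenerate = _upper_to_full(m, degenerate_u.astype(float)).astype(bool)
    return MIMatrix(
        columns=np.arange(1, m + 1),
        mi_raw=_upper_to_full(m, obs_raw),
        mi_apc=_upper_to_full(m, obs_apc),
        z=z,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Network and SDP/SDN classification
# ---------------------------------------------------------------------------

@dataclass
class MINetwork:
    """Significant-MI network: nodes are columns with >= 1 significant edge."""

    graph: nx.Graph
    z_cut: float

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def components(self) -> list[set[int]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: min(c))

    @property
    def cumulative(self) -> dict[int, float]:
        """Per node, summed z over its significant edges."""
        return {
            node: sum(d["z"] for _, _, d in self.graph.edges(node, data=True))
            for node in self.graph.nodes
        }


def build_network(mim: MIMatrix, z_cut: float = DEFAULT_Z_CUT) -> MINetwork:
    """Edges are pairs with z >= z_cut; isolated columns are not nodes."""
    if mim.z is None:
        raise SdpnetError("z-scores not computed; run mi_zscores first")
    g = nx.Graph()
    iu, ju = np.triu_indices(len(mim.columns), k=1)
    sig = mim.z[iu, ju] >= z_cut
    for i, j in zip(iu[sig], ju[sig]):
        g.add_edge(
            int(mim.columns[i]), int(mim.columns[j]),
            z=float(mim.z[i, j]),
            mi_raw=float(mim.mi_raw[i, j]),
            mi_apc=float(mim.mi_apc[i, j]) if mim.mi_apc is not None else None,
        )
    return MINetwork(graph=g, z_cut=z_cut)


@dataclass
class SDPReport:
    """Column statuses and specificity-determining sub-networks.

    status: none < CDP < pSDP < SDP. A pSDP is a CDP in the MI network; an
    SDP is a pSDP grouped with at least one other pSDP in an SDN.
    """

    frame: pd.DataFrame
    sdns: list[dict] = field(default_factory=list)
    max_link: int = DEFAULT_MAX_LINK

    def columns_with(self, status: str) -> list[int]:
        return self.frame.loc[self.frame.status == status, "column"].tolist()

    @property
    def cdps(self) -> list[int]:
        return self.frame.loc[
            self.frame.status.isin(["CDP", "pSDP", "SDP"]), "column"].tolist()

    @property
    def psdps(self) -> list[int]:
        return self.frame.loc[self.frame.status.isin(["pSDP", "SDP"]), "column"].tolist()

    @property
    def sdps(self) -> list[int]:
        return self.columns_with("SDP")

    def to_json_dict(self) -> dict:
        return {
            "max_link": self.max_link,
            "columns": self.frame.to_dict(orient="records"),
            "sdns": self.sdns,
        }


def classify_sdps(
    cdps: pd.DataFrame,
    net: MINetwork,
    max_link: int = DEFAULT_MAX_LINK,
) -> SDPReport:
    """Cross CDPs with the MI network and group SDPs into SDNs.

    Two pSDPs belong to the same SDN when a path of length <= max_link + 1
    joins them whose interior nodes are all non-pSDP (default: a direct edge
    or one intervening non-pSDP linker). Isolated pSDPs form singleton SDNs
    and keep pSDP status.
    """
    cdp_cols = set(cdps.loc[cdps.is_cdp, "column"].astype(int))
    psdps = cdp_cols & net.nodes

    pair_links: dict[tuple[int, int], set[int]] = {}
    sdn_graph = nx.Graph()
    sdn_graph.add_nodes_from(psdps)
    for u in psdps:
        stack: list[tuple[int, tuple[int, ...]]] = [(u, ())]
        while stack:
            node, interior = stack.pop()
            for nb in net.graph.neighbors(node):
                if nb == u or nb in interior:
                    continue
                if nb in psdps:
                    sdn_graph.add_edge(u, nb)
                    key = (min(u, nb), max(u, nb))
                    pair_links.setdefault(key, set()).update(interior)
                elif len(interior) < max_link:
                    stack.append((nb, interior + (nb,)))

    sdns: list[dict] = []
    sdn_of: dict[int, str] = {}
    comps = sorted((set(c) for c in nx.connected_components(sdn_graph)),
                   key=lambda c: min(c))
    for idx, comp in enumerate(comps, start=1):
        sdn_id = f"SDN{idx}"
        linkers: set[int] = set()
        for key, nodes in pair_links.items():
            if key[0] in comp:
                linkers |= nodes
        for col in comp:
            sdn_of[col] = sdn_id
        sdns.append({
            "id": sdn_id,
            "members": sorted(int(c) for c in comp),
            "linkers": sorted(int(x) for x in linkers),
        })

    confirmed = {c for s in sdns if len(s["members"]) > 1 for c in s["members"]}
    records = []
    for col in sorted(int(c) for c in cdps["column"]):
        if col in confirmed:
            status = "SDP"
        elif col in psdps:
            status = "pSDP"
        elif col in cdp_cols:
            status = "CDP"
        else:
            status = "none"
        records.append({"column": col, "status": status,
                        "sdn_id": sdn_of.get(col)})
    return SDPReport(frame=pd.DataFrame(records), sdns=sdns, max_link=max_link)
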