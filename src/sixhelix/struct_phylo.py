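"""Stutter-anchored structural phylogenetics of class I fusion-protein protomers.

Pipeline: filter candidate structures (resolution <= 4.5 A, intact HR1/CR/HR2),
truncate each protomer so it starts at the HR1 stutter, align all pairs with an
elastic distance-difference score, convert scores to length-calibrated Z-scores,
derive a pairwise distance d(A,B) = max(0, Z_AA + Z_BB - Z_AB) (self-distances
forced to zero), and agglomerate into a dendrogram written as Newick.

The elastic score of a residue correspondence follows the classic
distance-matrix alignment form: summing over ordered pairs of aligned positions
(k, l),

    S = sum [theta - |dA(k,l) - dB(k,l)| / d*] * exp(-(d*/alpha)^2),

with d* the mean of the two intramolecular CA distances, theta = 0.20 the
similarity threshold, alpha = 20 A the distance-deweighting scale, and each
diagonal k = l pair contributing theta. The Z calibration uses the published
mean-score curve m(L) = 7.95 + 0.71 L - 2.59e-4 L^2 - 1.92e-6 L^3 at
L = sqrt(LA * LB), held constant above L = 400.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist
from skbio import TreeNode

THETA = 0.20
ALPHA = 20.0
RESOLUTION_CUTOFF = 4.5


# ---------------------------------------------------------------------------
# input filtering and stutter truncation


@dataclass(frozen=True)
class StructureMeta:
    """Candidate-structure metadata used by the selection filter."""

    id: str
    resolution: float | None
    has_hr1: bool
    has_cr: bool
    has_hr2: bool


def filter_inputs(
    records: list[StructureMeta | dict],
    resolution_cutoff: float = RESOLUTION_CUTOFF,
) -> tuple[list[str], dict[str, str]]:
    """Keep structures with resolution <= cutoff and intact HR1, CR and HR2.

    Returns (accepted ids, rejected id -> reason).
    """
    accepted, rejected = [], {}
    for rec in records:
        if isinstance(rec, dict):
            rec = StructureMeta(**rec)
        if rec.resolution is None:
            rejected[rec.id] = "missing resolution"
        elif rec.resolution > resolution_cutoff:
            rejected[rec.id] = f"resolution {rec.resolution:.2f} A > {resolution_cutoff} A"
        elif not (rec.has_hr1 and rec.has_cr and rec.has_hr2):
            missing = [n for n, f in (("HR1", rec.has_hr1), ("CR", rec.has_cr),
                                      ("HR2", rec.has_hr2)) if not f]
            rejected[rec.id] = "missing " + "/".join(missing)
        else:
            accepted.append(rec.id)
    return accepted, rejected


@dataclass
class StutterAnchoredDomain:
    """CA trace of one protomer chain from the HR1 stutter to the C terminus."""

    id: str
    chain_id: str
    numbers: list[int]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.numbers) != len(self.coords):
            raise ValueError("numbers and coords length mismatch")

    def __len__(self) -> int:
        return len(self.numbers)


def truncate_at_stutter(
    model,
    stutter_span: tuple[int, int] | None = None,
    chain_id: str | None = None,
) -> StutterAnchoredDomain:
    """Remove all residues N-terminal to the HR1 stutter of one protomer chain.

    Only one chain per structure is used (the first polymer chain unless
    ``chain_id`` is given). If no span is supplied, a sequence-based register
    fallback is attempted; failing that, an error explains the fallback.
    """
    from . import coiled_coil, structure_io

    chain = model.get_chain(chain_id) if chain_id else model.chains[0]
    if stutter_span is None:
        seq, num_map = structure_io.extract_sequence(model, chain.chain_id)
        numbers = [num_map[i] for i in range(1, len(seq) + 1)]
        _, spans = coiled_coil.register_from_sequence(seq, numbers)
        if not spans:
            raise ValueError(
                "no stutter span given and none detected; run the sequence "
                "fallback register (coiled_coil.register_from_sequence) or "
                "supply the span explicitly"
            )
        stutter_span = spans[0]
    start = stutter_span[0]
    ca, nums = chain.ca_coords()
    keep = [i for i, n in enumerate(nums) if n >= start]
    if not keep or nums[keep[0]] != start:
        raise ValueError(f"stutter start {start} not present in chain {chain.chain_id}")
    return StutterAnchoredDomain(
        id=model.id,
        chain_id=chain.chain_id,
        numbers=[nums[i] for i in keep],
        coords=ca[keep],
    )


# ---------------------------------------------------------------------------
# elastic scoring and pairwise alignment


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, StutterAnchoredDomain):
        return obj.coords
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def _pair_terms(da: np.ndarray, db: np.ndarray,
                theta: float, alpha: float) -> np.ndarray:
    """Elementwise elastic terms for matched intramolecular distances."""
    dstar = 0.5 * (da + db)
    weight = np.exp(-((dstar / alpha) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(dstar > 0, np.abs(da - db) / np.where(dstar > 0, dstar, 1.0), 0.0)
    return (theta - rel) * weight


def elastic_score(
    a, b,
    correspondence: list[tuple[int, int]],
    theta: float = THETA,
    alpha: float = ALPHA,
) -> float:
    """Elastic similarity score S of a monotone residue correspondence.

    Sums over all ordered pairs of aligned positions; the k = l diagonal
    contributes theta per aligned residue.
    """
    pa = _as_coords(a)
    pb = _as_coords(b)
    if len(correspondence) < 3:
        raise ValueError("need at least 3 aligned pairs")
    ia = np.array([p[0] for p in correspondence])
    ib = np.array([p[1] for p in correspondence])
    if np.any(np.diff(ia) <= 0) or np.any(np.diff(ib) <= 0):
        raise ValueError("correspondence must be strictly increasing in both structures")
    da = cdist(pa[ia], pa[ia])
    db = cdist(pb[ib], pb[ib])
    terms = _pair_terms(da, db, theta, alpha)
    off = terms[~np.eye(len(ia), dtype=bool)].sum()
    return float(off + theta * len(ia))


def kabsch_superpose(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rotation of q onto p (after centering); returns (rotated q, RMSD)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc, qc = p - p.mean(0), q - q.mean(0)
    h = qc.T @ pc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    qr = qc @ rot
    rmsd = float(np.sqrt(np.mean(np.sum((qr - pc) ** 2, axis=1))))
    return qr + p.mean(0), rmsd


@dataclass
class PairAlignment:
    """Monotone residue correspondence between two structures with its elastic
    score, length-calibrated Z-score and post-superposition CA RMSD."""

    id_a: str
    id_b: str
    pairs: list[tuple[int, int]]
    score: float
    z: float
    rmsd: float

    @property
    def n_aligned(self) -> int:
        return len(self.pairs)


def _cell_scores(da: np.ndarray, db: np.ndarray,
                 pairs: list[tuple[int, int]],
                 theta: float, alpha: float) -> np.ndarray:
    """Marginal elastic gain of matching (i, j) against the current
    correspondence (off-diagonal terms doubled for the ordered-pair sum)."""
    ks = np.array([p[0] for p in pairs])
    ls = np.array([p[1] for p in pairs])
    # broadcast: (nA, 1, m) vs (1, nB, m)
    tda = da[:, ks][:, None, :]
    tdb = db[:, ls][None, :, :]
    terms = _pair_terms(tda, tdb, theta, alpha)
    s = 2.0 * terms.sum(axis=2) + theta
    # remove self-pairing inflation where (i, j) is itself in the current set
    for k, l in pairs:
        s[k, l] -= 2.0 * theta
    return s


def _monotone_dp(s: np.ndarray) -> list[tuple[int, int]]:
    """Maximum-weight monotone matching with free gaps (Needleman-Wunsch with
    zero gap penalty); matches with negative weight are never forced."""
    na, nb = s.shape
    h = np.zeros((na + 1, nb + 1))
    move = np.zeros((na + 1, nb + 1), dtype=np.int8)
    for i in range(1, na + 1):
        hi = h[i]
        hm1 = h[i - 1]
        for j in range(1, nb + 1):
            diag = hm1[j - 1] + s[i - 1, j - 1]
            up = hm1[j]
            left = hi[j - 1]
            best = diag
            mv = 0
            if up > best:
                best, mv = up, 1
            if left > best:
                best, mv = left, 2
            hi[j] = best
            move[i, j] = mv
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        mv = move[i, j]
        if mv == 0:
            if s[i - 1, j - 1] > 0:
                pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _seed_correspondences(na: int, nb: int, seed: int) -> list[list[tuple[int, int]]]:
    """Deterministic diagonal seeds (fixed enumeration order) plus a few
    seeded random monotone matchings."""
    seeds = []
    span = na + nb - 6
    step = max(1, span // 12)
    offsets = {0, 1, -1, nb - na}
    offsets.update(range(-(na - 3), nb - 2, step))
    for off in sorted(offsets):
        lo = max(0, -off)
        hi = min(na, nb - off)
        if hi - lo >= 3:
            seeds.append([(i, i + off) for i in range(lo, hi)])
    rng = np.random.default_rng(seed)
    for _ in range(3):
        m = min(na, nb)
        k = int(rng.integers(3, m + 1))
        ia = np.sort(rng.choice(na, size=k, replace=False))
        ib = np.sort(rng.choice(nb, size=k, replace=False))
        seeds.append(list(zip(ia.tolist(), ib.tolist())))
    return seeds


def _triplet_seeds(da: np.ndarray, db: np.ndarray, theta: float, alpha: float,
                   top: int = 30) -> list[list[tuple[int, int]]]:
    """Best-scoring 3-pair monotone correspondences, enumerated exhaustively.

    Small instances have sparse optima that diagonal seeding misses; for a
    3-pair set {(a1,b1),(a2,b2),(a3,b3)} the elastic score is 3 theta plus the
    three doubled off-diagonal terms, cheap enough to enumerate when the
    structures are small.
    """
    from itertools import combinations

    na, nb = len(da), len(db)
    scored = []
    for ca in combinations(range(na), 3):
        sub_a = da[np.ix_(ca, ca)]
        for cb in combinations(range(nb), 3):
            sub_b = db[np.ix_(cb, cb)]
            terms = _pair_terms(sub_a, sub_b, theta, alpha)
            s = 3.0 * theta + float(terms[~np.eye(3, dtype=bool)].sum())
            scored.append((s, list(zip(ca, cb))))
    scored.sort(key=lambda t: -t[0])
    return [pairs for _, pairs in scored[:top]]


def align_structures(
    a, b,
    seed: int = 0,
    theta: float = THETA,
    alpha: float = ALPHA,
    max_iter: int = 30,
    id_a: str = "A",
    id_b: str = "B",
) -> PairAlignment:
    """Heuristic elastic alignment: diagonal/random seeding followed by
    iterative dynamic programming over the distance-difference score.

    Deterministic given ``seed``. The returned correspondence is monotone and
    its score is at least the best seed score.
    """
    pa = _as_coords(a)
    pb = _as_coords(b)
    if len(pa) < 3 or len(pb) < 3:
        raise ValueError("structures must have at least 3 residues")
    for pts in (pa, pb):
        if len(pts) >= 3:
            rel = pts - pts.mean(0)
            if np.linalg.svd(rel, compute_uv=False)[1] < 1e-8:
                raise ValueError("degenerate (collinear) geometry")
    da = cdist(pa, pa)
    db = cdist(pb, pb)
    if isinstance(a, StutterAnchoredDomain):
        id_a = a.id
    if isinstance(b, StutterAnchoredDomain):
        id_b = b.id

    seeds = _seed_correspondences(len(pa), len(pb), seed)
    if min(len(pa), len(pb)) <= 12:
        seeds = _triplet_seeds(da, db, theta, alpha) + seeds

    best_pairs: list[tuple[int, int]] = []
    best_score = -np.inf
    for seed_pairs in seeds:
        pairs = seed_pairs
        try:
            score = elastic_score(pa, pb, pairs, theta, alpha)
        except ValueError:
            continue
        for _ in range(max_iter):
            s = _cell_scores(da, db, pairs, theta, alpha)
            new_pairs = _monotone_dp(s)
            if len(new_pairs) < 3 or new_pairs == pairs:
                break
            new_score = elastic_score(pa, pb, new_pairs, theta, alpha)
            if new_score <= score + 1e-12:
                break
            pairs, score = new_pairs, new_score
        if score > best_score:
            best_score, best_pairs = score, pairs

    ia = [p[0] for p in best_pairs]
    ib = [p[1] for p in best_pairs]
    _, rmsd = kabsch_superpose(pa[ia], pb[ib])
    z = zscore(best_score, len(pa), len(pb))
    return PairAlignment(id_a=id_a, id_b=id_b, pairs=best_pairs,
                         score=float(best_score), z=z, rmsd=rmsd)


def exhaustive_best_score(
    a, b, theta: float = THETA, alpha: float = ALPHA, max_n: int = 8
) -> float:
    """Exact optimum of the elastic score over all monotone correspondences of
    >= 3 pairs; exponential, intended for toy inputs (n <= ``max_n``)."""
    pa = _as_coords(a)
    pb = _as_coords(b)
    if len(pa) > max_n or len(pb) > max_n:
        raise ValueError(f"exhaustive mode limited to {max_n} residues")
    from itertools import combinations

    best = -np.inf
    idx_a = range(len(pa))
    idx_b = range(len(pb))
    for k in range(3, min(len(pa), len(pb)) + 1):
        for ca in combinations(idx_a, k):
            for cb in combinations(idx_b, k):
                s = elastic_score(pa, pb, list(zip(ca, cb)), theta, alpha)
                if s > best:
                    best = s
    return float(best)


def zscore(score: float, len_a: int, len_b: int) -> float:
    """Length-calibrated Z-score: Z = (S - m(L)) / (0.5 m(L)) with the published
    cubic mean-score curve, L = sqrt(LA * LB) held constant above 400."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if len_a < 3 or len_b < 3:
        raise ValueError("lengths must be >= 3")
    return (score - mean_score(np.sqrt(len_a * len_b))) / (
        0.5 * mean_score(np.sqrt(len_a * len_b))
    )


def mean_score(length: float) -> float:
    """Expected elastic score m(L) of an average structure pair of effective
    length L (published calibration; constant above L = 400)."""
    x = min(float(length), 400.0)
    return 7.95 + 0.71 * x - 2.59e-4 * x**2 - 1.92e-6 * x**3


def pairwise_distance(z_aa: float, z_bb: float, z_ab: float,
                      normalized: bool = False) -> float:
    """Z-score-derived structural distance.

    Literal form (default): d = max(0, (Z_AA + Z_BB) - Z_AB). The normalized
    variant d = max(0, Z_AA + Z_BB - 2 Z_AB) makes self-distance exactly zero
    without the diagonal override.
    """
    for z in (z_aa, z_bb, z_ab):
        if not np.isfinite(z):
            raise ValueError("Z-scores must be finite")
    if normalized:
        return max(0.0, z_aa + z_bb - 2.0 * z_ab)
    return max(0.0, (z_aa + z_bb) - z_ab)


# ---------------------------------------------------------------------------
# distance matrices and trees


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("matrix must be symmetric")
        if np.any(m < -1e-8):
            raise ValueError("matrix must be nonnegative")
        m = np.clip((m + m.T) / 2.0, 0.0, None)
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def all_vs_all(
    domains: list[StutterAnchoredDomain],
    seed: int = 0,
    normalized: bool = False,
    theta: float = THETA,
    alpha: float = ALPHA,
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Self- and cross-alignments for a domain set; returns the Z-derived
    distance matrix and a per-pair report (S, Z, RMSD, aligned length)."""
    n = len(domains)
    z_self = np.empty(n)
    for i, dom in enumerate(domains):
        s = elastic_score(dom, dom, [(k, k) for k in range(len(dom))], theta, alpha)
        z_self[i] = zscore(s, len(dom), len(dom))
    dmat = np.zeros((n, n))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_structures(domains[i], domains[j], seed=seed,
                                   theta=theta, alpha=alpha)
            d = pairwise_distance(z_self[i], z_self[j], aln.z, normalized=normalized)
            dmat[i, j] = dmat[j, i] = d
            rows.append({
                "a": domains[i].id, "b": domains[j].id,
                "score": aln.score, "z": aln.z, "rmsd": aln.rmsd,
                "n_aligned": aln.n_aligned, "distance": d,
            })
    labels = [d.id for d in domains]
    return DistanceMatrix(labels, dmat), pd.DataFrame(rows)


@dataclass
class PhyloTree:
    """Labelled dendrogram; UPGMA trees keep their scipy-format linkage so the
    k-cluster cut is exact."""

    tree: TreeNode
    labels: list[str]
    linkage: np.ndarray | None = None

    def cut(self, k: int) -> dict[str, int]:
        """Cluster id per label from cutting the dendrogram into k clusters."""
        if self.linkage is None:
            raise ValueError("k-cluster cut requires an agglomerative (UPGMA) tree")
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))


def _sanitize(label: str) -> str:
    out = label.replace(" ", "_")
    if any(ch in out for ch in "();,:'\""):
        raise ValueError(f"label {label!r} contains Newick metacharacters")
    return out


def build_dendrogram(dm: DistanceMatrix, method: str = "upgma") -> PhyloTree:
    """Average-linkage (UPGMA) agglomeration by default, with lexicographic
    tie-breaking; neighbor joining available as ``method="nj"``."""
    labels = [_sanitize(l) for l in dm.labels]
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    if method == "nj":
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        tree = nj(SkbioDM(dm.matrix, ids=labels))
        return PhyloTree(tree=tree, labels=labels, linkage=None)
    if method != "upgma":
        raise ValueError(f"unknown method {method!r}")

    n = len(labels)
    active: dict[int, dict] = {
        i: {"size": 1, "height": 0.0, "label": labels[i], "newick": labels[i]}
        for i in range(n)
    }
    dist = {frozenset((i, j)): float(dm.matrix[i, j])
            for i in range(n) for j in range(i + 1, n)}
    linkage_rows = []
    next_id = n
    while len(active) > 1:
        best = None
        for key, d in dist.items():
            i, j = sorted(key)
            tie_key = tuple(sorted((active[i]["label"], active[j]["label"])))
            cand = (d, tie_key, i, j)
            if best is None or cand < best:
                best = cand
        d, _, i, j = best
        hi = d / 2.0
        bi = hi - active[i]["height"]
        bj = hi - active[j]["height"]
        first, second = sorted((i, j), key=lambda c: active[c]["label"])
        merged = {
            "size": active[i]["size"] + active[j]["size"],
            "height": hi,
            "label": min(active[i]["label"], active[j]["label"]),
            "newick": "({}:{:.10g},{}:{:.10g})".format(
                active[first]["newick"], hi - active[first]["height"],
                active[second]["newick"], hi - active[second]["height"],
            ),
        }
        linkage_rows.append([i, j, d, merged["size"]])
        for other in list(active):
            if other in (i, j):
                continue
            dio = dist.pop(frozenset((i, other)))
            djo = dist.pop(frozenset((j, other)))
            dist[frozenset((next_id, other))] = (
                active[i]["size"] * dio + active[j]["size"] * djo
            ) / merged["size"]
        dist.pop(frozenset((i, j)))
        del active[i], active[j]
        active[next_id] = merged
        next_id += 1

    root = active.popitem()[1]
    tree = TreeNode.read(io.StringIO(root["newick"] + ";"))
    linkage = np.asarray(linkage_rows, dtype=float)
    return PhyloTree(tree=tree, labels=labels, linkage=linkage)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    tree.tree.write(buf)
    text = buf.getvalue().strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source: str | Path) -> PhyloTree:
    """Parse Newick text (or a file path) into a PhyloTree."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and "(" not in source
        and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick text")
    try:
        tree = TreeNode.read(io.StringIO(text))
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = sorted(t.name for t in tree.tips())
    return PhyloTree(tree=tree, labels=labels, linkage=None)
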