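"""Module-network learning with normal-gamma Bayesian scoring.

A module network is a Bayesian-network variant in which co-regulated genes
share one conditional distribution: each module of genes is explained by a
binary regression tree whose internal nodes split the samples on the state
of a candidate *modulator* gene — its expression, its gene-level copy-number
log2 ratio, or its binary mutation status.  Leaves pool the expression
values of all module genes over the leaf's samples, and each pool is scored
with the closed-form Gaussian marginal likelihood under a conjugate
normal-gamma prior on (mean, precision):

    log m(x) = lnG(a_n) - lnG(a_0) + a_0 ln b_0 - a_n ln b_n
               + (ln k_0 - ln k_n)/2 - (n/2) ln 2*pi

with k_n = k_0 + n, a_n = a_0 + n/2 and
b_n = b_0 + sum(x - xbar)^2 / 2 + k_0 n (xbar - mu_0)^2 / (2 k_n).

Learning alternates greedy top-down tree search per module (a split is kept
only when its score gain exceeds a fixed complexity penalty) with exact
sequential reassignment of genes to the module whose tree best explains
them, so the total network score is non-decreasing by construction.

Expression is standardized per gene (z-score across the run's samples)
before scoring so the default prior (0, 1, 1, 1) is on the data scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans

if TYPE_CHECKING:
    from drivermod.data_io import OmicsBundle

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)
SOURCES = ("expression", "cnv", "mutation")
_GAIN_TOL = 1e-9


@dataclass(frozen=True)
class NGPrior:
    """Conjugate normal-gamma prior on a Gaussian's (mean, precision)."""

    mu0: float = 0.0
    kappa0: float = 1.0
    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa0 <= 0 or self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("kappa0, alpha0, beta0 must be positive")


@dataclass
class ModuleNetworkConfig:
    prior: NGPrior = field(default_factory=NGPrior)
    #: log-score gain a split must exceed to be accepted (AIC-style constant)
    penalty: float = 2.0
    min_leaf: int = 5
    max_depth: int = 3
    target_module_size: int = 20
    n_modules: int | None = None
    max_iter: int = 20
    #: candidates handed to modules left empty by the initial association
    fallback_k: int = 5
    max_candidates: int | None = None
    #: count only tree roots as modulators in rankings
    root_only: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# normal-gamma marginal likelihood


def _ng_from_stats(n, total, sq_total, prior: NGPrior):
    """Vectorized log marginal from sufficient statistics (n, sum, sum of squares)."""
    n = np.asarray(n, dtype=float)
    total = np.asarray(total, dtype=float)
    sq_total = np.asarray(sq_total, dtype=float)
    safe_n = np.maximum(n, 1.0)
    mean = total / safe_n
    dev = np.maximum(sq_total - n * mean * mean, 0.0)
    kn = prior.kappa0 + n
    an = prior.alpha0 + 0.5 * n
    bn = prior.beta0 + 0.5 * dev + prior.kappa0 * n * (mean - prior.mu0) ** 2 / (2.0 * kn)
    val = (
        gammaln(an)
        - gammaln(prior.alpha0)
        + prior.alpha0 * math.log(prior.beta0)
        - an * np.log(bn)
        + 0.5 * (math.log(prior.kappa0) - np.log(kn))
        - 0.5 * n * LOG2PI
    )
    return np.where(n > 0, val, 0.0)


def _ng_scalar(n: float, total: float, sq_total: float, prior: NGPrior) -> float:
    if n <= 0:
        return 0.0
    mean = total / n
    dev = max(sq_total - n * mean * mean, 0.0)
    kn = prior.kappa0 + n
    an = prior.alpha0 + 0.5 * n
    bn = prior.beta0 + 0.5 * dev + prior.kappa0 * n * (mean - prior.mu0) ** 2 / (2.0 * kn)
    return (
        math.lgamma(an)
        - math.lgamma(prior.alpha0)
        + prior.alpha0 * math.log(prior.beta0)
        - an * math.log(bn)
        + 0.5 * (math.log(prior.kappa0) - math.log(kn))
        - 0.5 * n * LOG2PI
    )


def ng_log_marginal(x: Sequence[float], prior: NGPrior | None = None) -> float:
    """Log marginal likelihood of observations ``x`` under the normal-gamma prior.

    Equals the sequential product of Student-t posterior predictives; the
    empty sample has log marginal 0 (empty product).
    """
    prior = prior or NGPrior()
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        return 0.0
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    return float(_ng_scalar(arr.size, arr.sum(), float(np.dot(arr, arr)), prior))


def leaf_score(
    module_genes: Sequence[str],
    leaf_samples: Sequence[str],
    expr: pd.DataFrame,
    prior: NGPrior | None = None,
) -> float:
    """Shared-CPD score: normal-gamma marginal of the pooled module x leaf values."""
    prior = prior or NGPrior()
    if len(module_genes) == 0:
        raise ValueError("module must be non-empty")
    pool = expr.loc[list(module_genes), list(leaf_samples)].to_numpy(dtype=float).ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        logger.warning("all-missing pool in leaf_score; returning 0")
        return 0.0
    return float(_ng_scalar(pool.size, pool.sum(), float(np.dot(pool, pool)), prior))


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    modulator: str | None = None
    source: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    samples: np.ndarray | None = None  # leaf only: indices into the run's sample order

    @property
    def is_leaf(self) -> bool:
        return self.modulator is None


@dataclass
class RegulatoryTree:
    """Binary regression tree partitioning samples by modulator states."""

    root: TreeNode

    def leaves(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []

        def rec(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.samples)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    def splits(self) -> list[dict]:
        out: list[dict] = []

        def rec(node: TreeNode, depth: int) -> None:
            if node.is_leaf:
                return
            out.append(
                {
                    "modulator": node.modulator,
                    "source": node.source,
                    "threshold": node.threshold,
                    "depth": depth,
                    "is_root": depth == 0,
                }
            )
            rec(node.left, depth + 1)
            rec(node.right, depth + 1)

        rec(self.root, 0)
        return out

    @property
    def n_splits(self) -> int:
        return len(self.splits())

    def split_genes(self, root_only: bool = False) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.splits():
            if root_only and not s["is_root"]:
                continue
            seen.setdefault(s["modulator"])
        return list(seen)

    def to_dict(self, sample_names: Sequence[str] | None = None) -> dict:
        def rec(node: TreeNode):
            if node.is_leaf:
                idx = node.samples.tolist()
                return {"samples": [sample_names[i] for i in idx] if sample_names is not None else idx}
            return {
                "modulator": node.modulator,
                "source": node.source,
                "threshold": node.threshold,
                "left": rec(node.left),
                "right": rec(node.right),
            }

        return rec(self.root)


# ---------------------------------------------------------------------------
# signals and per-sample module statistics


class SignalSet:
    """Modulator split signals per source, aligned on one sample order.

    Missing values are imputed to the neutral state (0: mean expression on
    the z scale, neutral log2 ratio, unmutated) so every sample can be
    routed at every split.
    """

    def __init__(self, frames: dict[str, pd.DataFrame], samples: Sequence[str]):
        self.samples = list(samples)
        self._mats: dict[str, np.ndarray] = {}
        self._index: dict[str, dict[str, int]] = {}
        for source, df in frames.items():
            cols = [s for s in self.samples if s in set(df.columns)]
            if len(cols) != len(self.samples):
                raise ValueError(f"signal source {source!r} is missing samples")
            mat = df[self.samples].to_numpy(dtype=float)
            mat = np.where(np.isfinite(mat), mat, 0.0)
            self._mats[source] = mat
            self._index[source] = {g: i for i, g in enumerate(df.index)}

    def values(self, gene: str, source: str) -> np.ndarray | None:
        idx = self._index.get(source, {}).get(gene)
        if idx is None:
            return None
        return self._mats[source][idx]

    def sources_for(self, gene: str) -> list[str]:
        return [s for s in SOURCES if s in self._index and gene in self._index[s]]


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd


def _module_sample_stats(X: np.ndarray, X2: np.ndarray, member_idx: Sequence[int]):
    """Per-sample (count, sum, sum-of-squares) pooled over the module's genes."""
    sub = X[list(member_idx)]
    fin = np.isfinite(sub)
    cnt = fin.sum(axis=0).astype(float)
    s = np.where(fin, sub, 0.0).sum(axis=0)
    ss = np.where(fin, X2[list(member_idx)], 0.0).sum(axis=0)
    return cnt, s, ss


# ---------------------------------------------------------------------------
# split search


def best_split(
    stats: tuple[np.ndarray, np.ndarray, np.ndarray],
    node_idx: np.ndarray,
    candidates: Sequence[str],
    signals: SignalSet,
    prior: NGPrior,
    penalty: float,
    min_leaf: int,
    expr_banned: frozenset = frozenset(),
) -> tuple[str, str, float, float] | None:
    """Best (modulator, source, threshold, gain) over all candidate splits.

    Enumerates, per candidate and per available signal source, the midpoints
    between consecutive distinct signal values (for a binary mutation signal
    this is exactly the 0.5 threshold).  Gain is
    ``score(left) + score(right) - score(node) - penalty``; returns None when
    no split has positive gain.  Ties break toward the earlier candidate,
    earlier source, lower threshold.

    ``expr_banned`` lists genes whose *expression* signal may not be used
    (their CNV/mutation signals remain allowed): a module member splitting
    its own module on its expression would be self-explanatory, but a
    member's genomic aberration is a legitimate cis-driver parent.
    """
    cnt, s, ss = stats
    n_node = len(node_idx)
    c_n = cnt[node_idx]
    c_s = s[node_idx]
    c_ss = ss[node_idx]
    tot = (c_n.sum(), c_s.sum(), c_ss.sum())
    s0 = _ng_scalar(*tot, prior)
    best: tuple[str, str, float, float] | None = None
    best_gain = _GAIN_TOL
    for gene in candidates:
        for source in SOURCES:
            if source == "expression" and gene in expr_banned:
                continue
            sig = signals.values(gene, source)
            if sig is None:
                continue
            sv = sig[node_idx]
            order = np.argsort(sv, kind="stable")
            ssv = sv[order]
            bounds = np.nonzero(np.diff(ssv) > 0)[0]
            if bounds.size == 0:
                continue
            nl = bounds + 1
            valid = (nl >= min_leaf) & (n_node - nl >= min_leaf)
            if not valid.any():
                continue
            pc = np.cumsum(c_n[order])
            ps = np.cumsum(c_s[order])
            pss = np.cumsum(c_ss[order])
            ln, lsum, lss = pc[bounds], ps[bounds], pss[bounds]
            gains = (
                _ng_from_stats(ln, lsum, lss, prior)
                + _ng_from_stats(tot[0] - ln, tot[1] - lsum, tot[2] - lss, prior)
                - s0
                - penalty
            )
            gains = np.where(valid, gains, -np.inf)
            i = int(np.argmax(gains))
            if gains[i] > best_gain + 1e-12:
                thr = 0.5 * (ssv[bounds[i]] + ssv[bounds[i] + 1])
                best = (gene, source, float(thr), float(gains[i]))
                best_gain = float(gains[i])
    return best


def learn_tree(
    stats: tuple[np.ndarray, np.ndarray, np.ndarray],
    sample_idx: np.ndarray,
    candidates: Sequence[str],
    signals: SignalSet,
    prior: NGPrior,
    cfg: ModuleNetworkConfig,
    expr_banned: frozenset = frozenset(),
) -> RegulatoryTree:
    """Greedy top-down tree search; deterministic given its inputs."""

    def grow(node_idx: np.ndarray, depth: int) -> TreeNode:
        if depth >= cfg.max_depth or len(node_idx) < 2 * cfg.min_leaf:
            return TreeNode(samples=node_idx)
        sp = best_split(stats, node_idx, candidates, signals, prior, cfg.penalty, cfg.min_leaf, expr_banned)
        if sp is None:
            return TreeNode(samples=node_idx)
        gene, source, thr, _ = sp
        sv = signals.values(gene, source)[node_idx]
        left_idx = node_idx[sv <= thr]
        right_idx = node_idx[sv > thr]
        return TreeNode(
            modulator=gene,
            source=source,
            threshold=thr,
            left=grow(left_idx, depth + 1),
            right=grow(right_idx, depth + 1),
        )

    return RegulatoryTree(root=grow(np.asarray(sample_idx), 0))


def tree_score(
    tree: RegulatoryTree,
    stats: tuple[np.ndarray, np.ndarray, np.ndarray],
    prior: NGPrior,
    penalty: float,
) -> float:
    """Sum of leaf scores minus the per-split complexity penalty."""
    cnt, s, ss = stats
    total = 0.0
    for leaf in tree.leaves():
        total += _ng_scalar(cnt[leaf].sum(), s[leaf].sum(), ss[leaf].sum(), prior)
    return total - penalty * tree.n_splits


# ---------------------------------------------------------------------------
# modules


def init_modules(
    expr: pd.DataFrame,
    k: int | None = None,
    seed: int = 0,
    target_module_size: int = 20,
) -> dict[str, int]:
    """Initial co-expression modules by k-means on z-scored gene profiles.

    ``k`` defaults to ``ceil(n_genes / target_module_size)``; empty clusters
    are dropped (cluster ids are compacted).  Deterministic under ``seed``.
    """
    genes = list(expr.index)
    n = len(genes)
    if k is None:
        k = max(1, math.ceil(n / target_module_size))
    if k > n:
        logger.warning("k=%d exceeds %d genes; reducing", k, n)
        k = n
    Xz = _zscore_rows(expr.to_numpy(dtype=float))
    Xz = np.where(np.isfinite(Xz), Xz, 0.0)
    if k == 1:
        return {g: 0 for g in genes}
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(Xz)
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for g, lab in zip(genes, raw):
        if lab not in remap:
            remap[lab] = len(remap)
        out[g] = remap[lab]
    return out


def init_modulator_association(
    modules: dict[int, list[int]],
    candidates: Sequence[str],
    signals: SignalSet,
    module_stats: dict[int, tuple],
    all_samples: np.ndarray,
    prior: NGPrior,
    cfg: ModuleNetworkConfig,
    member_names: dict[int, set[str]] | None = None,
) -> dict[int, list[str]]:
    """Assign each candidate to the module where its best single split gains most.

    Every candidate lands somewhere (ties and no-gain cases fall to the
    lowest module id); each module's list is gain-ordered; modules that end
    up empty receive the globally strongest ``cfg.fallback_k`` candidates.
    A candidate belonging to a module may not use its expression signal on
    that module (see :func:`best_split`).
    """
    mids = sorted(modules)
    member_names = member_names or {}
    per_module: dict[int, list[tuple[float, str]]] = {m: [] for m in mids}
    global_best: list[tuple[float, str]] = []
    for gene in candidates:
        gains = []
        for mid in mids:
            banned = frozenset([gene]) if gene in member_names.get(mid, set()) else frozenset()
            sp = best_split(module_stats[mid], all_samples, [gene], signals, prior, cfg.penalty, cfg.min_leaf, banned)
            gains.append(sp[3] if sp is not None else 0.0)
        best_i = int(np.argmax(gains))  # first max -> lowest module id
        per_module[mids[best_i]].append((gains[best_i], gene))
        global_best.append((max(gains), gene))
    out: dict[int, list[str]] = {}
    for mid in mids:
        ranked = sorted(per_module[mid], key=lambda t: (-t[0], t[1]))
        out[mid] = [g for _, g in ranked]
    if candidates:
        fallback = [g for _, g in sorted(global_best, key=lambda t: (-t[0], t[1]))[: cfg.fallback_k]]
        for mid in mids:
            if not out[mid]:
                out[mid] = list(fallback)
    return out


def assign_genes(
    X: np.ndarray,
    X2: np.ndarray,
    modules: dict[int, list[int]],
    trees: dict[int, RegulatoryTree],
    prior: NGPrior,
) -> tuple[dict[int, list[int]], int]:
    """One sequential pass of exact gene reassignment.

    Each gene moves to the module whose current tree maximizes the gene's
    incremental contribution to the pooled leaf scores (computed by removing
    the gene from its module and re-adding it to each receiving pool), so
    the total score cannot decrease.  Empty modules are dropped.
    """
    mids = sorted(modules)
    leaf_sets = {m: trees[m].leaves() for m in mids}
    n_genes = X.shape[0]
    # static per-gene per-leaf stats
    gstats: dict[int, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for m in mids:
        per_leaf = []
        for leaf in leaf_sets[m]:
            sub = X[:, leaf]
            fin = np.isfinite(sub)
            per_leaf.append(
                (
                    fin.sum(axis=1).astype(float),
                    np.where(fin, sub, 0.0).sum(axis=1),
                    np.where(fin, X2[:, leaf], 0.0).sum(axis=1),
                )
            )
        gstats[m] = per_leaf
    # current pooled stats per module leaf
    pools: dict[int, list[list[float]]] = {}
    member_of = np.empty(n_genes, dtype=int)
    for m in mids:
        for g in modules[m]:
            member_of[g] = m
        pools[m] = []
        for cnt, s, ss in gstats[m]:
            members = modules[m]
            pools[m].append([float(cnt[members].sum()), float(s[members].sum()), float(ss[members].sum())])
    n_moved = 0
    new_modules: dict[int, list[int]] = {m: [] for m in mids}
    for g in range(n_genes):
        cur = int(member_of[g])
        # remove from current pools
        for li, (cnt, s, ss) in enumerate(gstats[cur]):
            p = pools[cur][li]
            p[0] -= cnt[g]
            p[1] -= s[g]
            p[2] -= ss[g]
        best_m, best_delta, cur_delta = cur, -np.inf, -np.inf
        for m in mids:
            delta = 0.0
            for li, (cnt, s, ss) in enumerate(gstats[m]):
                p = pools[m][li]
                if cnt[g] > 0:
                    delta += _ng_scalar(p[0] + cnt[g], p[1] + s[g], p[2] + ss[g], prior) - _ng_scalar(
                        p[0], p[1], p[2], prior
                    )
            if m == cur:
                cur_delta = delta
            if delta > best_delta + _GAIN_TOL:
                best_m, best_delta = m, delta
        if best_delta <= cur_delta + _GAIN_TOL:
            best_m = cur  # prefer staying put on ties
        if best_m != cur:
            n_moved += 1
        for li, (cnt, s, ss) in enumerate(gstats[best_m]):
            p = pools[best_m][li]
            p[0] += cnt[g]
            p[1] += s[g]
            p[2] += ss[g]
        new_modules[best_m].append(g)
    new_modules = {m: gs for m, gs in new_modules.items() if gs}
    return new_modules, n_moved


# ---------------------------------------------------------------------------
# network containers


@dataclass
class ModuleNetwork:
    """Final module assignment, per-module trees and the score trace."""

    modules: dict[int, list[str]]
    trees: dict[int, RegulatoryTree]
    total_score: float
    trace: list[float]
    samples: list[str]

    @property
    def assignment(self) -> dict[str, int]:
        return {g: m for m, gs in self.modules.items() for g in gs}

    def to_dict(self) -> dict:
        return {
            "total_score": self.total_score,
            "trace": self.trace,
            "samples": self.samples,
            "modules": {
                str(m): {"genes": gs, "tree": self.trees[m].to_dict(self.samples)} for m, gs in self.modules.items()
            },
        }


@dataclass
class ModulatorRanking:
    """Modulator usage across the final network, strongest first."""

    table: pd.DataFrame  # index gene; columns n_modules_split, n_modules_root, score_contribution
    root_only: bool = False

    @property
    def modulators(self) -> list[str]:
        if self.root_only:
            return list(self.table.index[self.table["n_modules_root"] > 0])
        return list(self.table.index)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


def _rank_modulators(
    network_modules: dict[int, list[int]],
    trees: dict[int, RegulatoryTree],
    module_stats: dict[int, tuple],
    gene_names: Sequence[str],
    prior: NGPrior,
    cfg: ModuleNetworkConfig,
) -> ModulatorRanking:
    rows: dict[str, dict[str, float]] = {}

    def node_eval(node: TreeNode, stats) -> tuple[float, float, float]:
        # local gain per split: leaf(left) + leaf(right) - leaf(node) - penalty;
        # these sum to (tree score - single-leaf score) over the whole tree
        cnt, s, ss = stats
        if node.is_leaf:
            return (float(cnt[node.samples].sum()), float(s[node.samples].sum()), float(ss[node.samples].sum()))
        lt = node_eval(node.left, stats)
        rt = node_eval(node.right, stats)
        tot = (lt[0] + rt[0], lt[1] + rt[1], lt[2] + rt[2])
        gain = _ng_scalar(*lt, prior) + _ng_scalar(*rt, prior) - _ng_scalar(*tot, prior) - cfg.penalty
        rec = rows.setdefault(node.modulator, {"n_modules_split": 0.0, "n_modules_root": 0.0, "score_contribution": 0.0})
        rec["score_contribution"] += gain
        return tot

    for mid, tree in trees.items():
        seen_here: set[str] = set()
        node_eval(tree.root, module_stats[mid])
        for sp in tree.splits():
            g = sp["modulator"]
            if g not in seen_here:
                rows[g]["n_modules_split"] += 1
                seen_here.add(g)
            if sp["is_root"]:
                rows[g]["n_modules_root"] += 1
    if rows:
        table = pd.DataFrame(rows).T
        table = table.sort_values(["score_contribution", "n_modules_split"], ascending=False)
        table = table.astype({"n_modules_split": int, "n_modules_root": int})
    else:
        table = pd.DataFrame(columns=["n_modules_split", "n_modules_root", "score_contribution"])
    table.index.name = "gene"
    return ModulatorRanking(table=table, root_only=cfg.root_only)


# ---------------------------------------------------------------------------
# the learner


def learn_network(
    bundle: "OmicsBundle",
    selected_genes: Sequence[str],
    candidates: Sequence[str],
    cfg: ModuleNetworkConfig | None = None,
) -> tuple[ModuleNetwork, ModulatorRanking]:
    """Learn the module network over ``selected_genes`` of the bundle.

    Candidate modulators may split on their expression (z-scored), gene-level
    CNV log2 ratio, or mutation indicator, whichever the bundle provides.  A
    candidate never splits its own module.  The learner alternates per-module
    tree search with sequential gene reassignment until no gene moves or
    ``cfg.max_iter`` is reached; the score trace is non-decreasing (asserted).
    """
    cfg = cfg or ModuleNetworkConfig()
    prior = cfg.prior
    samples = bundle.samples
    member_genes = [g for g in selected_genes if g in set(bundle.expr.index)]
    if not member_genes:
        raise ValueError("no selected gene present in the expression matrix")
    expr = bundle.expr.loc[member_genes, samples]
    X = _zscore_rows(expr.to_numpy(dtype=float))
    X2 = np.where(np.isfinite(X), X * X, np.nan)
    gene_pos = {g: i for i, g in enumerate(member_genes)}

    zfull = pd.DataFrame(
        _zscore_rows(bundle.expr[samples].to_numpy(dtype=float)), index=bundle.expr.index, columns=samples
    )
    signals = SignalSet({"expression": zfull, "cnv": bundle.cnv[samples], "mutation": bundle.mut[samples]}, samples)
    candidates = [c for c in candidates if signals.sources_for(c)]
    if cfg.max_candidates is not None:
        candidates = candidates[: cfg.max_candidates]

    assign0 = init_modules(expr, k=cfg.n_modules, seed=cfg.seed, target_module_size=cfg.target_module_size)
    modules: dict[int, list[int]] = {}
    for g, m in assign0.items():
        modules.setdefault(m, []).append(gene_pos[g])
    all_samples = np.arange(len(samples))

    def stats_for(mods: dict[int, list[int]]) -> dict[int, tuple]:
        return {m: _module_sample_stats(X, X2, gs) for m, gs in mods.items()}

    module_stats = stats_for(modules)
    member_names = {m: {member_genes[i] for i in gs} for m, gs in modules.items()}
    assoc = init_modulator_association(
        modules, list(candidates), signals, module_stats, all_samples, prior, cfg, member_names
    )

    trees: dict[int, RegulatoryTree] = {}
    trace: list[float] = []
    prev_total = -np.inf
    seen_assignments: set[tuple] = set()
    best_state = None
    for iteration in range(cfg.max_iter):
        # tree step: relearn greedily, keep the previous tree when it scores higher
        for mid, member_idx in modules.items():
            member_set = {member_genes[i] for i in member_idx}
            cand = list(assoc.get(mid, []))
            banned = frozenset(member_set)  # members may not self-explain via expression
            new_tree = learn_tree(module_stats[mid], all_samples, cand, signals, prior, cfg, banned)
            if mid in trees:
                old_sc = tree_score(trees[mid], module_stats[mid], prior, cfg.penalty)
                new_sc = tree_score(new_tree, module_stats[mid], prior, cfg.penalty)
                if new_sc >= old_sc:
                    trees[mid] = new_tree
            else:
                trees[mid] = new_tree
        trees = {m: t for m, t in trees.items() if m in modules}
        total = sum(tree_score(trees[m], module_stats[m], prior, cfg.penalty) for m in modules)
        assert total >= prev_total - 1e-6, "network score decreased in tree step"
        trace.append(total)
        prev_total = total

        new_modules, n_moved = assign_genes(X, X2, modules, trees, prior)
        modules = new_modules
        module_stats = stats_for(modules)
        total = sum(tree_score(trees[m], module_stats[m], prior, cfg.penalty) for m in modules)
        assert total >= prev_total - 1e-6, "network score decreased in assignment step"
        trace.append(total)
        prev_total = total
        if best_state is None or total >= best_state[0]:
            best_state = (total, {m: list(g) for m, g in modules.items()}, dict(trees))
        if n_moved == 0:
            break
        key = tuple(sorted((m, tuple(sorted(gs))) for m, gs in modules.items()))
        if key in seen_assignments:
            logger.warning("module assignment cycled; stopping at best-scoring iterate")
            total, modules, trees = best_state
            module_stats = stats_for(modules)
            break
        seen_assignments.add(key)

    named_modules = {m: [member_genes[i] for i in gs] for m, gs in modules.items()}
    network = ModuleNetwork(
        modules=named_modules,
        trees={m: trees[m] for m in modules},
        total_score=float(prev_total),
        trace=trace,
        samples=list(samples),
    )
    ranking = _rank_modulators(modules, network.trees, module_stats, member_genes, prior, cfg)
    return network, ranking
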