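"""Structural statistics of bipartite networks.

Implements the metric set reported for every weekly/annual network: size
(plants, insects, links), binary and weighted connectance, binary and
weighted NODF nestedness, and Barber's bipartite modularity Q maximized by
a seeded multi-restart local search. Pollen-transport networks are analysed
with binary measures only, because interaction "strength" means something
different there (individuals carrying pollen) than in visitation webs
(visit counts).

Undefined metrics (e.g. NODF on a 1x1 web) are reported as ``None``, never
as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .networks import BipartiteNetwork

__all__ = [
    "MetricSet",
    "UndefinedMetric",
    "connectance_binary",
    "connectance_weighted",
    "nodf_binary",
    "nodf_weighted",
    "modularity",
    "barber_q",
    "exhaustive_modularity",
    "metric_set",
    "METRIC_FUNCS",
]


class UndefinedMetric(ValueError):
    """The metric is not defined on this network (e.g. empty, or both sides
    singleton for NODF)."""


@dataclass
class MetricSet:
    period: str
    provenance: str
    n_plants: int
    n_insects: int
    n_links: int
    connectance_bin: float | None = None
    connectance_wt: float | None = None
    nodf_bin: float | None = None
    nodf_wt: float | None = None
    modularity_q: float | None = None
    module_assignment: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "provenance": self.provenance,
            "n_plants": self.n_plants,
            "n_insects": self.n_insects,
            "n_links": self.n_links,
            "connectance_bin": self.connectance_bin,
            "connectance_wt": self.connectance_wt,
            "nodf_bin": self.nodf_bin,
            "nodf_wt": self.nodf_wt,
            "modularity_q": self.modularity_q,
        }


def _pruned(net: BipartiteNetwork) -> BipartiteNetwork:
    if net.n_plants == 0 or net.n_insects == 0:
        raise UndefinedMetric("empty network")
    return net if net.is_pruned() else net.pruned()


# ---------------------------------------------------------------------------
# connectance

def connectance_binary(net: BipartiteNetwork) -> float:
    """Realized fraction of possible links, L/(P*A), over species present in
    the period (phenologically forbidden links excluded from the pool)."""
    net = _pruned(net)
    return net.n_links / (net.n_plants * net.n_insects)


def connectance_weighted(net: BipartiteNetwork) -> float:
    """Weighted connectance: entropy-based linkage density / (P + A).

    Linkage density LD = 1/2 [ sum_j (m_.j/m) e^{H_j} + sum_i (m_i./m) e^{H_i} ]
    where H is the natural-log Shannon entropy of a species' interaction
    weight distribution; e^H is its effective number of partners.
    """
    net = _pruned(net)
    w = net.weights
    m = w.sum()
    if m <= 0:
        raise UndefinedMetric("zero total weight")
    ld = 0.0
    for marg, axis in ((w.sum(axis=1), 1), (w.sum(axis=0), 0)):
        p = w / marg[:, None] if axis == 1 else w / marg[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        h = -plogp.sum(axis=axis)
        ld += 0.5 * float((marg / m * np.exp(h)).sum())
    return ld / (net.n_plants + net.n_insects)


# ---------------------------------------------------------------------------
# NODF

def _nodf_side_binary(mat: np.ndarray) -> tuple[float, int]:
    """Summed pair contributions and pair count over the rows of ``mat``."""
    n = mat.shape[0]
    if n < 2:
        return 0.0, 0
    fills = mat.sum(axis=1)
    shared = mat @ mat.T
    fi = fills[:, None]
    fj = fills[None, :]
    poorer = np.minimum(fi, fj)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where((fi != fj) & (poorer > 0), 100.0 * shared / poorer, 0.0)
    iu = np.triu_indices(n, k=1)
    return float(contrib[iu].sum()), len(iu[0])


def nodf_binary(net: BipartiteNetwork) -> float:
    """NODF: mean pairwise overlap percentage under strictly decreasing fill,
    averaged over all row pairs and column pairs (0-100)."""
    net = _pruned(net)
    if net.n_plants < 2 and net.n_insects < 2:
        raise UndefinedMetric("NODF needs >= 2 species on at least one side")
    b = net.binary()
    s_rows, n_rows = _nodf_side_binary(b)
    s_cols, n_cols = _nodf_side_binary(b.T)
    return (s_rows + s_cols) / (n_rows + n_cols)


def _nodf_side_weighted(w: np.ndarray) -> tuple[float, int]:
    n = w.shape[0]
    if n < 2:
        return 0.0, 0
    totals = w.sum(axis=1)
    fills = (w > 0).sum(axis=1)
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            if totals[a] == totals[b]:
                continue
            rich, poor = (a, b) if totals[a] > totals[b] else (b, a)
            if fills[poor] == 0:
                continue
            dominated = int(np.sum((w[poor] > 0) & (w[poor] < w[rich])))
            total += 100.0 * dominated / fills[poor]
    return total, n * (n - 1) // 2


def nodf_weighted(net: BipartiteNetwork) -> float:
    """Weighted NODF: pair contribution counts partners where the poorer
    species' weight is positive but strictly below the richer species'
    weight, taken only when the poorer side's marginal total is strictly
    smaller; ties contribute zero."""
    net = _pruned(net)
    if net.n_plants < 2 and net.n_insects < 2:
        raise UndefinedMetric("NODF needs >= 2 species on at least one side")
    s_rows, n_rows = _nodf_side_weighted(net.weights)
    s_cols, n_cols = _nodf_side_weighted(net.weights.T)
    return (s_rows + s_cols) / (n_rows + n_cols)


# ---------------------------------------------------------------------------
# Barber bipartite modularity

def barber_q(net: BipartiteNetwork, plant_labels: np.ndarray, insect_labels: np.ndarray) -> float:
    """Barber's bipartite modularity of a given partition.

    Q = (1/m) sum_{p,i} [w_pi - s_p t_i / m] delta(g_p, g_i), with s and t
    the plant and insect marginal totals and m the total weight.
    """
    return barber_q_from_labels(
        net.weights, np.asarray(plant_labels), np.asarray(insect_labels)
    )


def _local_search(w: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> float:
    """Greedy node-move + module-merge hill climbing on Barber Q in place."""
    n_p, n_i = w.shape
    m = w.sum()
    s = w.sum(axis=1)  # plant strengths
    t = w.sum(axis=0)  # insect strengths
    n = n_p + n_i

    def aggregates():
        k = labels.max() + 1
        s_c = np.bincount(labels[:n_p], weights=s, minlength=k)
        t_c = np.bincount(labels[n_p:], weights=t, minlength=k)
        w_c = np.zeros(k)
        for c in range(k):
            w_c[c] = w[np.ix_(labels[:n_p] == c, labels[n_p:] == c)].sum()
        return s_c, t_c, w_c

    improved = True
    while improved:
        improved = False
        s_c, t_c, w_c = aggregates()
        k = len(s_c)
        # node moves (allow moving to a fresh empty module)
        for node in rng.permutation(n):
            a = labels[node]
            if node < n_p:
                link = np.bincount(labels[n_p:], weights=w[node], minlength=k + 1)
                strength, other_tot = s[node], np.append(t_c, 0.0)
            else:
                link = np.bincount(labels[:n_p], weights=w[:, node - n_p], minlength=k + 1)
                strength, other_tot = t[node - n_p], np.append(s_c, 0.0)
            dq = (link - link[a]) / m - strength * (other_tot - other_tot[a]) / m**2
            best = int(np.argmax(dq))
            if dq[best] > 1e-13 and best != a:
                labels[node] = best
                s_c, t_c, w_c = aggregates()
                k = len(s_c)
                improved = True
        # module merges
        k = labels.max() + 1
        s_c, t_c, w_c = aggregates()
        for a in range(k):
            for b in range(a + 1, k):
                pa, pb = labels[:n_p] == a, labels[:n_p] == b
                ia, ib = labels[n_p:] == a, labels[n_p:] == b
                cross = w[np.ix_(pa, ib)].sum() + w[np.ix_(pb, ia)].sum()
                dq = cross / m - (s_c[a] * t_c[b] + s_c[b] * t_c[a]) / m**2
                if dq > 1e-13:
                    labels[labels == b] = a
                    improved = True
                    break
            else:
                continue
            break
        # compact labels
        _, labels[:] = np.unique(labels, return_inverse=True)
    full_q = barber_q_from_labels(w, labels[:n_p], labels[n_p:])
    return full_q


def barber_q_from_labels(w: np.ndarray, pl: np.ndarray, il: np.ndarray) -> float:
    m = w.sum()
    s = w.sum(axis=1)
    t = w.sum(axis=0)
    q = 0.0
    for c in np.unique(np.concatenate([pl, il])):
        pc = pl == c
        ic = il == c
        q += w[np.ix_(pc, ic)].sum() / m - s[pc].sum() * t[ic].sum() / m**2
    return float(q)


def modularity(
    net: BipartiteNetwork, restarts: int = 20, seed: int | np.random.Generator = 0
) -> tuple[float, dict[str, int]]:
    """Maximize Barber's Q over partitions by seeded multi-restart local
    search (random initial labellings, greedy node moves and module merges).

    Returns the best Q found and its module assignment keyed
    ``"plant:<name>"`` / ``"insect:<name>"``. The heuristic never exceeds
    the exhaustive optimum (it only evaluates valid partitions).
    """
    net = _pruned(net)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = net.n_plants + net.n_insects
    best_q = -np.inf
    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            labels = np.arange(n)  # singletons
        else:
            k = int(rng.integers(2, max(3, min(n, 10) + 1)))
            labels = rng.integers(0, k, size=n)
        _, labels = np.unique(labels, return_inverse=True)
        q = _local_search(net.weights, labels, rng)
        if q > best_q:
            best_q = q
            best = labels.copy()
    assignment = {f"plant:{p}": int(best[k]) for k, p in enumerate(net.plants)}
    assignment.update(
        {f"insect:{i}": int(best[net.n_plants + k]) for k, i in enumerate(net.insects)}
    )
    return float(best_q), assignment


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)
    yield labels.copy()
    while True:
        i = n - 1
        while i > 0 and labels[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]
        yield labels.copy()


def exhaustive_modularity(net: BipartiteNetwork, max_species: int = 9) -> tuple[float, np.ndarray]:
    """Exact maximum Barber Q by enumerating every set partition of the
    species (feasible for <= 9 species; Bell(9) = 21147 partitions).

    Q is evaluated by the raw double sum, independently of the optimizer's
    aggregated bookkeeping.
    """
    net = _pruned(net)
    n = net.n_plants + net.n_insects
    if n > max_species:
        raise ValueError(f"exhaustive search limited to {max_species} species, got {n}")
    w = net.weights
    m = w.sum()
    s = w.sum(axis=1)
    t = w.sum(axis=0)
    b_mod = w - np.outer(s, t) / m  # modularity matrix
    best_q, best = -np.inf, None
    for labels in _set_partitions(n):
        same = labels[: net.n_plants, None] == labels[None, net.n_plants :]
        q = float((b_mod * same).sum() / m)
        if q > best_q:
            best_q, best = q, labels.copy()
    return best_q, best


# ---------------------------------------------------------------------------
# metric sets

def _try(func, net):
    try:
        return func(net)
    except UndefinedMetric:
        return None


METRIC_FUNCS = {
    "connectance_bin": connectance_binary,
    "connectance_wt": connectance_weighted,
    "nodf_bin": nodf_binary,
    "nodf_wt": nodf_weighted,
}


def metric_set(
    net: BipartiteNetwork,
    mode: str = "full",
    restarts: int = 20,
    seed: int | np.random.Generator = 0,
) -> MetricSet:
    """All structural statistics of one network.

    ``mode="binary_only"`` omits the weighted connectance/NODF variants;
    pollen-transport provenance forces binary_only (with a warning if full
    was requested). Undefined metrics propagate as ``None`` without
    aborting the rest of the set.
    """
    if mode not in ("full", "binary_only"):
        raise ValueError(f"unknown mode {mode!r}")
    net = _pruned(net)
    if net.provenance == "pollen" and mode == "full":
        warnings.warn(
            "pollen-transport networks are analysed with binary metrics only; "
            "coercing mode to binary_only",
            stacklevel=2,
        )
        mode = "binary_only"
    ms = MetricSet(
        period=net.period,
        provenance=net.provenance,
        n_plants=net.n_plants,
        n_insects=net.n_insects,
        n_links=net.n_links,
    )
    ms.connectance_bin = _try(connectance_binary, net)
    ms.nodf_bin = _try(nodf_binary, net)
    if mode == "full":
        ms.connectance_wt = _try(connectance_weighted, net)
        ms.nodf_wt = _try(nodf_weighted, net)
    try:
        ms.modularity_q, ms.module_assignment = modularity(net, restarts=restarts, seed=seed)
    except UndefinedMetric:
        ms.modularity_q = None
    return ms
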