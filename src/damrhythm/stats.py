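"""Group comparison scheme: Bartlett gate, transformation ladder, ANOVA +
Tukey or Kruskal-Wallis + Dunn, and compact letter displays.

The decision scheme mirrors common practice in behavioural chronobiology:
test homoscedasticity with Bartlett's test; if it fails, try a ladder of
variance-stabilizing transforms (log(x+1), square root, arcsine-square-root
for proportions); if no transform restores homoscedasticity, fall back to
the non-parametric Kruskal-Wallis omnibus with Dunn's pairwise test.
Pairwise outcomes are rendered as compact letters: two groups share a
letter iff their difference is not significant at the chosen alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GateResult",
    "ComparisonResult",
    "variance_gate",
    "compare_groups",
    "compact_letters",
    "dunn_test",
]

TRANSFORMS = {
    "none": lambda x: x,
    "log": lambda x: np.log(x + 1.0),
    "sqrt": np.sqrt,
    "arcsine": lambda x: np.arcsin(np.sqrt(x)),
}
LADDER = ("none", "log", "sqrt", "arcsine")


@dataclass
class GateResult:
    """Outcome of the homoscedasticity gate."""

    path: str  # "parametric" | "nonparametric"
    transform: str  # member of LADDER ("none" when nonparametric)
    bartlett_p: dict[str, float] = field(default_factory=dict)


@dataclass
class ComparisonResult:
    """One parameter's omnibus test, pairwise matrix and letter display."""

    parameter: str
    groups: list[str]
    n: dict[str, int]
    test_used: str  # "anova" | "kruskal_wallis"
    transform_used: str
    statistic: float  # F or H (chi-square approx)
    df: tuple
    p_value: float
    pairwise_p: np.ndarray | None  # symmetric, NaN diagonal
    letters: dict[str, str] | None
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        if self.pairwise_p is None:
            return []
        out = []
        for i, j in itertools.combinations(range(len(self.groups)), 2):
            if self.pairwise_p[i, j] < self.alpha:
                out.append((self.groups[i], self.groups[j]))
        return out


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]  # undefined values dropped listwise
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        clean[name] = arr
    return clean


def variance_gate(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GateResult:
    """Pick the analysis path: first transform passing Bartlett, else KW.

    The arcsine transform is only attempted when every observation lies in
    [0, 1] (it is meant for proportions, never raw counts).
    """
    clean = _check_groups(groups)
    ps: dict[str, float] = {}
    in_unit = all(np.all((v >= 0) & (v <= 1)) for v in clean.values())
    nonneg = all(np.all(v >= 0) for v in clean.values())
    for name in LADDER:
        if name == "arcsine" and not in_unit:
            continue
        if name in ("log", "sqrt") and not nonneg:
            continue
        transformed = [TRANSFORMS[name](v) for v in clean.values()]
        if any(np.ptp(t) == 0 for t in transformed):
            ps[name] = 0.0  # Bartlett undefined on a constant group
            continue
        p = sps.bartlett(*transformed).pvalue
        ps[name] = float(p)
        if p > alpha:
            return GateResult(path="parametric", transform=name, bartlett_p=ps)
    return GateResult(path="nonparametric", transform="none", bartlett_p=ps)


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "holm") -> np.ndarray:
    """Dunn's rank-based pairwise test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12(N-1)); two-sided normal
    p-values are adjusted across pairs (Holm by default; any method
    accepted by statsmodels ``multipletests``, or "none").
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[i] * len(groups[g]) for i, g in enumerate(names)])
    ranks = sps.rankdata(pooled)
    n_tot = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    k = len(names)
    mean_ranks = np.array([ranks[labels == i].mean() for i in range(k)])
    sizes = np.array([np.sum(labels == i) for i in range(k)])
    raw = []
    pairs = list(itertools.combinations(range(k), 2))
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    if adjust == "none":
        adj = np.asarray(raw)
    else:
        adj = multipletests(raw, method=adjust)[1]
    pmat = np.full((k, k), np.nan)
    for (i, j), p in zip(pairs, adj):
        pmat[i, j] = pmat[j, i] = p
    return pmat


def _anova_pairwise_tukey(
    clean: dict[str, np.ndarray], transform: str, alpha: float
) -> tuple[float, tuple, float, np.ndarray]:
    names = list(clean)
    tvals = [TRANSFORMS[transform](v) for v in clean.values()]
    f, p = sps.f_oneway(*tvals)
    df = (len(names) - 1, sum(len(v) for v in tvals) - len(names))
    data = np.concatenate(tvals)
    labels = np.concatenate([[g] * len(v) for g, v in zip(names, tvals)])
    tk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    k = len(names)
    pmat = np.full((k, k), np.nan)
    for (g1, g2), padj in zip(
        itertools.combinations(tk.groupsunique, 2), tk.pvalues
    ):
        i, j = names.index(g1), names.index(g2)
        pmat[i, j] = pmat[j, i] = padj
    return float(f), df, float(p), pmat


def compare_groups(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    parameter: str = "",
    gate: GateResult | None = None,
    dunn_adjust: str = "holm",
    include_pairwise: bool = True,
) -> ComparisonResult:
    """Full comparison of one parameter across treatment groups.

    Non-finite observations (e.g. undefined PMI) are dropped listwise.
    ``include_pairwise=False`` skips the post-hoc test and letters (useful
    in large simulation studies that only need the omnibus decision).
    """
    clean = _check_groups(groups)
    names = list(clean)
    if gate is None:
        gate = variance_gate(clean, alpha=alpha)

    pmat: np.ndarray | None = None
    letters: dict[str, str] | None = None
    if gate.path == "parametric":
        if include_pairwise:
            stat, df, p, pmat = _anova_pairwise_tukey(clean, gate.transform, alpha)
        else:
            tvals = [TRANSFORMS[gate.transform](v) for v in clean.values()]
            stat, p = (float(x) for x in sps.f_oneway(*tvals))
            df = (len(names) - 1, sum(len(v) for v in tvals) - len(names))
        test = "anova"
        transform = gate.transform
    else:
        stat, p = (float(x) for x in sps.kruskal(*clean.values()))
        if include_pairwise:
            pmat = dunn_test(clean, adjust=dunn_adjust)
        df = (len(names) - 1,)
        test = "kruskal_wallis"
        transform = "none"

    if pmat is not None:
        sig = pmat < alpha
        np.fill_diagonal(sig, False)
        letter_list = compact_letters(sig)
        letters = dict(zip(names, letter_list))

    return ComparisonResult(
        parameter=parameter,
        groups=names,
        n={g: len(v) for g, v in clean.items()},
        test_used=test,
        transform_used=transform,
        statistic=stat,
        df=df,
        p_value=float(p),
        pairwise_p=pmat,
        letters=letters,
        alpha=alpha,
    )


def compact_letters(significant: np.ndarray) -> list[str]:
    """Minimal compact letter display from a pairwise significance matrix.

    Groups share >= 1 letter iff their pairwise difference is NOT
    significant.  Letters correspond to cliques of the non-significance
    graph; a minimal cover by maximal cliques is found exactly (group
    counts are small), so the display uses as few letters as possible.
    """
    sig = np.asarray(significant, dtype=bool)
    if sig.ndim != 2 or sig.shape[0] != sig.shape[1]:
        raise ValueError("significance matrix must be square")
    if not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric")
    k = sig.shape[0]
    nonsig = ~sig
    np.fill_diagonal(nonsig, True)

    # maximal cliques of the non-significance graph (Bron-Kerbosch)
    adj = [set(np.flatnonzero(nonsig[i])) - {i} for i in range(k)]
    cliques: list[frozenset[int]] = []

    def bron_kerbosch(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in list(p - adj[pivot]):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    bron_kerbosch(set(), set(range(k)), set())

    # required: every non-significant pair inside some chosen clique, every
    # group in >= 1 clique; find the smallest subset of maximal cliques
    need_pairs = {
        (i, j) for i in range(k) for j in range(i + 1, k) if nonsig[i, j]
    }
    groups_all = set(range(k))
    best: list[frozenset[int]] | None = None
    for size in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, size):
            covered = {
                (i, j)
                for c in combo
                for i, j in itertools.combinations(sorted(c), 2)
            }
            members = set().union(*combo)
            if need_pairs <= covered and members == groups_all:
                best = list(combo)
                break
        if best is not None:
            break
    assert best is not None  # the full maximal-clique set always covers

    # order letters by the first group they contain
    best.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for i in range(k):
        out.append("".join(alphabet[ci] for ci, c in enumerate(best) if i in c))
    return out
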