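"""Leaf-trait stage: do the a-priori plant functional types hold up?

Two complementary checks on a species x trait table (SLA, toughness, %N,
C:N, %lignin, Si) labelled with the five functional types (giant graminoids
GG, evergreen shrubs ES, evergreen trees ET, deciduous shrubs DS, deciduous
trees DT):

1. per-trait one-way ANOVA on log-transformed values, followed by
   Tukey-Kramer HSD pairwise comparisons (unequal group sizes) with a
   compact letter display;
2. unsupervised K-means over the standardized log-trait matrix with the
   elbow rule on within-cluster sum of squares, cross-tabulated against the
   a-priori grouping.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "TRAIT_COLUMNS",
    "PFT_LABELS",
    "AnovaResult",
    "TukeyPair",
    "TukeyTable",
    "ClusterResult",
    "ElbowResult",
    "log_transform_traits",
    "anova_oneway",
    "tukey_hsd",
    "kmeans_elbow",
    "trait_anova_table",
]

TRAIT_COLUMNS = ["SLA", "toughness", "N_mass", "CN", "lignin", "Si"]
PFT_LABELS = ["GG", "ES", "ET", "DS", "DT"]


def log_transform_traits(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Natural-log transform every trait column; labels and index preserved.

    Raises ValueError naming species and trait for any nonpositive value.
    """
    if columns is None:
        columns = [c for c in TRAIT_COLUMNS if c in table.columns]
    out = table.copy()
    for col in columns:
        vals = pd.to_numeric(out[col])
        bad = vals.index[vals <= 0]
        if len(bad):
            raise ValueError(f"nonpositive {col} for species {list(bad)}: cannot log-transform")
        out[col] = np.log(vals)
    return out


@dataclass(frozen=True)
class AnovaResult:
    trait: str
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def _groups_as_arrays(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    return out


def anova_oneway(groups: dict[str, np.ndarray], trait: str = "") -> AnovaResult:
    """Classical one-way ANOVA from the between/within sum-of-squares split.

    ``groups`` maps group label to a 1-D array of observations. SS_total =
    SS_between + SS_within holds to numerical precision by construction.
    """
    groups = _groups_as_arrays(groups)
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(trait=trait, F=float(F), df_between=df_b, df_within=df_w,
                       p=p, ss_between=float(ss_between), ss_within=float(ss_within))


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float  # mean(a) - mean(b)
    q: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class TukeyTable:
    pairs: list[TukeyPair]
    letters: dict[str, str]
    alpha: float

    def pair(self, a: str, b: str) -> TukeyPair:
        for pr in self.pairs:
            if {pr.group_a, pr.group_b} == {a, b}:
                return pr
        raise KeyError((a, b))


def _compact_letters(groups: list[str], sig: dict[frozenset, bool]) -> dict[str, str]:
    # greedy insert-absorb: start from one all-groups letter set, split on
    # each significant pair, then drop sets contained in others
    sets: list[set[str]] = [set(groups)]
    for (a, b), is_sig in ((tuple(sorted(k)), v) for k, v in sig.items()):
        if not is_sig:
            continue
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                sets.extend([s - {a}, s - {b}])
        # absorb duplicates/subsets
        sets = [s for s in sets if not any(s < t for t in sets)]
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in s:
                letters[g] += ch
    return letters


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyTable:
    """Tukey-Kramer HSD for all pairwise comparisons with unequal group sizes.

    q_ij = |mean_i - mean_j| / sqrt( MSW/2 * (1/n_i + 1/n_j) ), with the
    adjusted p-value from the studentized range distribution on k groups and
    the within-group df. For two groups this reduces analytically to the
    pooled-variance t-test (q = sqrt(2) |t|).
    """
    groups = _groups_as_arrays(groups)
    labels = list(groups)
    k = len(labels)
    n_tot = sum(v.size for v in groups.values())
    df_w = n_tot - k
    msw = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values()) / df_w
    pairs: list[TukeyPair] = []
    sig: dict[frozenset, bool] = {}
    for a, b in itertools.combinations(labels, 2):
        va, vb = groups[a], groups[b]
        diff = va.mean() - vb.mean()
        if msw == 0:
            q = 0.0 if diff == 0 else np.inf
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
        signif = p_adj < alpha
        pairs.append(TukeyPair(a, b, float(diff), float(q), p_adj, signif))
        sig[frozenset((a, b))] = signif
    letters = _compact_letters(labels, sig)
    return TukeyTable(pairs=pairs, letters=letters, alpha=alpha)


@dataclass(frozen=True)
class ClusterResult:
    K: int
    assignments: np.ndarray
    wss: float
    bss: float
    tss: float

    @property
    def intra_pct(self) -> float:
        return 100.0 * self.wss / self.tss

    @property
    def inter_pct(self) -> float:
        return 100.0 * self.bss / self.tss


@dataclass(frozen=True)
class ElbowResult:
    per_k: dict[int, ClusterResult]
    k_star: int | None          # None when the elbow is degenerate (zero TSS)
    agreement: pd.DataFrame | None  # cross-tab clusters x a-priori labels

    @property
    def selected(self) -> ClusterResult | None:
        return None if self.k_star is None else self.per_k[self.k_star]


def kmeans_elbow(X, k_range: range = range(2, 6), *, labels=None,
                 restarts: int = 50, seed: int = 0, standardize: bool = True) -> ElbowResult:
    """Best-of-restarts K-means over ``k_range`` with elbow selection.

    The matrix is standardized column-wise (population SD) before clustering
    unless ``standardize=False``. The elbow K* maximises the second
    difference WSS(K-1) - 2 WSS(K) + WSS(K+1), using WSS(1) = TSS so the
    smallest K in the range is eligible. If a-priori ``labels`` are given,
    the result carries a clusters-by-labels cross-tabulation.
    """
    arr, _ = _matrix(X)
    n = arr.shape[0]
    ks = sorted(k_range)
    if ks[-1] >= n:
        raise ValueError("K_max must be smaller than the number of species")
    if standardize:
        sd = arr.std(axis=0)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=0)) / sd
    tss = float(np.sum((arr - arr.mean(axis=0)) ** 2))
    per_k: dict[int, ClusterResult] = {}
    wss_by_k = {1: tss}
    for K in ks:
        with warnings.catch_warnings():
            # duplicate-point inputs legitimately yield fewer distinct clusters
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            km = KMeans(n_clusters=K, n_init=restarts, random_state=seed).fit(arr)
        wss = float(km.inertia_)
        per_k[K] = ClusterResult(K=K, assignments=km.labels_.copy(), wss=wss,
                                 bss=tss - wss, tss=tss)
        wss_by_k[K] = wss
    if tss == 0:
        return ElbowResult(per_k=per_k, k_star=None, agreement=None)
    candidates = [K for K in ks if K + 1 in wss_by_k]  # need WSS at K-1, K, K+1
    second_diff = {K: wss_by_k[K - 1] - 2 * wss_by_k[K] + wss_by_k[K + 1] for K in candidates}
    k_star = max(candidates, key=lambda K: (second_diff[K], -K))
    agreement = None
    if labels is not None:
        agreement = pd.crosstab(
            pd.Series(per_k[k_star].assignments, name="cluster"),
            pd.Series(np.asarray(labels), name="pft"),
        )
    return ElbowResult(per_k=per_k, k_star=k_star, agreement=agreement)


def _matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.columns))
    return np.asarray(X, dtype=float), None


def trait_anova_table(traits: pd.DataFrame, *, pft_col: str = "pft",
                      columns: list[str] | None = None,
                      alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, TukeyTable]]:
    """Run the full per-trait stage: log-transform, ANOVA, Tukey letters.

    Returns an ANOVA summary DataFrame (one row per trait) and a dict of
    TukeyTable keyed by trait.
    """
    columns = columns or [c for c in TRAIT_COLUMNS if c in traits.columns]
    logged = log_transform_traits(traits, columns)
    rows = []
    tukeys: dict[str, TukeyTable] = {}
    for col in columns:
        groups = {g: sub[col].to_numpy() for g, sub in logged.groupby(pft_col, sort=False)}
        res = anova_oneway(groups, trait=col)
        tk = tukey_hsd(groups, alpha=alpha)
        tukeys[col] = tk
        rows.append({"trait": col, "F": res.F, "df_between": res.df_between,
                     "df_within": res.df_within, "p": res.p,
                     "letters": ";".join(f"{g}:{tk.letters[g]}" for g in groups)})
    return pd.DataFrame(rows), tukeys
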