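"""The full inference protocol linking environment blocks to functional types.

Stages, in order:

1. leaf-trait stage (ANOVA + Tukey letters, K-means elbow);
2. variable pruning: within each predictor block, correlated pairs
   (|r| > 0.85) lose their lower-VIP member, then blocks are trimmed to a
   target width (8) by dropping lowest-VIP variables;
3. multivariate-response models for the three blocks and their four
   combinations (climate C, soil S, physical P, C+S, C+P, S+P, C+S+P),
   separately for percent covers (arcsine-sqrt transformed) and Simpson
   diversities;
4. univariate models per response (5 covers + total canopy, 5 diversities
   + total diversity) on the pooled pruned predictors, with a VIP > 0.9 /
   top-15 prescreen;
5. leave-N-out resampling: sites split into 5 near-equal random groups,
   the model refit with each group omitted; the number of significant
   components N (mode and range) and the mean/SD of Q2, R2, VIP and
   standardized coefficients across folds summarise model robustness.

Models are significant when at least one component passes the Q2 > 0.097
entry rule. Variable selection (pruning, prescreening) is frozen from the
full-data model and reused inside folds, so the fold-wise VIP mean/SD
describes one fixed predictor set; scaling is refit per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import pls, schema, traits
from .indices import arcsine_sqrt
from .schema import BLOCKS, ENV_BLOCK_OF

__all__ = [
    "PipelineConfig",
    "CrossValSummary",
    "PipelineReport",
    "COMBO_LABELS",
    "partition_sites",
    "prune_correlated",
    "prescreen_vip",
    "lno_crossvalidate",
    "combination_models",
    "univariate_models",
    "run_pipeline",
]

#: Block combinations in reporting order.
COMBO_LABELS: dict[str, tuple[str, ...]] = {
    "C": ("climate",),
    "S": ("soil",),
    "P": ("physical",),
    "C+S": ("climate", "soil"),
    "C+P": ("climate", "physical"),
    "S+P": ("soil", "physical"),
    "C+S+P": ("climate", "soil", "physical"),
}

PFTS = ["GG", "ES", "ET", "DS", "DT"]
COVER_SET = [f"cover_{p}" for p in PFTS]
DIV_SET = [f"div_{p}" for p in PFTS]
UNIVARIATE_RESPONSES = COVER_SET + ["cover_total_canopy"] + DIV_SET + ["div_total"]


@dataclass
class PipelineConfig:
    """Analysis settings; defaults are the protocol defaults."""

    seed: int = 0
    r_threshold: float = 0.85
    target_width: int = 8
    q2_threshold: float = pls.Q2_SIGNIFICANCE
    n_groups: int = 5
    vip_cut: float = 0.9
    max_vars: int = 15
    combos: tuple[str, ...] = tuple(COMBO_LABELS)
    lno_eval: str = "internal"  # "internal" (LOO Q2 within training set) | "holdout"
    alpha: float = 0.05
    k_range: tuple[int, int] = (2, 5)
    kmeans_restarts: int = 50

    def validate(self) -> None:
        if self.target_width < 1:
            raise ValueError("target block width must be at least 1")
        bad = [c for c in self.combos if c not in COMBO_LABELS]
        if bad:
            raise ValueError(f"unknown block combination(s): {bad}")
        if not self.combos:
            raise ValueError("at least one block combination is required")
        if self.lno_eval not in ("internal", "holdout"):
            raise ValueError("lno_eval must be 'internal' or 'holdout'")


def partition_sites(n: int, n_groups: int, seed) -> list[np.ndarray]:
    """Seeded random split of range(n) into near-equal disjoint groups.

    Group sizes differ by at most one (e.g. 34 sites, 5 groups ->
    7/7/7/7/6).
    """
    if n_groups > n:
        raise ValueError("more groups than sites")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, extra = divmod(n, n_groups)
    groups, start = [], 0
    for g in range(n_groups):
        size = base + (1 if g < extra else 0)
        groups.append(np.sort(order[start:start + size]))
        start += size
    return groups


def _mode(values: Iterable[int]) -> int:
    vals, counts = np.unique(np.asarray(list(values)), return_counts=True)
    return int(vals[np.argmax(counts)])  # ties -> smallest value


def prune_correlated(env: pd.DataFrame, responses: pd.DataFrame,
                     r_threshold: float = 0.85, target_width: int = 8,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce each predictor block by collinearity and preliminary VIP.

    Within each block, while any pair has |Pearson r| > ``r_threshold``,
    the pair with the largest |r| loses its lower-VIP member (VIP from a
    one-component PLS of all responses on the full predictor table). Blocks
    still wider than ``target_width`` then lose their lowest-VIP variables.
    Returns the reduced table and a removal log (variable, block, reason).
    """
    if target_width < 1:
        raise ValueError("target block width must be at least 1")
    model = pls.fit_pls(env, responses, 1)
    vip0 = pd.Series(pls.vip(model), index=env.columns)
    removals: list[dict] = []
    keep_cols: list[str] = []
    for block, cols in BLOCKS.items():
        cols = [c for c in cols if c in env.columns]
        if len(cols) < 2:
            keep_cols += cols
            continue
        current = list(cols)
        while True:
            corr = env[current].corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            if corr.size == 0 or corr.max() <= r_threshold:
                break
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            a, b = current[i], current[j]
            drop, kept = (a, b) if vip0[a] <= vip0[b] else (b, a)
            removals.append({"variable": drop, "block": block,
                             "reason": f"|r| = {corr[i, j]:.3f} with {kept}, lower VIP"})
            current.remove(drop)
        while len(current) > target_width:
            drop = min(current, key=lambda c: (vip0[c], current.index(c)))
            removals.append({"variable": drop, "block": block,
                             "reason": "lowest VIP, block width reduction"})
            current.remove(drop)
        keep_cols += [c for c in cols if c in current]
    log = pd.DataFrame(removals, columns=["variable", "block", "reason"])
    return env[keep_cols], log


def prescreen_vip(env: pd.DataFrame, response, vip_cut: float = 0.9,
                  max_vars: int = 15) -> list[str]:
    """Preliminary one-component PLS screen for a single response.

    Keeps predictors with VIP > ``vip_cut``; if more than ``max_vars``
    qualify, only the highest-VIP ``max_vars`` are retained.
    """
    model = pls.fit_pls(env, response, 1)
    v = pd.Series(pls.vip(model), index=env.columns)
    selected = v[v > vip_cut].sort_values(ascending=False, kind="stable")
    return list(selected.index[:max_vars])


@dataclass
class CrossValSummary:
    """Full-data fit plus leave-N-out fold statistics for one model."""

    label: str
    predictors: list[str]
    full_n_comp: int
    full_q2: float
    full_r2: float
    significant: bool
    fold_n_comp: list[int]
    fold_q2: list[float]
    fold_r2: list[float]
    vip_mean: pd.Series
    vip_sd: pd.Series
    coef_mean: pd.DataFrame
    coef_sd: pd.DataFrame
    partition: list[np.ndarray]
    full_model: pls.PLSModel = field(repr=False, default=None)

    @property
    def n_mode(self) -> int:
        return _mode(self.fold_n_comp)

    @property
    def n_range(self) -> tuple[int, int]:
        return int(min(self.fold_n_comp)), int(max(self.fold_n_comp))

    @property
    def q2_mean(self) -> float:
        return float(np.mean(self.fold_q2))

    @property
    def q2_sd(self) -> float:
        return float(np.std(self.fold_q2, ddof=1))

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.fold_r2, ddof=1))

    def summary_row(self) -> dict:
        lo, hi = self.n_range
        return {
            "model": self.label, "n_predictors": len(self.predictors),
            "N": self.full_n_comp, "Q2": self.full_q2, "R2": self.full_r2,
            "N_mode": self.n_mode, "N_range": f"{lo}-{hi}",
            "Q2_LNO_mean": self.q2_mean, "Q2_LNO_sd": self.q2_sd,
            "R2_LNO_mean": self.r2_mean, "R2_LNO_sd": self.r2_sd,
            "significant": self.significant,
        }


def _fit_summaries(X: pd.DataFrame, Y, threshold: float):
    """Component selection + fit on one data subset; returns stats at
    max(a*, 1) components so non-significant models still report their
    one-component diagnostics."""
    sel = pls.select_components(X, Y, threshold=threshold)
    a_fit = max(sel.a_star, 1)
    model = pls.fit_pls(X, Y, a_fit)
    q2 = float(sel.q2.q2_cum[a_fit - 1])
    r2 = float(model.r2y_cum[a_fit - 1])
    return sel, model, q2, r2


def lno_crossvalidate(X: pd.DataFrame, Y, *, n_groups: int = 5, seed=0,
                      threshold: float = pls.Q2_SIGNIFICANCE,
                      lno_eval: str = "internal", label: str = "",
                      partition: list[np.ndarray] | None = None) -> CrossValSummary:
    """Leave-N-out resampling of one PLS model.

    Sites are split into ``n_groups`` near-equal random groups; the model
    (scaling and component selection, predictor set frozen) is refit with
    each group left out. Per fold, Q2 is the internal leave-one-out
    cumulative Q2 of the training subsample (default) or, with
    ``lno_eval='holdout'``, the prediction Q2 on the omitted group.
    """
    Y = Y.to_frame() if isinstance(Y, pd.Series) else Y
    n = X.shape[0]
    if partition is None:
        partition = partition_sites(n, n_groups, seed)
    sel_f, model_f, q2_f, r2_f = _fit_summaries(X, Y, threshold)

    fold_n, fold_q2, fold_r2, vips, coefs = [], [], [], [], []
    for group in partition:
        mask = np.ones(n, dtype=bool)
        mask[group] = False
        X_tr, Y_tr = X.iloc[mask], Y.iloc[mask]
        sel, model, q2_k, r2_k = _fit_summaries(X_tr, Y_tr, threshold)
        if lno_eval == "holdout":
            pred = pls.predict(model, X.iloc[~mask])
            resid = Y.iloc[~mask].to_numpy(dtype=float) - pred
            denom = float(np.sum((Y.iloc[~mask].to_numpy(dtype=float)
                                  - Y_tr.to_numpy(dtype=float).mean(axis=0)) ** 2))
            q2_k = 1.0 - float(np.sum(resid**2)) / denom
        fold_n.append(sel.a_star)
        fold_q2.append(q2_k)
        fold_r2.append(r2_k)
        vips.append(pd.Series(pls.vip(model), index=X.columns))
        coefs.append(pd.DataFrame(model.B, index=X.columns, columns=Y.columns))

    vip_df = pd.concat(vips, axis=1)
    coef_stack = np.stack([c.to_numpy() for c in coefs])
    return CrossValSummary(
        label=label, predictors=list(X.columns),
        full_n_comp=sel_f.a_star, full_q2=q2_f, full_r2=r2_f,
        significant=sel_f.significant,
        fold_n_comp=fold_n, fold_q2=fold_q2, fold_r2=fold_r2,
        vip_mean=vip_df.mean(axis=1), vip_sd=vip_df.std(axis=1, ddof=1),
        coef_mean=pd.DataFrame(coef_stack.mean(axis=0), index=X.columns, columns=Y.columns),
        coef_sd=pd.DataFrame(coef_stack.std(axis=0, ddof=1), index=X.columns, columns=Y.columns),
        partition=partition, full_model=model_f,
    )


def _combo_columns(env: pd.DataFrame, combo: str) -> list[str]:
    blocks = COMBO_LABELS[combo]
    return [c for c in env.columns if ENV_BLOCK_OF.get(c) in blocks]


def combination_models(env: pd.DataFrame, responses: pd.DataFrame,
                       config: PipelineConfig | None = None, *,
                       response_set: str = "",
                       partition: list[np.ndarray] | None = None,
                       ) -> tuple[pd.DataFrame, dict[str, CrossValSummary]]:
    """Multivariate-response PLS for each block combination.

    Returns a summary table (one row per combination) and the underlying
    cross-validation summaries keyed by combination label.
    """
    config = config or PipelineConfig()
    config.validate()
    rows, details = [], {}
    for combo in config.combos:
        cols = _combo_columns(env, combo)
        if not cols:
            raise ValueError(f"combination {combo!r} selects no predictor columns")
        cv = lno_crossvalidate(
            env[cols], responses, n_groups=config.n_groups, seed=config.seed,
            threshold=config.q2_threshold, lno_eval=config.lno_eval,
            label=combo, partition=partition)
        details[combo] = cv
        row = cv.summary_row()
        row["response_set"] = response_set
        rows.append(row)
    table = pd.DataFrame(rows)
    return table[["response_set"] + [c for c in table.columns if c != "response_set"]], details


def univariate_models(env: pd.DataFrame, responses: pd.DataFrame,
                      config: PipelineConfig | None = None, *,
                      response_names: list[str] | None = None,
                      partition: list[np.ndarray] | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, CrossValSummary]]:
    """Per-response PLS models on the pooled pruned predictor table.

    Covers are arcsine-sqrt transformed (diversities never are); predictors
    pass the VIP > 0.9 / top-15 prescreen before the final cross-validated
    model. Returns the per-response summary table, the VIP report (only
    fold-mean VIP > 1 rows, descending), and the full summaries.
    """
    config = config or PipelineConfig()
    config.validate()
    names = response_names or UNIVARIATE_RESPONSES
    missing = [r for r in names if r not in responses.columns]
    if missing:
        raise ValueError(f"missing response column(s): {missing}")
    rows, vip_rows, details = [], [], {}
    for name in names:
        y = responses[name]
        if name.startswith("cover"):
            y = pd.Series(arcsine_sqrt(y.to_numpy(dtype=float) / 100.0),
                          index=y.index, name=name)
        selected = prescreen_vip(env, y, vip_cut=config.vip_cut, max_vars=config.max_vars)
        if not selected:  # nothing passes the screen: fall back to all predictors
            selected = list(env.columns)
        cv = lno_crossvalidate(
            env[selected], y, n_groups=config.n_groups, seed=config.seed,
            threshold=config.q2_threshold, lno_eval=config.lno_eval,
            label=name, partition=partition)
        details[name] = cv
        rows.append(cv.summary_row())
        strong = cv.vip_mean[cv.vip_mean > 1.0].sort_values(ascending=False, kind="stable")
        for pred in strong.index:
            vip_rows.append({
                "response": name, "predictor": pred,
                "VIP_mean": float(cv.vip_mean[pred]), "VIP_sd": float(cv.vip_sd[pred]),
                "coef_mean": float(cv.coef_mean.loc[pred, name]),
                "coef_sd": float(cv.coef_sd.loc[pred, name]),
            })
    summary = pd.DataFrame(rows)
    vip_report = pd.DataFrame(
        vip_rows, columns=["response", "predictor", "VIP_mean", "VIP_sd",
                           "coef_mean", "coef_sd"])
    return summary, vip_report, details


@dataclass
class PipelineReport:
    """Everything the end-to-end run produced, ready to serialise."""

    config: PipelineConfig
    trait_anova: pd.DataFrame
    trait_tukeys: dict
    cluster: traits.ElbowResult
    removals: pd.DataFrame
    pruned_env: pd.DataFrame
    combo_table: pd.DataFrame
    combo_details: dict[str, dict[str, CrossValSummary]]
    univariate_summary: pd.DataFrame
    vip_report: pd.DataFrame
    univariate_details: dict[str, CrossValSummary]
    partition: list[np.ndarray]

    def metadata(self) -> dict:
        sel = self.cluster.selected
        return {
            "seed": self.config.seed,
            "q2_threshold": self.config.q2_threshold,
            "r_threshold": self.config.r_threshold,
            "lno_eval": self.config.lno_eval,
            "sd_convention": "sample (n-1)",
            "partition": [g.tolist() for g in self.partition],
            "kmeans_k_star": self.cluster.k_star,
            "kmeans_intra_pct": None if sel is None else round(sel.intra_pct, 3),
            "kmeans_inter_pct": None if sel is None else round(sel.inter_pct, 3),
        }

    def tables(self) -> dict[str, pd.DataFrame]:
        """Report tables, deterministically ordered, keyed by file stem."""
        meta = self.metadata()
        cluster_rows = [
            {"K": K, "WSS": r.wss, "BSS": r.bss, "intra_pct": r.intra_pct,
             "inter_pct": r.inter_pct, "selected": K == self.cluster.k_star}
            for K, r in sorted(self.cluster.per_k.items())
        ]
        return {
            "trait_anova": (self.trait_anova, meta),
            "trait_clusters": (pd.DataFrame(cluster_rows).set_index("K"), meta),
            "removals": (self.removals.set_index("variable"), meta),
            "combination_models": (self.combo_table.set_index("model"), meta),
            "univariate_models": (self.univariate_summary.set_index("model"), meta),
            "vip_report": (self.vip_report.set_index(["response", "predictor"])
                           if len(self.vip_report) else self.vip_report, meta),
        }


def run_pipeline(environment: pd.DataFrame, responses: pd.DataFrame,
                 trait_table: pd.DataFrame,
                 config: PipelineConfig | None = None) -> PipelineReport:
    """Execute the complete protocol on schema-valid input tables."""
    config = config or PipelineConfig()
    config.validate()

    problems = []
    for validator, df in ((schema.validate_environment, environment),
                          (schema.validate_responses, responses),
                          (schema.validate_traits, trait_table)):
        try:
            validator(df)
        except schema.SchemaError as exc:
            problems += [f"{exc.table}: {p}" for p in exc.problems]
    if problems:
        raise schema.SchemaError("input", problems)
    if not environment.index.equals(responses.index):
        raise schema.SchemaError("input", ["environment and responses row ids differ"])

    anova_df, tukeys = traits.trait_anova_table(trait_table, alpha=config.alpha)
    logged = traits.log_transform_traits(trait_table)
    cluster = traits.kmeans_elbow(
        logged[schema.TRAIT_COLUMNS], range(config.k_range[0], config.k_range[1] + 1),
        labels=trait_table["pft"].to_numpy(), restarts=config.kmeans_restarts,
        seed=config.seed)

    transformed = responses.copy()
    for col in transformed.columns:
        if col.startswith("cover"):
            transformed[col] = arcsine_sqrt(transformed[col].to_numpy(dtype=float) / 100.0)
    pruned, removals = prune_correlated(
        environment, transformed, r_threshold=config.r_threshold,
        target_width=config.target_width)

    partition = partition_sites(environment.shape[0], config.n_groups, config.seed)

    combo_tables, combo_details = [], {}
    for set_name, cols in (("cover", COVER_SET), ("diversity", DIV_SET)):
        table, details = combination_models(
            pruned, transformed[cols], config, response_set=set_name,
            partition=partition)
        combo_tables.append(table)
        combo_details[set_name] = details
    combo_table = pd.concat(combo_tables, ignore_index=True)

    uni_summary, vip_report, uni_details = univariate_models(
        pruned, responses, config, partition=partition)

    return PipelineReport(
        config=config, trait_anova=anova_df, trait_tukeys=tukeys, cluster=cluster,
        removals=removals, pruned_env=pruned, combo_table=combo_table,
        combo_details=combo_details, univariate_summary=uni_summary,
        vip_report=vip_report, univariate_details=uni_details, partition=partition,
    )


def write_report(report: PipelineReport, out_dir) -> list[str]:
    """Serialise every report table as CSV with metadata headers.

    Deterministic: the same report writes byte-identical files.
    """
    from . import io  # local import keeps io free of pipeline imports
    from pathlib import Path

    out = Path(out_dir)
    written = []
    for stem, (df, meta) in report.tables().items():
        path = out / f"{stem}.csv"
        io.write_table(df, path, metadata=meta)
        written.append(str(path))
    return written
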