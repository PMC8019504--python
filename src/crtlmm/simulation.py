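"""Monte Carlo estimation of Type I error rates over a factorial design grid.

For each grid point (K clusters, N per cluster, between-cluster variance
sigma_b2, residual variance sigma2) the engine simulates null datasets,
analyzes each with the random-intercept mixed model (REML for the Wald
family, ML twice for the likelihood ratio test) plus the cluster-means
t-test, and records the proportion of replicates whose two-sided p-value
falls below the nominal alpha — the empirical Type I error (TIE) rate —
together with its binomial Monte Carlo standard error.

Replicate random streams are pre-assigned from a seed tree keyed by
(master_seed, condition_index, replicate_index), so results are
bit-identical regardless of execution order, and any condition can be rerun
in isolation.

Also provided: batching of a condition's replicates into equal blocks of
TIE outcomes, and the balanced three-way factorial ANOVA (K x N x sigma_b2,
factors categorical) on those batch TIE rates used to test factor
interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dgp import DesignConfig, generate_null_dataset, icc, replicate_rng
from .inference import ALL_METHODS, cluster_means_ttest, lrt, wald_test
from .lmm import fit_ml, fit_reml

__all__ = [
    "SimulationGrid",
    "MethodTIE",
    "ConditionResult",
    "ConditionAbortError",
    "run_condition",
    "run_grid",
    "mc_standard_error",
    "batched_tie",
    "interaction_anova",
    "interaction_anova_by_method",
    "results_to_frame",
    "write_results_csv",
    "read_results_csv",
]

#: Default factor levels: 4 cluster counts x 4 cluster sizes x 7 variance
#: ratios at unit residual variance, 10,000 replicates per condition.
DEFAULT_K = (10, 20, 40, 100)
DEFAULT_N = (3, 10, 20, 50)
DEFAULT_SIGMA_B2 = (0.001, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5)


@dataclass(frozen=True)
class SimulationGrid:
    """Full factorial simulation design (defaults reproduce the study grid)."""

    K_values: tuple[int, ...] = DEFAULT_K
    N_values: tuple[int, ...] = DEFAULT_N
    sigma_b2_values: tuple[float, ...] = DEFAULT_SIGMA_B2
    sigma2: float = 1.0
    replicates: int = 10_000
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.replicates < 0:
            raise ValueError("replicates must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        for sb2 in self.sigma_b2_values:
            if sb2 < 0:
                raise ValueError("sigma_b2 values must be >= 0")
        # K/N constraints surface via DesignConfig at condition build time
        if not self.K_values or not self.N_values or not self.sigma_b2_values:
            raise ValueError("factor level sets must be non-empty")

    def conditions(self) -> list[DesignConfig]:
        """Grid points in deterministic (K, N, sigma_b2) product order.

        The position in this list is the condition_index of the seed tree.
        """
        return [
            DesignConfig(K=K, N=N, sigma_b2=sb2, sigma2=self.sigma2, seed=self.master_seed)
            for K, N, sb2 in itertools.product(self.K_values, self.N_values, self.sigma_b2_values)
        ]


@dataclass(frozen=True)
class MethodTIE:
    """Per-method rejection tally for one condition."""

    rejections: int
    tie: float  # NaN when there are no replicates
    mc_se: float
    ci_lo: float
    ci_hi: float


@dataclass
class ConditionResult:
    """TIE estimates for every method at one grid point."""

    config: DesignConfig
    icc: float
    replicates: int
    alpha: float
    methods: dict[str, MethodTIE]
    boundary_rate: float
    n_converged: int
    p_values: pd.DataFrame | None = field(default=None, repr=False)


class ConditionAbortError(RuntimeError):
    """More than 1% of replicates failed to fit: the condition is unusable."""


def mc_standard_error(tie: float, replicates: int) -> float:
    """Binomial Monte Carlo standard error sqrt(tie (1 - tie) / replicates)."""
    if not 0.0 <= tie <= 1.0:
        raise ValueError(f"tie must be in [0, 1], got {tie}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    return float(np.sqrt(tie * (1.0 - tie) / replicates))


def _tally(rejections: int, replicates: int) -> MethodTIE:
    if replicates == 0:
        return MethodTIE(rejections=0, tie=float("nan"), mc_se=float("nan"),
                         ci_lo=float("nan"), ci_hi=float("nan"))
    tie = rejections / replicates
    se = mc_standard_error(tie, replicates)
    z = stats.norm.ppf(0.975)
    return MethodTIE(
        rejections=rejections,
        tie=tie,
        mc_se=se,
        ci_lo=max(0.0, tie - z * se),
        ci_hi=min(1.0, tie + z * se),
    )


def run_condition(
    config: DesignConfig,
    replicates: int,
    alpha: float = 0.05,
    master_seed: int | None = None,
    condition_index: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    keep_pvalues: bool = False,
) -> ConditionResult:
    """Estimate per-method TIE at one grid point.

    Each replicate generates a null dataset from its own pre-assigned random
    stream, fits the model by REML (Wald tests) and by ML with and without
    the treatment term (LRT), runs the requested tests, and counts two-sided
    p-values strictly below ``alpha`` as rejections.  A replicate whose fit
    fails is excluded and reported through ``n_converged``; more than 1%
    failures aborts the condition (the closed-form balanced fits should
    never fail, so failures indicate a defect, not bad luck).

    ``methods`` may be a subset of the six labels; restricting it (e.g. to
    the cluster-means t-test alone) skips the model fits it does not need.
    ``master_seed`` defaults to ``config.seed``.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if master_seed is None:
        master_seed = config.seed
    need_reml = any(m.startswith("wald_") for m in methods)
    need_ml = "lrt" in methods

    rejections = {m: 0 for m in methods}
    boundary_count = 0
    n_converged = 0
    failures = 0
    pval_rows = np.empty((replicates, len(methods))) if keep_pvalues else None

    for rep in range(replicates):
        rng = replicate_rng(master_seed, condition_index, rep)
        data = generate_null_dataset(config, rng=rng)
        try:
            pvals: dict[str, float] = {}
            reml = fit_reml(data, validate=False) if need_reml else None
            if need_reml:
                boundary_count += reml.boundary
                for m in methods:
                    if m.startswith("wald_"):
                        pvals[m] = wald_test(reml, m, config.K, config.N).p_value
            if need_ml:
                ml_full = fit_ml(data, include_treatment=True, validate=False)
                ml_null = fit_ml(data, include_treatment=False, validate=False)
                pvals["lrt"] = lrt(ml_null, ml_full).p_value
            if "cluster_means_ttest" in methods:
                pvals["cluster_means_ttest"] = cluster_means_ttest(data, validate=False).p_value
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            failures += 1
            if pval_rows is not None:
                pval_rows[rep, :] = np.nan
            continue
        n_converged += 1
        for j, m in enumerate(methods):
            if pvals[m] < alpha:
                rejections[m] += 1
            if pval_rows is not None:
                pval_rows[rep, j] = pvals[m]

    if replicates > 0 and failures > 0.01 * replicates:
        raise ConditionAbortError(
            f"{failures}/{replicates} replicates failed to fit at {config}"
        )

    return ConditionResult(
        config=config,
        icc=icc(config.sigma_b2, config.sigma2),
        replicates=replicates,
        alpha=alpha,
        methods={m: _tally(rejections[m], n_converged) for m in methods},
        boundary_rate=(boundary_count / n_converged) if (n_converged and need_reml) else float("nan"),
        n_converged=n_converged,
        p_values=(
            pd.DataFrame(pval_rows, columns=list(methods)) if pval_rows is not None else None
        ),
    )


def run_grid(
    grid: SimulationGrid,
    methods: tuple[str, ...] = ALL_METHODS,
    keep_pvalues: bool = False,
    progress=None,
) -> list[ConditionResult]:
    """Run every condition of the grid; one :class:`ConditionResult` each.

    Conditions are independent (each owns its replicate streams through its
    position in the grid), so results are identical regardless of execution
    order.  ``progress`` may be a callable ``(index, total, config)`` invoked
    before each condition.
    """
    configs = grid.conditions()
    results = []
    for idx, config in enumerate(configs):
        if progress is not None:
            progress(idx, len(configs), config)
        try:
            results.append(
                run_condition(
                    config,
                    replicates=grid.replicates,
                    alpha=grid.alpha,
                    master_seed=grid.master_seed,
                    condition_index=idx,
                    methods=methods,
                    keep_pvalues=keep_pvalues,
                )
            )
        except ConditionAbortError as err:
            raise ConditionAbortError(f"condition {idx}: {err}") from err
    return results


def batched_tie(p_values: np.ndarray, batches: int, alpha: float = 0.05) -> np.ndarray:
    """Split one method's replicate p-values into equal batches of TIE rates.

    Returns per-batch rejection proportions in replicate order; the mean of
    the batch TIEs equals the overall TIE exactly.  The replicate count must
    be divisible by ``batches``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D (one method)")
    if batches < 1 or p.size % batches != 0:
        raise ValueError(f"cannot split {p.size} replicates into {batches} equal batches")
    return (p.reshape(batches, -1) < alpha).mean(axis=1)


def _balanced_anova_3way(df: pd.DataFrame, response: str, factors: tuple[str, str, str]) -> pd.DataFrame:
    """Closed-form sums of squares for a balanced 3-way fixed-effects factorial."""
    a_f, b_f, c_f = factors
    cell_counts = df.groupby(list(factors), observed=True)[response].count()
    if cell_counts.nunique() != 1:
        raise ValueError("unbalanced input: all factor cells must have equal replication")
    r = int(cell_counts.iloc[0])
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()

    def level_means(cols):
        return df.groupby(list(cols), observed=True)[response].mean()

    mA, mB, mC = level_means([a_f]), level_means([b_f]), level_means([c_f])
    mAB, mAC, mBC = level_means([a_f, b_f]), level_means([a_f, c_f]), level_means([b_f, c_f])
    mABC = level_means([a_f, b_f, c_f])
    a, b, c = len(mA), len(mB), len(mC)

    ss = {}
    ss[a_f] = b * c * r * ((mA - grand) ** 2).sum()
    ss[b_f] = a * c * r * ((mB - grand) ** 2).sum()
    ss[c_f] = a * b * r * ((mC - grand) ** 2).sum()

    def interaction_ss(m2, m1a, m1b, mult):
        dev = m2.copy()
        for (la, lb), v in m2.items():
            dev.loc[(la, lb)] = v - m1a[la] - m1b[lb] + grand
        return mult * (dev**2).sum()

    ss[f"{a_f}:{b_f}"] = interaction_ss(mAB, mA, mB, c * r)
    ss[f"{a_f}:{c_f}"] = interaction_ss(mAC, mA, mC, b * r)
    ss[f"{b_f}:{c_f}"] = interaction_ss(mBC, mB, mC, a * r)

    dev3 = mABC.copy()
    for (la, lb, lc), v in mABC.items():
        dev3.loc[(la, lb, lc)] = (
            v - mAB[(la, lb)] - mAC[(la, lc)] - mBC[(lb, lc)] + mA[la] + mB[lb] + mC[lc] - grand
        )
    ss[f"{a_f}:{b_f}:{c_f}"] = r * (dev3**2).sum()

    cell_mean_per_row = df.groupby(list(factors), observed=True)[response].transform("mean")
    ss_error = float(((y - cell_mean_per_row.to_numpy(dtype=float)) ** 2).sum())

    dofs = {
        a_f: a - 1,
        b_f: b - 1,
        c_f: c - 1,
        f"{a_f}:{b_f}": (a - 1) * (b - 1),
        f"{a_f}:{c_f}": (a - 1) * (c - 1),
        f"{b_f}:{c_f}": (b - 1) * (c - 1),
        f"{a_f}:{b_f}:{c_f}": (a - 1) * (b - 1) * (c - 1),
    }
    df_error = a * b * c * (r - 1)
    ms_error = ss_error / df_error if df_error > 0 else float("nan")

    rows = []
    for effect, ss_val in ss.items():
        d = dofs[effect]
        ms = ss_val / d
        if ms_error > 0:
            F = ms / ms_error
            p = float(stats.f.sf(F, d, df_error))
        else:
            F, p = float("nan"), float("nan")
        rows.append({"effect": effect, "df": d, "ss": float(ss_val), "ms": float(ms), "F": F, "p": p})
    rows.append({"effect": "residual", "df": df_error, "ss": ss_error,
                 "ms": ms_error, "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)


def interaction_anova(
    batch_ties: pd.DataFrame,
    factors: tuple[str, str, str] = ("K", "N", "sigma_b2"),
    response: str = "tie",
) -> pd.DataFrame:
    """Three-way fixed-effects factorial ANOVA on batch TIE outcomes.

    ``batch_ties`` is long-format with one row per (condition, batch):
    factor columns plus the batch TIE response.  Factors are treated as
    categorical; the input must be a balanced full factorial (equal batches
    per cell).  Returns a table of effect, df, SS, MS, F and p covering all
    main effects and two- and three-way interactions.
    """
    for col in (*factors, response):
        if col not in batch_ties.columns:
            raise ValueError(f"batch_ties missing column {col!r}")
    return _balanced_anova_3way(batch_ties, response, factors)


def interaction_anova_by_method(
    results: list[ConditionResult],
    batches: int = 10,
    methods: tuple[str, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Batch each condition's archived p-values and run one ANOVA per method.

    Requires results produced with ``keep_pvalues=True``.
    """
    tables = {}
    if not results:
        raise ValueError("no condition results supplied")
    if results[0].p_values is None:
        raise ValueError("interaction ANOVA needs archived p-values (keep_pvalues=True)")
    if methods is None:
        methods = tuple(results[0].p_values.columns)
    for m in methods:
        rows = []
        for res in results:
            ties = batched_tie(res.p_values[m].to_numpy(), batches, alpha=res.alpha)
            for batch_idx, tie in enumerate(ties):
                rows.append(
                    {
                        "K": res.config.K,
                        "N": res.config.N,
                        "sigma_b2": res.config.sigma_b2,
                        "batch": batch_idx,
                        "tie": tie,
                    }
                )
        tables[m] = interaction_anova(pd.DataFrame(rows))
    return tables


def results_to_frame(results: list[ConditionResult]) -> pd.DataFrame:
    """Flatten condition results to one row per (condition, method)."""
    rows = []
    for res in results:
        cfg = res.config
        for m, tally in res.methods.items():
            rows.append(
                {
                    "K": cfg.K,
                    "N": cfg.N,
                    "sigma_b2": cfg.sigma_b2,
                    "sigma2": cfg.sigma2,
                    "icc": res.icc,
                    "method": m,
                    "replicates": res.replicates,
                    "rejections": tally.rejections,
                    "tie": tally.tie,
                    "mc_se": tally.mc_se,
                    "ci_lo": tally.ci_lo,
                    "ci_hi": tally.ci_hi,
                    "boundary_rate": res.boundary_rate,
                    "n_converged": res.n_converged,
                }
            )
    return pd.DataFrame(rows)


def write_results_csv(results: list[ConditionResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"K", "N", "sigma_b2", "icc", "method", "tie"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results CSV missing columns: {sorted(missing)}")
    return df
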